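"""Two-state maximum-likelihood gain/loss model and ancestral reconstruction.

Gene-family presence evolves along the rooted tree as a continuous-time
two-state Markov chain with gain rate ``alpha`` (absent -> present) and loss
rate ``beta`` (present -> absent), per unit branch length. The chain is the
standard binary-trait model: for a branch of length ``t`` with ``s = alpha +
beta`` the transition matrix is

    P(t) = [[ (beta + alpha e^{-st}) / s,  alpha (1 - e^{-st}) / s ],
            [ beta  (1 - e^{-st}) / s,  (alpha + beta e^{-st}) / s ]]

and the root prior is the stationary distribution
(beta/s absent, alpha/s present).

Likelihoods use Felsenstein's pruning algorithm vectorised over families;
marginal posteriors of presence at every node come from an upward/downward
pass. Event calling thresholds the posteriors in two tiers: an inclusive
tier (present iff P >= 0.5) and a high-confidence tier (gain on a branch iff
the parent is absent with P <= 0.2 and the child present with P >= 0.8,
symmetrically for losses).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .phylo import Phylogeny

ABSENT, PRESENT = 0, 1


class DegenerateDataError(ValueError):
    """Raised when no family varies across the leaves."""


@dataclass
class GainLossModel:
    """Fitted two-state gain/loss model."""

    alpha: float
    beta: float
    log_likelihood: float = np.nan

    @property
    def root_prior(self) -> np.ndarray:
        s = self.alpha + self.beta
        return np.array([self.beta / s, self.alpha / s])

    def transition_matrix(self, t: float) -> np.ndarray:
        return transition_matrices(np.array([t]), self.alpha, self.beta)[0]


def transition_matrices(t: np.ndarray, alpha: float, beta: float) -> np.ndarray:
    """Stack of 2x2 transition matrices for branch lengths ``t``."""
    t = np.asarray(t, dtype=float)
    s = alpha + beta
    e = np.exp(-s * t)
    P = np.empty(t.shape + (2, 2))
    P[..., 0, 0] = (beta + alpha * e) / s
    P[..., 0, 1] = (alpha - alpha * e) / s
    P[..., 1, 0] = (beta - beta * e) / s
    P[..., 1, 1] = (alpha + beta * e) / s
    return P


def _leaf_matrix(tree: Phylogeny, M: pd.DataFrame) -> np.ndarray:
    """Observed presence (families x leaves) ordered by tree leaf index."""
    labels = tree.leaf_labels()
    missing = [g for g in labels if g not in M.columns]
    if missing:
        raise ValueError(f"presence matrix lacks genomes: {missing}")
    X = M[labels].to_numpy()
    if not np.isin(X, (0, 1)).all():
        raise ValueError("presence matrix must be binary")
    return X.astype(np.int8)


def _pruning(tree: Phylogeny, X: np.ndarray, alpha: float, beta: float):
    """Upward pass: scaled partial likelihoods ``D`` and total log-likelihood.

    Returns (D, logscale, loglik) with D of shape (F, n_nodes, 2); each
    node's D is normalised to sum 1 per family and the dropped factor is
    accumulated in logscale.
    """
    F = X.shape[0]
    n = tree.n_nodes
    P = transition_matrices(tree.blen, alpha, beta)  # (n, 2, 2); P[0] unused
    D = np.ones((F, n, 2))
    logscale = np.zeros(F)
    leaves = tree.leaf_indices()
    for k, node in enumerate(leaves):
        D[:, node, 0] = X[:, k] == 0
        D[:, node, 1] = X[:, k] == 1
    for node in tree.postorder():
        ch = tree.children[node]
        if not ch:
            continue
        prod = np.ones((F, 2))
        for c in ch:
            # message from child c: sum_j P_c[i, j] * D_c[j]
            prod *= D[:, c, :] @ P[c].T
        norm = prod.sum(axis=1)
        norm = np.where(norm > 0, norm, 1.0)
        D[:, node, :] = prod / norm[:, None]
        logscale += np.log(norm)
    prior = np.array([beta, alpha]) / (alpha + beta)
    root_lik = D[:, 0, :] @ prior
    loglik = float(np.sum(np.log(root_lik) + logscale))
    return D, logscale, loglik


def log_likelihood(tree: Phylogeny, M: pd.DataFrame, alpha: float, beta: float) -> float:
    X = _leaf_matrix(tree, M)
    return _pruning(tree, X, alpha, beta)[2]


def fit_model(
    tree: Phylogeny,
    M: pd.DataFrame,
    n_starts: int = 3,
    seed: int = 0,
) -> GainLossModel:
    """Fit (alpha, beta) by maximising the pruning likelihood over families.

    Optimisation runs in log-rate space with bounded L-BFGS-B from
    ``n_starts`` deterministic multistart points.
    """
    X = _leaf_matrix(tree, M)
    variable = ~np.all(X == X[:, :1], axis=1)
    if not variable.any():
        raise DegenerateDataError("every family is constant across leaves")
    # invariant families carry no gain/loss signal and would only drag the
    # stationary frequencies toward their state; fit on variable families
    X = X[variable]

    def nll(logrates: np.ndarray) -> float:
        a, b = np.exp(logrates)
        return -_pruning(tree, X, a, b)[2]

    rng = np.random.default_rng(seed)
    starts = [np.log([0.5, 0.5])]
    starts += [rng.uniform(np.log(0.02), np.log(20.0), size=2) for _ in range(n_starts - 1)]
    best = None
    for x0 in starts:
        res = minimize(
            nll,
            x0,
            method="L-BFGS-B",
            bounds=[(np.log(1e-4), np.log(1e3))] * 2,
        )
        if best is None or res.fun < best.fun:
            best = res
    a, b = np.exp(best.x)
    return GainLossModel(alpha=float(a), beta=float(b), log_likelihood=float(-best.fun))


def posterior_presence(
    tree: Phylogeny, M: pd.DataFrame, model: GainLossModel
) -> pd.DataFrame:
    """Marginal posterior probability of presence at every node.

    Upward (pruning) pass followed by a downward pass propagating the
    above-branch message; leaf posteriors equal the observed states.
    Returns a families x nodes DataFrame whose columns follow preorder
    node indexing and are labelled with branch/leaf ids (root = 'root').
    """
    X = _leaf_matrix(tree, M)
    F = X.shape[0]
    n = tree.n_nodes
    alpha, beta = model.alpha, model.beta
    P = transition_matrices(tree.blen, alpha, beta)
    D, _, _ = _pruning(tree, X, alpha, beta)

    # U[:, v, i]: message arriving at node v from above, i = state of v.
    U = np.ones((F, n, 2))
    U[:, 0, :] = model.root_prior
    for node in tree.preorder():
        ch = tree.children[node]
        if not ch:
            continue
        # sibling-excluded products of child messages
        msgs = {c: D[:, c, :] @ P[c].T for c in ch}
        for c in ch:
            above = U[:, node, :].copy()
            for s in ch:
                if s != c:
                    above *= msgs[s]
            U[:, c, :] = above @ P[c]
            norm = U[:, c, :].sum(axis=1, keepdims=True)
            norm[norm == 0] = 1.0
            U[:, c, :] /= norm

    post = U * D
    total = post.sum(axis=2)
    total[total == 0] = 1.0
    p_present = post[..., 1] / total

    # pin leaves exactly to observations
    for k, node in enumerate(tree.leaf_indices()):
        p_present[:, node] = X[:, k]

    cols = ["root"] + tree.branch_ids()
    return pd.DataFrame(p_present, index=M.index, columns=cols)


@dataclass
class EventCalls:
    """Branch-wise gain/loss calls for every family.

    ``gained``/``lost`` are boolean (families x branches) arrays in the
    canonical branch order (preorder of child nodes).
    """

    families: pd.Index
    branch_ids: list
    gained: np.ndarray
    lost: np.ndarray
    tier: str

    def to_frame(self) -> pd.DataFrame:
        fam_idx, br_idx = np.nonzero(self.gained | self.lost)
        rows = []
        for f, b in zip(fam_idx, br_idx):
            rows.append(
                {
                    "family_id": self.families[f],
                    "branch_id": self.branch_ids[b],
                    "event": "gain" if self.gained[f, b] else "loss",
                    "tier": self.tier,
                }
            )
        return pd.DataFrame(rows, columns=["family_id", "branch_id", "event", "tier"])


def call_events(post: pd.DataFrame, tree: Phylogeny, tier: str = "inclusive") -> EventCalls:
    """Call gains/losses on each branch by thresholding node posteriors.

    inclusive: gain iff P_parent < 0.5 and P_child >= 0.5 (>= is inclusive:
    a node at exactly 0.5 counts as present). high: gain iff P_parent <= 0.2
    and P_child >= 0.8. Losses are symmetric.
    """
    if tier not in ("inclusive", "high"):
        raise ValueError(f"unknown tier {tier!r}")
    Pm = post.to_numpy()
    child = tree.branch_child_nodes()
    par = tree.parent[child]
    pa, pd_ = Pm[:, par], Pm[:, child]
    if tier == "inclusive":
        gained = (pa < 0.5) & (pd_ >= 0.5)
        lost = (pa >= 0.5) & (pd_ < 0.5)
    else:
        gained = (pa <= 0.2) & (pd_ >= 0.8)
        lost = (pa >= 0.8) & (pd_ <= 0.2)
    return EventCalls(
        families=post.index,
        branch_ids=tree.branch_ids(),
        gained=gained,
        lost=lost,
        tier=tier,
    )


def branch_gain_probabilities(post: pd.DataFrame, tree: Phylogeny) -> pd.DataFrame:
    """Per-branch gain probabilities: posterior presence increase along the
    branch, clipped to [0, 1]. Used by the experimental product score."""
    Pm = post.to_numpy()
    child = tree.branch_child_nodes()
    par = tree.parent[child]
    g = np.clip(Pm[:, child] - Pm[:, par], 0.0, 1.0)
    return pd.DataFrame(g, index=post.index, columns=tree.branch_ids())


def simulate_presence_under_model(
    tree: Phylogeny,
    alpha: float,
    beta: float,
    n_families: int,
    rng: np.random.Generator,
    condition_on_variable: bool = False,
) -> pd.DataFrame:
    """Simulate leaf presence directly under the two-state model.

    Independent families, root drawn from the stationary prior. Used for
    parameter-recovery checks and as a model-faithful counterpart to the
    segmental co-transfer simulator (which deliberately violates the
    per-family independence this model assumes).
    """
    P = transition_matrices(tree.blen, alpha, beta)
    prior1 = alpha / (alpha + beta)
    states = np.empty((n_families, tree.n_nodes), dtype=np.int8)
    states[:, 0] = rng.random(n_families) < prior1
    for node in tree.preorder()[1:]:
        p_present = P[node][states[:, tree.parent[node]], 1]
        states[:, node] = rng.random(n_families) < p_present
    leaves = tree.leaf_indices()
    X = states[:, leaves]
    if condition_on_variable:
        keep = ~np.all(X == X[:, :1], axis=1)
        X = X[keep]
    fam = [f"fam{i:05d}" for i in range(X.shape[0])]
    return pd.DataFrame(X, index=pd.Index(fam, name="family_id"), columns=tree.leaf_labels())
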