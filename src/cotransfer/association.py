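"""Co-gain association scores, permutation null model and empirical FDR.

Each gene family's gain history is a binary vector over the tree's branches
(1 = gained on that branch). For a pair of families the branch-wise pattern
counts form a 2x2 contingency table; the association score

    t = log10( right-tail p of Fisher's exact test )

is more negative for pairs co-gained more often than chance expects.
Because branch observations are not independent, significance comes from an
empirical null: leaf presences of every family are permuted independently
across genomes, the whole reconstruction/calling/scoring chain is re-run,
and FDR(t) = N_null(t) / N_data(t) with strict `score < t` counting on both
sides.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .phylo import Phylogeny
from .reconstruction import (
    EventCalls,
    GainLossModel,
    branch_gain_probabilities,
    call_events,
    fit_model,
    posterior_presence,
)


def build_gain_vectors(events: EventCalls) -> pd.DataFrame:
    """Gain vectors (families x branches, {0,1}) for families with >= 1 gain.

    Branch order is the canonical preorder-of-child order fixed by the tree;
    families never gained contribute only [0,0] patterns (p = 1) and are
    excluded from the pair universe.
    """
    G = events.gained.astype(np.int8)
    keep = G.sum(axis=1) > 0
    return pd.DataFrame(
        G[keep], index=events.families[keep], columns=events.branch_ids
    )


def fisher_right_tail(n00: int, n01: int, n10: int, n11: int) -> float:
    """Right-tail Fisher p-value: P(X >= n11) for the hypergeometric with
    the table's margins. Equals scipy's `fisher_exact(..., 'greater')`."""
    for v in (n00, n01, n10, n11):
        if v < 0:
            raise ValueError("contingency counts must be non-negative")
    N = n00 + n01 + n10 + n11
    K = n11 + n10  # gains of family A
    n = n11 + n01  # gains of family B
    return float(hypergeom.sf(n11 - 1, N, K, n))


def score_pair(a: np.ndarray, b: np.ndarray) -> float:
    """Association score t = log10 Fisher right-tail p for two gain vectors."""
    a = np.asarray(a, dtype=np.int8)
    b = np.asarray(b, dtype=np.int8)
    if a.shape != b.shape:
        raise ValueError("gain vectors must have equal length")
    n11 = int(np.sum((a == 1) & (b == 1)))
    n10 = int(np.sum((a == 1) & (b == 0)))
    n01 = int(np.sum((a == 0) & (b == 1)))
    n00 = int(np.sum((a == 0) & (b == 0)))
    return float(np.log10(fisher_right_tail(n00, n01, n10, n11)))


def score_all_pairs(gain_vectors: pd.DataFrame) -> pd.DataFrame:
    """Scores for every unordered pair of families with >= 1 gain each.

    Vectorised: co-gain counts via a single matrix product, the Fisher tail
    via the hypergeometric survival function on the unique (n11, kA, kB)
    triples.
    """
    G = gain_vectors.to_numpy(dtype=np.int64)
    fams = gain_vectors.index.to_numpy()
    F, B = G.shape
    if F < 2:
        return pd.DataFrame(columns=["family_a", "family_b", "n11", "t"])
    n11 = G @ G.T
    k = G.sum(axis=1)
    iu, ju = np.triu_indices(F, k=1)
    c11 = n11[iu, ju]
    kA, kB = k[iu], k[ju]
    # de-duplicate hypergeometric evaluations
    triples = np.stack([c11, kA, kB], axis=1)
    uniq, inv = np.unique(triples, axis=0, return_inverse=True)
    p_uniq = hypergeom.sf(uniq[:, 0] - 1, B, uniq[:, 1], uniq[:, 2])
    t = np.log10(p_uniq[inv])
    return pd.DataFrame(
        {
            "family_a": fams[iu],
            "family_b": fams[ju],
            "n11": c11,
            "t": np.minimum(t, 0.0),
        }
    )


def prob_product_score(gain_prob_a: np.ndarray, gain_prob_b: np.ndarray) -> float:
    """Experimental alternative score: sum over branches of the product of
    the two families' per-branch gain probabilities. Kept for comparison;
    in practice it picks up many weakly-related pairs."""
    a = np.clip(np.asarray(gain_prob_a, dtype=float), 0.0, 1.0)
    b = np.clip(np.asarray(gain_prob_b, dtype=float), 0.0, 1.0)
    if a.shape != b.shape:
        raise ValueError("gain probability vectors must have equal length")
    return float(np.dot(a, b))


def prob_product_scores(post: pd.DataFrame, tree: Phylogeny) -> pd.DataFrame:
    g = branch_gain_probabilities(post, tree)
    Gm = g.to_numpy()
    S = Gm @ Gm.T
    iu, ju = np.triu_indices(len(g), k=1)
    return pd.DataFrame(
        {
            "family_a": g.index.to_numpy()[iu],
            "family_b": g.index.to_numpy()[ju],
            "score": S[iu, ju],
        }
    )


# ----------------------------------------------------------------------
@dataclass
class NullEnsemble:
    """Null association scores from leaf-presence shuffling replicates."""

    scores: list  # one np.ndarray of t scores per replicate
    universe_sizes: list  # pair-universe size per replicate

    @property
    def n_reps(self) -> int:
        return len(self.scores)


def shuffle_null(
    M: pd.DataFrame,
    tree: Phylogeny,
    model: GainLossModel,
    n_reps: int = 1,
    seed: int = 0,
    tier: str = "inclusive",
    refit: bool = False,
) -> NullEnsemble:
    """Permutation null: shuffle each family's presences across extant
    genomes (preserving per-family counts), re-run posterior reconstruction,
    event calling and pair scoring.

    By default the empirically fitted (alpha, beta) is reused for the
    shuffled data (`refit=True` refits per replicate).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    X = M.to_numpy()
    scores, sizes = [], []
    for _ in range(n_reps):
        Xp = np.array([rng.permutation(row) for row in X])
        Mp = pd.DataFrame(Xp, index=M.index, columns=M.columns)
        mod = fit_model(tree, Mp) if refit else model
        post = posterior_presence(tree, Mp, mod)
        ev = call_events(post, tree, tier=tier)
        gv = build_gain_vectors(ev)
        tab = score_all_pairs(gv)
        scores.append(tab["t"].to_numpy())
        sizes.append(len(tab))
    return NullEnsemble(scores=scores, universe_sizes=sizes)


@dataclass
class FdrResult:
    threshold: float  # t*; -inf when no threshold reaches alpha
    alpha: float
    significant: pd.DataFrame  # rows of the empirical pair table with t < t*
    curve: pd.DataFrame = field(repr=False)  # t, N_d, N_n, FDR


def fdr_threshold(
    pair_table: pd.DataFrame,
    null: NullEnsemble,
    alpha: float,
) -> FdrResult:
    """Empirical FDR thresholding.

    N_d(t) = #{empirical pairs with score < t}; N_n(t) is the replicate mean
    of the null count, rescaled to the empirical pair-universe size. t* is
    the largest candidate t with FDR(t) = N_n(t)/N_d(t) <= alpha; the
    significant set is {pairs: score < t*}.
    """
    emp = np.sort(pair_table["t"].to_numpy())
    if emp.size == 0 or null.n_reps == 0:
        raise ValueError("both empirical and null score sets must be non-empty")
    n_emp = len(emp)
    null_sorted = [np.sort(s) for s in null.scores]
    scales = [n_emp / max(u, 1) for u in null.universe_sizes]

    # candidate thresholds: just above each distinct empirical score, so the
    # strict `< t` count at candidate t_k includes scores <= that value
    uniq = np.unique(emp)
    cand = np.nextafter(uniq, np.inf)
    Nd = np.searchsorted(emp, cand, side="left")
    Nn = np.zeros_like(cand, dtype=float)
    for s, sc in zip(null_sorted, scales):
        Nn += np.searchsorted(s, cand, side="left") * sc
    Nn /= null.n_reps
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(Nd > 0, Nn / np.maximum(Nd, 1), np.inf)
    curve = pd.DataFrame({"t": cand, "N_d": Nd, "N_n": Nn, "FDR": fdr})

    ok = np.nonzero(fdr <= alpha)[0]
    if ok.size == 0:
        warnings.warn(f"no threshold achieves FDR <= {alpha}; empty significant set")
        thr = -np.inf
    else:
        thr = float(cand[ok[-1]])
    sig = pair_table[pair_table["t"] < thr]
    return FdrResult(threshold=thr, alpha=alpha, significant=sig, curve=curve)
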