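import itertools

import numpy as np
import pandas as pd
import pytest

from cotransfer.phylo import Phylogeny
from cotransfer.reconstruction import (
    DegenerateDataError,
    GainLossModel,
    call_events,
    fit_model,
    log_likelihood,
    posterior_presence,
    simulate_presence_under_model,
    transition_matrices,
)
from cotransfer.simulate import SimulationConfig, simulate_tree


# ----------------------------------------------------------------------
# independent oracle: enumerate all internal-state assignments


def brute_force_posterior(tree, X_leaves, alpha, beta):
    """Exact marginal posteriors by summing over every internal assignment."""
    P = transition_matrices(tree.blen, alpha, beta)
    prior = np.array([beta, alpha]) / (alpha + beta)
    leaves = list(tree.leaf_indices())
    internals = list(tree.internal_indices())
    F = X_leaves.shape[0]
    post = np.zeros((F, tree.n_nodes))
    for f in range(F):
        state = np.zeros(tree.n_nodes, dtype=int)
        state[leaves] = X_leaves[f]
        num = np.zeros(tree.n_nodes)
        den = 0.0
        for assign in itertools.product((0, 1), repeat=len(internals)):
            state[internals] = assign
            p = prior[state[0]]
            for c in range(1, tree.n_nodes):
                p *= P[c][state[tree.parent[c]], state[c]]
            den += p
            num += p * state
        post[f] = num / den
    return post


def random_tree(n_leaves, seed):
    return simulate_tree(SimulationConfig(n_leaves=n_leaves, seed=seed))


@pytest.mark.parametrize("n_leaves,seed", [(4, 0), (5, 1), (5, 2)])
def test_posterior_matches_exhaustive_enumeration(n_leaves, seed):
    """Marginal posteriors equal brute-force state enumeration (tol 1e-9)."""
    tree = random_tree(n_leaves, seed)
    rng = np.random.default_rng(seed)
    X = rng.integers(0, 2, size=(12, n_leaves)).astype(np.int8)
    X[0] = 0
    X[1] = 1
    M = pd.DataFrame(X, columns=tree.leaf_labels())
    model = GainLossModel(alpha=0.6, beta=1.3)
    post = posterior_presence(tree, M, model).to_numpy()
    expected = brute_force_posterior(tree, X, 0.6, 1.3)
    np.testing.assert_allclose(post, expected, atol=1e-9)


def test_two_leaf_root_posterior_closed_form():
    """Root posterior on a cherry equals the hand-computed Bayes ratio."""
    alpha, beta, t1, t2 = 0.7, 1.1, 0.4, 0.9
    tree = Phylogeny(np.array([-1, 0, 0]), np.array([0.0, t1, t2]), [None, "A", "B"])
    M = pd.DataFrame([[1, 1]], columns=["A", "B"])
    P1 = transition_matrices(np.array([t1]), alpha, beta)[0]
    P2 = transition_matrices(np.array([t2]), alpha, beta)[0]
    prior = np.array([beta, alpha]) / (alpha + beta)
    joint = prior * P1[:, 1] * P2[:, 1]  # both leaves present
    expected = joint[1] / joint.sum()
    post = posterior_presence(tree, M, GainLossModel(alpha, beta))
    assert post.iloc[0]["root"] == pytest.approx(expected, abs=1e-12)


def test_root_posterior_approaches_one_with_short_branches():
    tree = Phylogeny(np.array([-1, 0, 0]), np.array([0.0, 1e-6, 1e-6]), [None, "A", "B"])
    M = pd.DataFrame([[1, 1]], columns=["A", "B"])
    post = posterior_presence(tree, M, GainLossModel(0.5, 0.5))
    assert post.iloc[0]["root"] > 1 - 1e-5


def test_leaf_posteriors_pinned_to_observations(tiny_tree):
    M = pd.DataFrame([[1, 0, 1, 0]], columns=tiny_tree.leaf_labels())
    post = posterior_presence(tiny_tree, M, GainLossModel(0.5, 0.8))
    leaf_cols = tiny_tree.leaf_labels()
    np.testing.assert_array_equal(post[leaf_cols].to_numpy()[0], [1, 0, 1, 0])
    assert ((post.to_numpy() >= 0) & (post.to_numpy() <= 1)).all()


# ----------------------------------------------------------------------
# model fitting


def test_parameter_recovery_within_25_percent():
    """Rates recovered from 2000 families on 16 leaves simulated under the
    model itself."""
    tree = random_tree(16, 3)
    rng = np.random.default_rng(7)
    M = simulate_presence_under_model(tree, alpha=0.5, beta=1.0, n_families=2000, rng=rng)
    model = fit_model(tree, M)
    assert abs(model.alpha - 0.5) / 0.5 < 0.25
    assert abs(model.beta - 1.0) / 1.0 < 0.25


def test_symmetric_rates_recover_unit_ratio():
    tree = random_tree(16, 4)
    rng = np.random.default_rng(8)
    M = simulate_presence_under_model(tree, alpha=0.8, beta=0.8, n_families=2000, rng=rng)
    model = fit_model(tree, M)
    assert 0.8 < model.alpha / model.beta < 1.25


def test_fitted_likelihood_beats_grid_points():
    tree = random_tree(8, 5)
    rng = np.random.default_rng(9)
    M = simulate_presence_under_model(tree, alpha=0.6, beta=1.2, n_families=300, rng=rng)
    model = fit_model(tree, M)
    Mv = M[~np.all(M.to_numpy() == M.to_numpy()[:, :1], axis=1)]
    for a in (0.2, 0.6, 1.5):
        for b in (0.3, 1.2, 2.5):
            assert model.log_likelihood >= log_likelihood(tree, Mv, a, b) - 1e-6


def test_constant_matrix_raises():
    tree = random_tree(4, 6)
    M = pd.DataFrame(np.ones((5, 4), dtype=int), columns=tree.leaf_labels())
    with pytest.raises(DegenerateDataError):
        fit_model(tree, M)


# ----------------------------------------------------------------------
# event calling


@pytest.mark.parametrize(
    "pa,pd_,incl,high",
    [
        (0.1, 0.9, True, True),  # clear gain in both tiers
        (0.4, 0.6, True, False),  # inclusive only
        (0.5, 0.5, False, False),  # boundary: 0.5 counts as present
        (0.2, 0.8, True, True),  # high-tier thresholds are inclusive
    ],
)
def test_gain_thresholds(tiny_tree, pa, pd_, incl, high):
    post = pd.DataFrame(
        np.full((1, 7), pa), columns=["root"] + tiny_tree.branch_ids()
    )
    # put the transition on the first branch (root -> node 1)
    post.iloc[0, 1] = pd_
    for c in (2, 3, 4, 5):  # descendants of node 1 stay at the child level
        post.iloc[0, c] = pd_
    ev_i = call_events(post, tiny_tree, "inclusive")
    ev_h = call_events(post, tiny_tree, "high")
    assert bool(ev_i.gained[0, 0]) is incl
    assert bool(ev_h.gained[0, 0]) is high
    # high-confidence calls are a subset of inclusive calls
    assert not (ev_h.gained & ~ev_i.gained).any()


def test_gain_loss_mutually_exclusive_and_flip_consistent(study_run):
    ev = call_events(
        posterior_presence(study_run.ds.tree, study_run.ds.presence, study_run.res.model),
        study_run.ds.tree,
        "inclusive",
    )
    assert not (ev.gained & ev.lost).any()
    # total gains equal the number of 0->1 flips of the thresholded states
    post = posterior_presence(study_run.ds.tree, study_run.ds.presence, study_run.res.model)
    S = (post.to_numpy() >= 0.5)
    tree = study_run.ds.tree
    child = tree.branch_child_nodes()
    flips = (~S[:, tree.parent[child]] & S[:, child]).sum()
    assert ev.gained.sum() == flips


def fitch_gains(tree, X):
    """Parsimony oracle: Fitch sets upward, arbitrary-but-fixed resolution
    downward; returns boolean gains (families x branches)."""
    leaves = list(tree.leaf_indices())
    F = X.shape[0]
    gains = np.zeros((F, tree.n_branches), dtype=bool)
    for f in range(F):
        sets = [None] * tree.n_nodes
        for k, nd in enumerate(leaves):
            sets[nd] = {int(X[f, k])}
        for nd in tree.postorder():
            if tree.children[nd]:
                a, b = (sets[c] for c in tree.children[nd])
                sets[nd] = (a & b) or (a | b)
        state = np.zeros(tree.n_nodes, dtype=int)
        state[0] = min(sets[0])  # resolve root ties toward absent
        for nd in tree.preorder()[1:]:
            p = state[tree.parent[nd]]
            state[nd] = p if p in sets[nd] else min(sets[nd])
        child = tree.branch_child_nodes()
        gains[f] = (state[tree.parent[child]] == 0) & (state[child] == 1)
    return gains


def test_inclusive_calls_agree_with_fitch_at_low_rates():
    tree = random_tree(16, 10)
    rng = np.random.default_rng(11)
    M = simulate_presence_under_model(tree, alpha=0.08, beta=0.12, n_families=400, rng=rng)
    model = fit_model(tree, M)
    post = posterior_presence(tree, M, model)
    ev = call_events(post, tree, "inclusive")
    gains_fitch = fitch_gains(tree, M.to_numpy())
    agreement = (ev.gained == gains_fitch).mean()
    assert agreement >= 0.90
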