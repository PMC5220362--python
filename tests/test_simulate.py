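import filecmp
import logging

import numpy as np
import pytest

from cotransfer import profiles as prof
from cotransfer.simulate import (
    ConfigurationError,
    SimulationConfig,
    evolve_genomes,
    genome_to_table,
    simulate_dataset,
    simulate_panel_profiles,
    simulate_root_genome,
    simulate_tree,
)


def small_config(**kw):
    base = dict(
        n_leaves=6, genome_length=400_000, n_families=300, n_clusters=20,
        cluster_size_range=(3, 5), n_panel_species=60, seed=11,
    )
    base.update(kw)
    return SimulationConfig(**base)


# ----------------------------------------------------------------------
# configuration invariants


def test_config_validation():
    with pytest.raises(ConfigurationError):
        SimulationConfig(n_leaves=3)
    with pytest.raises(ConfigurationError):
        SimulationConfig(segment_cap=50_000, phage_segment_cap=12_000)
    with pytest.raises(ConfigurationError):
        SimulationConfig(phage_segment_cap=1_500_000)  # > genome_length / 2
    with pytest.raises(ConfigurationError):
        SimulationConfig(gain_rate=-1)


def test_root_genome_overflow_rejected():
    with pytest.raises(ConfigurationError):
        cfg = small_config(genome_length=40_000)  # genes alone exceed this
        simulate_root_genome(cfg)


# ----------------------------------------------------------------------
# root genome structure


def test_no_clusters_means_all_singletons():
    cfg = small_config(n_clusters=0)
    universe, root, truth = simulate_root_genome(cfg)
    assert truth.true_cluster_membership == {}
    assert truth.true_intra_cluster_distance_samples == []
    assert len(root.order) == cfg.n_families


def test_intra_cluster_distance_sample_counts():
    cfg = small_config()
    universe, root, truth = simulate_root_genome(cfg)
    expected = sum(
        len(m) * (len(m) - 1) // 2 for m in universe.cluster_members
    )
    assert len(truth.true_intra_cluster_distance_samples) == expected
    assert max(truth.true_intra_cluster_distance_samples) <= cfg.cluster_span_bound()


def test_cluster_members_contiguous_at_root():
    cfg = small_config()
    universe, root, truth = simulate_root_genome(cfg)
    order = root.order
    for members in universe.cluster_members:
        idx = sorted(order.index(f) for f in members)
        assert idx == list(range(idx[0], idx[0] + len(members)))


def test_every_cluster_shares_go_terms():
    cfg = small_config(go_missing_fraction=0.0)
    universe, _, _ = simulate_root_genome(cfg)
    for c, members in enumerate(universe.cluster_members):
        shared = set.intersection(*(universe.go_map[f] for f in members))
        assert len(shared) >= cfg.go_terms_per_cluster


# ----------------------------------------------------------------------
# evolution


def test_zero_rates_leave_genomes_identical_to_root():
    cfg = small_config(gain_rate=0.0, loss_rate=0.0)
    tree = simulate_tree(cfg)
    universe, root, truth = simulate_root_genome(cfg)
    presence, leaf_genomes, lengths, truth = evolve_genomes(
        tree, universe, root, cfg, truth
    )
    assert (presence.to_numpy() == 1).all()
    for g in leaf_genomes.values():
        assert g.order == root.order
    assert truth.true_event_log == []


def test_segment_caps_respected_in_event_log():
    ds = simulate_dataset(small_config())
    for branch, fams, phage, length in ds.truth.true_event_log:
        cap = ds.config.phage_segment_cap if phage else ds.config.segment_cap
        assert length <= cap
    nonphage = [e for e in ds.truth.true_event_log if not e[2]]
    assert nonphage, "expected at least one ordinary acquisition"


def test_all_phage_events_interleave_phage_genes(caplog):
    cfg = small_config(phage_event_fraction=1.0)
    with caplog.at_level(logging.WARNING):
        ds = simulate_dataset(cfg)
    assert ds.truth.true_event_log, "some phage-mediated events must succeed"
    for branch, fams, phage, length in ds.truth.true_event_log:
        assert phage
        assert any(f in ds.universe.phage for f in fams)
        if len(fams) >= 3:
            # phage genes sit between cargo genes, not only at the edges
            inner = fams[1:-1]
            assert any(f in ds.universe.phage for f in inner) or len(
                [f for f in fams if f in ds.universe.phage]
            ) >= len(fams) - 2


def test_cotransfer_pairs_come_from_events():
    ds = simulate_dataset(small_config())
    from_log = set()
    for _, fams, _, _ in ds.truth.true_event_log:
        for i in range(len(fams)):
            for j in range(i + 1, len(fams)):
                from_log.add(frozenset((fams[i], fams[j])))
    assert ds.truth.true_cotransfer_pairs == from_log
    assert len(ds.truth.true_cotransfer_pairs) > 0


def test_presence_matrix_consistent_with_leaf_tables():
    ds = simulate_dataset(small_config())
    for gid in ds.presence.columns:
        fams_in_table = set(ds.genes[ds.genes.genome_id == gid]["family_id"])
        fams_in_matrix = set(ds.presence.index[ds.presence[gid] == 1])
        assert fams_in_table == fams_in_matrix


def test_leaf_coordinates_valid_on_circle():
    ds = simulate_dataset(small_config())
    for gid, sub in ds.genes.groupby("genome_id"):
        L = ds.genome_lengths[gid]
        assert (sub["start"] >= 0).all() and (sub["start"] < L).all()
        assert (sub["end"] > sub["start"]).all()
        assert ((sub["end"] - sub["start"]) < L).all()


def test_core_families_never_lost():
    ds = simulate_dataset(small_config())
    core = sorted(ds.universe.core)
    assert (ds.presence.loc[core].to_numpy() == 1).all()


def test_dataset_determinism_byte_identical(tmp_path):
    cfg = small_config()
    d1, d2 = tmp_path / "a", tmp_path / "b"
    simulate_dataset(cfg).write(d1)
    simulate_dataset(cfg).write(d2)
    names = [p.name for p in d1.iterdir()]
    match, mismatch, errors = filecmp.cmpfiles(d1, d2, names, shallow=False)
    assert not mismatch and not errors


# ----------------------------------------------------------------------
# panel profiles


def test_panel_profile_shape_and_order():
    cfg = small_config()
    universe, _, _ = simulate_root_genome(cfg)
    profs = simulate_panel_profiles(universe, cfg)
    assert profs.shape == (cfg.n_families, cfg.n_panel_species)
    assert list(profs.index) == universe.ids
    assert set(np.unique(profs.to_numpy())) <= {0, 1}


def test_noise_free_same_operon_profiles_identical():
    cfg = small_config(panel_flip_noise=0.0, operon_panel_prob=1.0)
    universe, _, _ = simulate_root_genome(cfg)
    profs = simulate_panel_profiles(universe, cfg)
    for members in universe.cluster_members[:5]:
        base = profs.loc[members[0]].to_numpy()
        for f in members[1:]:
            np.testing.assert_array_equal(profs.loc[f].to_numpy(), base)
        if 0 < base.mean() < 1:
            mi = prof.mutual_information(base, profs.loc[members[1]].to_numpy())
            h = prof.pattern_counts(base, base).H_A
            assert mi == pytest.approx(h)  # maximal: equals marginal entropy


def test_cross_cluster_mi_near_zero():
    cfg = small_config(n_panel_species=200)
    universe, _, _ = simulate_root_genome(cfg)
    profs = simulate_panel_profiles(universe, cfg)
    rng = np.random.default_rng(3)
    vals = []
    for _ in range(150):
        c1, c2 = rng.choice(len(universe.cluster_members), 2, replace=False)
        a = universe.cluster_members[c1][0]
        b = universe.cluster_members[c2][0]
        vals.append(prof.mutual_information(profs.loc[a], profs.loc[b]))
    # Monte-Carlo mean stays near the plug-in bias floor ~1/(2 N ln 2)
    assert np.mean(vals) < 5 / (2 * cfg.n_panel_species * np.log(2))
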