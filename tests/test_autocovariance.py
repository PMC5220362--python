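import numpy as np
import pandas as pd
import pytest

from cotransfer import annotation as ann
from cotransfer import autocovariance as ac
from cotransfer import profiles as prof
from cotransfer.distances import DistanceDistribution


def make_genes(spec, genome_id="g1"):
    """spec: list of (family, start, end[, mobile])."""
    rows = []
    for item in spec:
        fam, s, e = item[:3]
        rows.append(
            {"family_id": fam, "genome_id": genome_id, "start": s, "end": e,
             "strand": "+", "product_text": "",
             "mobile_element": int(item[3]) if len(item) > 3 else 0}
        )
    return pd.DataFrame(rows)


def brute_force_ac(genes, pairs, eligible, L, x_max):
    """Site-by-site enumeration of G(x) at 1 bp resolution."""
    site_gene = np.full(L, -1)
    fams = list(genes["family_id"])
    for gi, row in genes.reset_index(drop=True).iterrows():
        for pos in range(int(row.start), int(row.end)):
            site_gene[pos % L] = gi
    elig_sites = [
        i for i in range(L)
        if site_gene[i] >= 0 and fams[site_gene[i]] in eligible
    ]
    n = len(elig_sites)
    xs = np.arange(1, x_max + 1)
    G = np.zeros(len(xs))
    for k, x in enumerate(xs):
        hits = 0
        for i in elig_sites:
            j = (i + x) % L
            gj = site_gene[j]
            if gj >= 0 and gj != site_gene[i]:
                if frozenset((fams[site_gene[i]], fams[gj])) in pairs:
                    hits += 1
        G[k] = hits / n
    return xs, G


def test_compute_ac_matches_site_enumeration_exactly():
    """frame=1 autocovariance equals brute-force enumeration on a toy genome."""
    L = 6_000
    genes = make_genes([("A", 0, 500), ("B", 700, 1_200), ("C", 3_000, 3_500)])
    pairs = {frozenset(("A", "B")), frozenset(("A", "C"))}
    eligible = {"A", "B", "C"}
    curve = ac.compute_ac(genes, pairs, eligible, L, frame=1, x_max=2_500)
    xs, G = brute_force_ac(genes, pairs, eligible, L, 2_500)
    np.testing.assert_array_equal(curve.x, xs)
    np.testing.assert_allclose(curve.G, G, atol=1e-12)


def test_adjacent_gene_pair_support():
    """Two adjacent 1 kb qualifying genes: G(x) > 0 exactly for cross-gene
    offsets, i.e. x in (0, 2 kb)."""
    L = 20_000
    genes = make_genes([("A", 0, 1_000), ("B", 1_000, 2_000)])
    curve = ac.compute_ac(genes, {frozenset(("A", "B"))}, {"A", "B"}, L,
                          frame=1, x_max=3_000)
    pos = curve.x[curve.G > 0]
    assert pos.min() == 1
    assert pos.max() == 1_999
    assert (curve.G[curve.x >= 2_000] == 0).all()


def test_frame_10_agrees_with_frame_1_up_to_discretization():
    L = 8_000
    genes = make_genes([("A", 100, 900), ("B", 1_200, 2_100), ("C", 4_000, 4_700)])
    pairs = {frozenset(("A", "B")), frozenset(("B", "C"))}
    c1 = ac.compute_ac(genes, pairs, {"A", "B", "C"}, L, frame=1, x_max=3_000)
    c10 = ac.compute_ac(genes, pairs, {"A", "B", "C"}, L, frame=10, x_max=3_000)
    # compare on the common lattice: averages agree within discretization
    g1_on_10 = c1.G[9::10][: len(c10.G)]
    assert np.abs(g1_on_10 - c10.G).mean() < 0.02


def test_no_qualifying_pairs_gives_zero_curve():
    genes = make_genes([("A", 0, 500), ("B", 1_000, 1_500)])
    curve = ac.compute_ac(genes, set(), {"A", "B"}, 10_000, frame=10, x_max=2_000)
    assert (curve.G == 0).all()
    with pytest.raises(ac.DegenerateCurveError):
        _ = curve.G_tilde


# ----------------------------------------------------------------------
# pair qualification


@pytest.fixture
def qual_setup():
    genes = make_genes(
        [("A", 0, 500), ("B", 700, 1_200), ("C", 2_000, 2_500), ("P", 3_000, 3_500),
         ("M", 4_000, 4_500, 1)]
    )
    status = pd.Series({f: ann.NOT_ASSOCIATED for f in "ABCM"} | {"P": ann.ASSOCIATED})
    go_map = {"A": {"GO:1", "GO:2"}, "B": {"GO:1", "GO:2"}, "C": {"GO:2"},
              "P": {"GO:1"}, "M": {"GO:1"}}
    return genes, status, go_map


def test_qualify_go_mode(qual_setup):
    genes, status, go_map = qual_setup
    pairs, elig = ac.qualify_pairs(
        genes, ac.PairQualifier("GO", n_go=1), status, go_map=go_map
    )
    assert frozenset(("A", "B")) in pairs
    assert frozenset(("A", "C")) in pairs  # one shared term qualifies at n_go=1
    # phage-associated and mobile-element genes are excluded regardless
    assert all("P" not in p and "M" not in p for p in pairs)
    assert "P" not in elig and "M" not in elig
    pairs2, _ = ac.qualify_pairs(
        genes, ac.PairQualifier("GO", n_go=2), status, go_map=go_map
    )
    assert pairs2 == {frozenset(("A", "B"))}  # tighter cutoff drops single-term pairs


def test_qualify_co_mode_threshold(qual_setup):
    genes, status, _ = qual_setup
    mi = pd.DataFrame(0.5, index=list("ABCPM"), columns=list("ABCPM"))
    mi.loc["A", "C"] = mi.loc["C", "A"] = 0.05
    pairs, _ = ac.qualify_pairs(
        genes, ac.PairQualifier("CO", mi_cutoff=0.8), status, mi=mi
    )
    assert pairs == set()  # MI 0.5 < cutoff 0.8
    pairs, _ = ac.qualify_pairs(
        genes, ac.PairQualifier("CO", mi_cutoff=0.2), status, mi=mi
    )
    assert frozenset(("A", "B")) in pairs
    assert frozenset(("A", "C")) not in pairs


def test_qualify_operon_restricted(qual_setup):
    genes, status, go_map = qual_setup
    pairs, _ = ac.qualify_pairs(
        genes, ac.PairQualifier("GO", n_go=1, operon_restricted=True), status,
        go_map=go_map, operons=[["A", "B"]],
    )
    assert pairs == {frozenset(("A", "B"))}


# ----------------------------------------------------------------------
# rescaling / binning


def planted_cluster_genome(rng, n_pairs=120, gene_len=100, d_max=2_000, L=1_000_000):
    spec = []
    pairs = set()
    pos = 0
    for k in range(n_pairs):
        gap = float(rng.uniform(1, d_max))
        a, b = f"a{k}", f"b{k}"
        spec.append((a, pos, pos + gene_len))
        spec.append((b, pos + gene_len + gap, pos + 2 * gene_len + gap))
        pairs.add(frozenset((a, b)))
        pos += int(8_000 + rng.uniform(0, 2_000))
    genes = make_genes(spec)
    return genes, pairs, {f for p in pairs for f in p}, L


def test_rescaled_curve_peaks_at_one():
    rng = np.random.default_rng(0)
    genes, pairs, elig, L = planted_cluster_genome(rng)
    curve = ac.compute_ac(genes, pairs, elig, L, frame=10, x_max=10_000)
    assert curve.G_tilde.max() == pytest.approx(1.0)
    soc = ac.rescale_and_bin(curve)
    assert soc.mass.sum() == pytest.approx(1.0)
    assert (np.diff(soc.cum) >= -1e-12).all()


def test_planted_cluster_support_recovered_within_one_bin():
    """Pairs at boundary gaps uniform on (0, d_max]: the recovered
    distribution's upper edge sits within one log-bin of the maximum
    site-to-site distance."""
    rng = np.random.default_rng(1)
    genes, pairs, elig, L = planted_cluster_genome(rng, d_max=2_000, gene_len=100)
    true_max_site_distance = 2_000 + 2 * 100  # gap + both gene bodies
    curve = ac.compute_ac(genes, pairs, elig, L, frame=10, x_max=10_000)
    soc = ac.rescale_and_bin(curve, bins_per_decade=25)
    edge = soc.support_max
    bin_width_ratio = 10 ** (1 / 25)
    assert edge <= true_max_site_distance * bin_width_ratio**2
    assert edge >= true_max_site_distance / bin_width_ratio**2


def test_compare_distributions_extremes():
    a = DistanceDistribution(np.array([1.0, 2.0, 3.0]))
    same = ac.compare_distributions(a, DistanceDistribution(np.array([1.0, 2.0, 3.0])))
    assert same["ks"] == 0.0
    disjoint = ac.compare_distributions(
        a, DistanceDistribution(np.array([10.0, 20.0]))
    )
    assert disjoint["ks"] == 1.0


def test_operon_distance_distribution_counts():
    genes = make_genes(
        [("A", 0, 1_000), ("B", 1_100, 2_100), ("C", 2_200, 3_200)]
    )
    ops = {"g1": [["A", "B"]]}
    d = ac.operon_distance_distribution(ops, genes, {"g1": 100_000})
    assert list(d.values) == [100.0]  # boundary-gap convention
    ops3 = {"g1": [["A", "B", "C"]]}
    d3 = ac.operon_distance_distribution(ops3, genes, {"g1": 100_000})
    assert len(d3) == 3  # k(k-1)/2


def test_operon_restricted_goac_approximates_operon_distances():
    """Validation genome: operons whose pair distances dominate gene length;
    the operon-restricted GO-AC estimate matches the direct within-operon
    distance distribution (KS < 0.15)."""
    rng = np.random.default_rng(2)
    spec, operons, go_map = [], [], {}
    pos = 0
    for k in range(150):
        fams = [f"o{k}a", f"o{k}b"]
        gap = float(rng.uniform(500, 4_000))
        spec.append((fams[0], pos, pos + 80))
        spec.append((fams[1], pos + 80 + gap, pos + 160 + gap))
        operons.append(fams)
        term = {f"GO:OP{k}"}
        for f in fams:
            go_map[f] = term
        pos += int(12_000 + rng.uniform(0, 3_000))
    L = 2_200_000
    genes = make_genes(spec)
    status = pd.Series({f: ann.NOT_ASSOCIATED for f in go_map})
    pairs, elig = ac.qualify_pairs(
        genes, ac.PairQualifier("GO", n_go=1, operon_restricted=True), status,
        go_map=go_map, operons=operons,
    )
    curve = ac.compute_ac(genes, pairs, elig, L, frame=10, x_max=12_000)
    soc = ac.rescale_and_bin(curve)
    direct = ac.operon_distance_distribution({"g1": operons}, genes, {"g1": L})
    ks = ac.compare_distributions(soc, direct)["ks"]
    assert ks < 0.15


# ----------------------------------------------------------------------
# study-condition behaviour


def test_tightening_cutoffs_shifts_mass_left(study_run):
    soc = study_run.res.soc
    assert soc[("GO", 5)].median <= soc[("GO", 1)].median
    assert soc[("CO", 0.8)].median <= soc[("CO", 0.0001)].median


def test_co_and_go_estimates_agree_on_planted_clusters(study_run):
    """With the CO cutoff above the plug-in MI bias floor, co-occurrence and
    co-function qualify the same (same-cluster) pairs and the two SOC
    estimates coincide (KS < 0.1)."""
    b = study_run.ds
    from cotransfer.io import bundle_from_dataset

    bundle = bundle_from_dataset(b)
    status = study_run.res.phage_status
    mi = prof.mi_matrix(bundle.profiles)
    gids = sorted(bundle.genome_lengths)[:5]
    dists = {}
    for mode, kw in (("CO", {"mi_cutoff": 0.01}), ("GO", {"n_go": 1})):
        curves = []
        for gid in gids:
            sub = bundle.genes[bundle.genes.genome_id == gid]
            prs, elig = ac.qualify_pairs(
                sub, ac.PairQualifier(mode, **kw), status,
                mi=mi if mode == "CO" else None,
                go_map=bundle.go_map if mode == "GO" else None,
            )
            curves.append(
                ac.compute_ac(sub, prs, elig, bundle.genome_lengths[gid],
                              frame=10, x_max=30_000)
            )
        G = np.mean([c.G for c in curves], axis=0)
        dists[mode] = ac.rescale_and_bin(
            ac.AcCurve(x=curves[0].x, G=G, n_sites=1, frame=10)
        )
    ks = ac.compare_distributions(dists["CO"], dists["GO"])["ks"]
    assert ks < 0.1
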