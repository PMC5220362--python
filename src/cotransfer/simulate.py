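"""Ground-truthed forward simulator of segmental gene co-transfer.

The generator produces every input the analysis chain consumes — a rooted
bifurcating tree, per-leaf gene coordinate tables on circular chromosomes, a
binary presence/absence matrix, GO annotations, operon membership, and a
cross-species co-occurrence panel — together with the ground truth needed to
score the inference (which pairs actually rode one transferred segment, the
event log, cluster membership, and the intra-cluster distance distribution).

Model of genome evolution
-------------------------
The root genome carries all ``n_families`` gene loci arranged on a circle:
``n_clusters`` supra-operonic clusters (contiguous runs of co-functioning
genes with sampled intra-cluster gaps, each cluster split into 1-3 gene
operons and sharing cluster- and operon-level GO terms) plus singleton
families, a fraction of which are phage genes. Along each branch:

* deletion events remove contiguous runs of genes (bacterial deletions are
  segmental; the configured ``loss_rate`` is the marginal per-gene loss rate
  per unit branch length);
* acquisition events (Poisson with rate ``gain_rate`` per unit branch
  length) insert a contiguous donor segment drawn from the local pan-genome
  — the families currently absent from the lineage — respecting cluster
  adjacency. Ordinary segments are capped at ``segment_cap`` bp (the "30 kb"
  analog); with probability ``phage_event_fraction`` an acquisition is
  phage-mediated: phage-flagged genes are interleaved between the cargo
  genes and the segment may extend to ``phage_segment_cap`` bp (the "70 kb"
  analog), mimicking co-transfer of host DNA with an imprecisely excised
  prophage.

Insertion sites are uniform on the circle and never split a gene. No
nucleotide sequence is simulated; only gene content and coordinates.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .phylo import Phylogeny

logger = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic co-transfer dataset.

    Defaults define a desk-scale analog of a 53-strain bacterial panel:
    16 genomes, a 2 Mb circular chromosome, 1500 gene families in 80
    clusters, a 5 kb cap on ordinary transferred segments and a 12 kb cap on
    phage-mediated ones (scaled stand-ins for the 30 kb / 70 kb bounds).
    """

    n_leaves: int = 16
    tree_depth: float = 1.0  # expected root-to-tip branch-length sum
    genome_length: int = 2_000_000
    n_families: int = 1500
    n_clusters: int = 70
    cluster_size_range: tuple = (5, 8)
    intra_cluster_gap: tuple = (100.0, 400.0)  # within-operon: exp mean, truncation
    inter_operon_gap: tuple = (800.0, 2000.0)  # between operons of one cluster
    gain_rate: float = 140.0  # acquisition events per unit branch length
    loss_rate: float = 2.5  # per accessory gene loss rate per unit branch length
    segment_cap: int = 5_000
    phage_segment_cap: int = 12_000
    phage_event_fraction: float = 0.15
    go_terms_per_cluster: int = 2
    n_panel_species: int = 233
    seed: int = 0
    # generator internals
    gene_length_median: float = 300.0
    gene_length_sigma: float = 0.25
    gene_length_max: float = 900.0
    gene_length_min: float = 100.0
    phage_family_fraction: float = 0.15  # of singleton families
    core_fraction: float = 0.75  # of non-phage singletons: never lost
    cluster_seed_bias: float = 0.65  # P(acquisition seeds in a clustered family)
    mobile_element_fraction: float = 0.02
    go_missing_fraction: float = 0.15
    operon_size_range: tuple = (1, 3)
    go_terms_per_operon: int = 4
    background_go_pool: int = 200
    loss_run_mean: float = 3.0  # mean genes per deletion event
    filler_gap: float = 100.0  # bp between interleaved phage genes
    cluster_panel_prob: float = 0.5
    operon_panel_prob: float = 0.85
    singleton_panel_prob: float = 0.5
    panel_flip_noise: float = 0.01

    def __post_init__(self) -> None:
        for f in (
            "cluster_size_range", "intra_cluster_gap", "inter_operon_gap",
            "operon_size_range",
        ):
            setattr(self, f, tuple(getattr(self, f)))
        if self.n_leaves < 4:
            raise ConfigurationError("n_leaves must be >= 4")
        if not (self.segment_cap < self.phage_segment_cap < self.genome_length / 2):
            raise ConfigurationError(
                "need segment_cap < phage_segment_cap < genome_length/2"
            )
        if self.gain_rate < 0 or self.loss_rate < 0:
            raise ConfigurationError("rates must be >= 0")
        lo, hi = self.cluster_size_range
        if not (1 <= lo <= hi):
            raise ConfigurationError("invalid cluster_size_range")
        if not 0 <= self.phage_event_fraction <= 1:
            raise ConfigurationError("phage_event_fraction must be in [0,1]")

    def cluster_span_bound(self) -> float:
        """Upper bound on any intra-cluster nearest-boundary distance."""
        kmax = self.cluster_size_range[1]
        gap_max = max(self.intra_cluster_gap[1], self.inter_operon_gap[1])
        return (kmax - 2) * self.gene_length_max + (kmax - 1) * gap_max


@dataclass
class GroundTruth:
    """What actually happened in the simulation."""

    true_cotransfer_pairs: set = field(default_factory=set)  # frozenset pairs
    true_event_log: list = field(default_factory=list)
    true_cluster_membership: dict = field(default_factory=dict)
    true_intra_cluster_distance_samples: list = field(default_factory=list)

    def is_true_pair(self, a: str, b: str) -> bool:
        """True co-transfer pair or same-cluster pair (co-organised genes
        repeatedly co-gained through overlapping segment events)."""
        if frozenset((a, b)) in self.true_cotransfer_pairs:
            return True
        ca = self.true_cluster_membership.get(a)
        return ca is not None and ca == self.true_cluster_membership.get(b)

    def to_json(self) -> str:
        return json.dumps(
            {
                "true_cotransfer_pairs": sorted(sorted(p) for p in self.true_cotransfer_pairs),
                "true_event_log": [
                    {"branch": br, "families": list(fams), "phage": ph, "length_bp": ln}
                    for br, fams, ph, ln in self.true_event_log
                ],
                "true_cluster_membership": self.true_cluster_membership,
                "true_intra_cluster_distance_samples": self.true_intra_cluster_distance_samples,
            },
            indent=1,
        )


# ----------------------------------------------------------------------
# tree simulation


def simulate_tree(config: SimulationConfig) -> Phylogeny:
    """Random rooted bifurcating tree with exponential branch lengths,
    rescaled so the mean root-to-tip branch-length sum equals
    ``tree_depth``."""
    rng = np.random.default_rng(config.seed)
    n = config.n_leaves
    # random coalescent-style topology: join random pairs of subtrees
    nodes = [{"children": [], "label": f"G{i:02d}"} for i in range(n)]
    roots = list(range(n))
    while len(roots) > 1:
        i, j = rng.choice(len(roots), size=2, replace=False)
        a, b = roots[i], roots[j]
        nodes.append({"children": [a, b], "label": None})
        roots = [r for k, r in enumerate(roots) if k not in (i, j)] + [len(nodes) - 1]
    root = roots[0]

    # preorder numbering
    parent, blen, labels, order = [], [], [], []

    def visit(nd: int, par_idx: int) -> None:
        idx = len(order)
        order.append(nd)
        parent.append(par_idx)
        labels.append(nodes[nd]["label"])
        blen.append(0.0 if par_idx < 0 else max(rng.exponential(1.0), 1e-3))
        for c in nodes[nd]["children"]:
            visit(c, idx)

    visit(root, -1)
    tree = Phylogeny(np.array(parent), np.array(blen) + 1e-12, labels)
    # rescale to the requested expected depth
    depth = np.zeros(tree.n_nodes)
    for i in range(1, tree.n_nodes):
        depth[i] = depth[tree.parent[i]] + tree.blen[i]
    mean_tip_depth = depth[tree.leaf_indices()].mean()
    scale = config.tree_depth / mean_tip_depth
    return Phylogeny(tree.parent, np.maximum(tree.blen * scale, 1e-9), labels)


# ----------------------------------------------------------------------
# root genome


@dataclass
class FamilyUniverse:
    """Canonical per-family attributes shared by all genomes."""

    ids: list
    lengths: np.ndarray
    cluster_of: dict  # family -> cluster id (clustered families only)
    cluster_members: list  # cluster id -> ordered family list
    cluster_gaps: list  # cluster id -> canonical gaps between neighbours
    phage: set
    core: set  # essential families: never deleted, never absent
    mobile: set
    products: dict
    go_map: dict  # after withholding
    operons_of_cluster: list  # cluster id -> list of ordered family lists

    def length_of(self, fam: str) -> float:
        return float(self.lengths[self.index[fam]])

    def __post_init__(self) -> None:
        self.index = {f: i for i, f in enumerate(self.ids)}


@dataclass
class Genome:
    """Ordered circular arrangement: gene i is followed by gap_after[i]."""

    order: list  # family ids, circular order
    gap_after: list  # bp gap following each gene

    def copy(self) -> "Genome":
        return Genome(list(self.order), list(self.gap_after))

    def total_length(self, universe: FamilyUniverse) -> float:
        return float(
            sum(universe.length_of(f) for f in self.order) + sum(self.gap_after)
        )


def simulate_root_genome(config: SimulationConfig):
    """Build the family universe, the root genome and the partial truth.

    Returns ``(universe, root_genome, truth)`` where truth already carries
    cluster membership and the canonical intra-cluster distance samples.
    """
    rng = np.random.default_rng(config.seed + 1)
    n_fam = config.n_families
    ids = [f"fam{i:04d}" for i in range(n_fam)]
    lengths = np.clip(
        rng.lognormal(np.log(config.gene_length_median), config.gene_length_sigma, n_fam),
        config.gene_length_min,
        config.gene_length_max,
    ).round()

    # assign clusters
    lo, hi = config.cluster_size_range
    cluster_members, cluster_gaps, operons_of_cluster = [], [], []
    cluster_of: dict = {}
    cursor = 0
    for c in range(config.n_clusters):
        k = int(rng.integers(lo, hi + 1))
        if cursor + k > n_fam:
            raise ConfigurationError("not enough families for the requested clusters")
        members = ids[cursor : cursor + k]
        cursor += k
        cluster_members.append(members)
        for f in members:
            cluster_of[f] = c
        # split the cluster into operons of consecutive genes
        ops, i = [], 0
        while i < k:
            olen = int(rng.integers(config.operon_size_range[0], config.operon_size_range[1] + 1))
            ops.append(members[i : i + olen])
            i += olen
        operons_of_cluster.append(ops)
        # tight gaps within an operon, wide gaps between operons
        operon_of = {f: j for j, op in enumerate(ops) for f in op}
        gaps = []
        for j in range(k - 1):
            same_operon = operon_of[members[j]] == operon_of[members[j + 1]]
            mean, cap = (
                config.intra_cluster_gap if same_operon else config.inter_operon_gap
            )
            gaps.append(float(np.minimum(rng.exponential(mean), cap).round()))
        cluster_gaps.append(gaps)
    singletons = ids[cursor:]

    # phage pool, essential core and mobile elements among singletons
    n_phage = int(round(config.phage_family_fraction * len(singletons)))
    phage = set(rng.choice(singletons, size=n_phage, replace=False)) if n_phage else set()
    non_phage_singletons = [f for f in singletons if f not in phage]
    n_core = int(round(config.core_fraction * len(non_phage_singletons)))
    core = (
        set(rng.choice(non_phage_singletons, size=n_core, replace=False)) if n_core else set()
    )
    mob_pool = [f for f in non_phage_singletons if f not in core]
    n_mob = int(round(config.mobile_element_fraction * len(non_phage_singletons)))
    n_mob = min(n_mob, len(mob_pool))
    mobile = set(rng.choice(mob_pool, size=n_mob, replace=False)) if n_mob else set()

    products = {}
    for f in ids:
        if f in phage:
            products[f] = f"putative phage protein {f}"
        elif f in cluster_of:
            products[f] = f"cluster enzyme {f}"
        else:
            products[f] = f"hypothetical protein {f}"

    # GO terms: cluster-level, operon-level, background; withhold a fraction
    phage_go = ["GO:PHAGE_CAPSID", "GO:PHAGE_TAIL", "GO:PHAGE_INTEGRATION"]
    go_map: dict = {f: set() for f in ids}
    for c, members in enumerate(cluster_members):
        terms = {f"GO:CLST{c:03d}_{j}" for j in range(config.go_terms_per_cluster)}
        for f in members:
            go_map[f] |= terms
        for o, op in enumerate(operons_of_cluster[c]):
            oterms = {f"GO:OP{c:03d}_{o}_{j}" for j in range(config.go_terms_per_operon)}
            for f in op:
                go_map[f] |= oterms
    bg_pool = [f"GO:BG{j:03d}" for j in range(config.background_go_pool)]
    for f in ids:
        for term in rng.choice(bg_pool, size=int(rng.integers(0, 3)), replace=False):
            go_map[f].add(term)
    for f in phage:
        if rng.random() < 0.5:
            go_map[f].add(str(rng.choice(phage_go)))
    withheld = rng.random(n_fam) < config.go_missing_fraction
    for f, w in zip(ids, withheld):
        if w and f not in phage:
            go_map[f] = set()

    universe = FamilyUniverse(
        ids=ids,
        lengths=lengths,
        cluster_of=cluster_of,
        cluster_members=cluster_members,
        cluster_gaps=cluster_gaps,
        phage=phage,
        core=core,
        mobile=mobile,
        products=products,
        go_map=go_map,
        operons_of_cluster=operons_of_cluster,
    )

    # lay the blocks (clusters + singletons) around the circle
    blocks = [("cluster", c) for c in range(config.n_clusters)] + [
        ("single", f) for f in singletons
    ]
    perm = rng.permutation(len(blocks))
    order, gap_flags = [], []  # gap_flags marks canonical intra-cluster gaps
    intra_gaps_total = 0.0
    for bi in perm:
        kind, val = blocks[bi]
        if kind == "cluster":
            members = cluster_members[val]
            for j, f in enumerate(members):
                order.append(f)
                if j < len(members) - 1:
                    gap_flags.append(cluster_gaps[val][j])
                    intra_gaps_total += cluster_gaps[val][j]
                else:
                    gap_flags.append(None)
        else:
            order.append(val)
            gap_flags.append(None)
    gene_total = float(lengths.sum())
    free = config.genome_length - gene_total - intra_gaps_total
    n_free = sum(1 for g in gap_flags if g is None)
    if free < n_free:  # want at least ~1 bp per inter-block gap
        raise ConfigurationError(
            "total gene + intra-cluster gap length exceeds genome_length"
        )
    w = rng.dirichlet(np.ones(n_free)) * free
    it = iter(w.round())
    gap_after = [g if g is not None else float(next(it)) for g in gap_flags]

    truth = GroundTruth(true_cluster_membership=dict(cluster_of))
    for c, members in enumerate(cluster_members):
        k = len(members)
        lens = [universe.length_of(f) for f in members]
        gaps = cluster_gaps[c]
        for i in range(k):
            for j in range(i + 1, k):
                d = sum(lens[i + 1 : j]) + sum(gaps[i:j])
                truth.true_intra_cluster_distance_samples.append(float(d))
    return universe, Genome(order, gap_after), truth


# ----------------------------------------------------------------------
# evolution along the tree


def _delete_runs(
    genome: Genome, n_events: int, run_mean: float, universe: "FamilyUniverse", rng
) -> None:
    """Remove ``n_events`` contiguous runs of accessory genes (segmental
    deletions). A run never removes an essential (core) gene — such a
    deletion is lethal and never observed — and stays within one functional
    block: contiguous genes of one cluster (accessory islands are deleted
    wholesale) or a single singleton gene."""
    core = universe.core
    for _ in range(n_events):
        n = len(genome.order)
        if n <= 2:
            break
        acc = [i for i, f in enumerate(genome.order) if f not in core]
        if not acc:
            break
        start = int(rng.choice(acc))
        start_cluster = universe.cluster_of.get(genome.order[start])
        if start_cluster is None:
            idxs = [start]  # singleton: single-gene deletion
        else:
            # excise the whole contiguous island of this cluster
            lo = start
            while True:
                prev = (lo - 1) % n
                if prev == start or universe.cluster_of.get(genome.order[prev]) != start_cluster:
                    break
                lo = prev
            idxs = []
            i = lo
            while (
                len(idxs) < n - 2
                and universe.cluster_of.get(genome.order[i]) == start_cluster
            ):
                idxs.append(i)
                i = (i + 1) % n
                if i == lo:
                    break
        removed = set(idxs)
        before = (idxs[0] - 1) % n  # not in the run since len(idxs) <= n-2
        # the removed DNA spans from the start of the first gene to the end
        # of the last: internal gaps vanish, the flanking gaps merge
        genome.gap_after[before] += genome.gap_after[idxs[-1]]
        genome.order = [f for i, f in enumerate(genome.order) if i not in removed]
        genome.gap_after = [g for i, g in enumerate(genome.gap_after) if i not in removed]


def _sample_segment(universe, absent: set, seed_fam: str, cap: float, rng):
    """Contiguous run of absent same-cluster families containing the seed,
    grown left/right while the segment stays within ``cap`` bp. Returns
    (families, internal_gaps)."""
    c = universe.cluster_of.get(seed_fam)
    if c is None:
        return [seed_fam], []
    members = universe.cluster_members[c]
    gaps = universe.cluster_gaps[c]
    pos = members.index(seed_fam)
    lo = hi = pos
    length = universe.length_of(seed_fam)
    while True:
        grew = False
        for side in rng.permutation(2):
            if side == 0 and lo > 0 and members[lo - 1] in absent:
                add = universe.length_of(members[lo - 1]) + gaps[lo - 1]
                if length + add <= cap:
                    lo -= 1
                    length += add
                    grew = True
            elif side == 1 and hi < len(members) - 1 and members[hi + 1] in absent:
                add = universe.length_of(members[hi + 1]) + gaps[hi]
                if length + add <= cap:
                    hi += 1
                    length += add
                    grew = True
        if not grew:
            break
    return members[lo : hi + 1], list(gaps[lo:hi])


def _insert_segment(genome: Genome, fams: list, gaps: list, rng) -> None:
    """Insert the segment at a uniform circular position, never splitting a
    gene: the insertion point is drawn inside an intergenic gap with
    probability proportional to gap length."""
    total = sum(genome.gap_after)
    weights = np.asarray(genome.gap_after, dtype=float)
    if total <= 0:
        j = int(rng.integers(len(genome.gap_after)))
        u = 0.0
    else:
        j = int(rng.choice(len(weights), p=weights / total))
        u = float(rng.uniform(0, genome.gap_after[j]))
    rest = genome.gap_after[j] - u
    genome.gap_after[j] = u
    new_gaps = gaps + [rest]
    pos = j + 1
    genome.order[pos:pos] = fams
    genome.gap_after[pos:pos] = new_gaps


def _segment_length(universe, fams, gaps) -> float:
    return float(sum(universe.length_of(f) for f in fams) + sum(gaps))


def evolve_genomes(
    tree: Phylogeny,
    universe: FamilyUniverse,
    root: Genome,
    config: SimulationConfig,
    truth: GroundTruth,
):
    """Evolve the root genome along every branch.

    Returns ``(presence, leaf_genomes, genome_lengths, truth)`` where
    ``presence`` is the families x leaf-genomes 0/1 DataFrame,
    ``leaf_genomes`` maps genome id -> Genome, and truth has been extended
    with the event log and co-transfer pairs.
    """
    rng = np.random.default_rng(config.seed + 2)
    genomes: dict = {0: root.copy()}
    branch_ids = ["root"] + tree.branch_ids()
    for node in tree.preorder()[1:]:
        g = genomes[tree.parent[node]].copy()
        t = float(tree.blen[node])
        # segmental deletions: marginal per-accessory-gene rate = loss_rate
        if config.loss_rate > 0 and len(g.order) > 2:
            n_acc = sum(1 for f in g.order if f not in universe.core)
            lam = config.loss_rate * t * n_acc / config.loss_run_mean
            _delete_runs(g, rng.poisson(lam), config.loss_run_mean, universe, rng)
        # acquisitions from the local pan-genome
        if config.gain_rate > 0:
            for _ in range(rng.poisson(config.gain_rate * t)):
                present = set(g.order)
                absent = [f for f in universe.ids if f not in present]
                if not absent:
                    logger.warning("empty donor pool on branch %s; event skipped", branch_ids[node])
                    continue
                phage_event = rng.random() < config.phage_event_fraction
                absent_set = set(absent)
                # acquisitions preferentially pick up clustered toolbox genes
                clustered_pool = [
                    f for f in absent if f in universe.cluster_of and f not in universe.phage
                ]
                single_pool = [
                    f for f in absent
                    if f not in universe.cluster_of and f not in universe.phage
                ]
                if clustered_pool and (
                    not single_pool or rng.random() < config.cluster_seed_bias
                ):
                    cargo_pool = clustered_pool
                elif single_pool:
                    cargo_pool = single_pool
                else:
                    cargo_pool = absent
                seed_fam = str(rng.choice(cargo_pool))
                fams, gaps = _sample_segment(
                    universe, absent_set, seed_fam, config.segment_cap, rng
                )
                if phage_event:
                    pool = [f for f in absent if f in universe.phage and f not in fams]
                    if not pool:
                        logger.warning(
                            "no absent phage family for phage-mediated event on %s; skipped",
                            branch_ids[node],
                        )
                        continue
                    rng.shuffle(pool)
                    target = rng.uniform(config.segment_cap, config.phage_segment_cap)
                    while pool:
                        nxt = pool[0]
                        add = universe.length_of(nxt) + 2 * config.filler_gap
                        if _segment_length(universe, fams, gaps) + add > min(
                            target, config.phage_segment_cap
                        ):
                            break
                        pool.pop(0)
                        slot = int(rng.integers(1, len(fams))) if len(fams) > 1 else 1
                        if len(fams) == 1:
                            fams = fams + [nxt]
                            gaps = gaps + [config.filler_gap]
                        else:
                            fams = fams[:slot] + [nxt] + fams[slot:]
                            old = gaps[slot - 1]
                            gaps = (
                                gaps[: slot - 1]
                                + [config.filler_gap, old + config.filler_gap]
                                + gaps[slot:]
                            )
                    if not any(f in universe.phage for f in fams):
                        logger.warning(
                            "phage-mediated event on %s could not fit a phage gene; skipped",
                            branch_ids[node],
                        )
                        continue
                seg_len = _segment_length(universe, fams, gaps)
                cap = config.phage_segment_cap if phage_event else config.segment_cap
                if seg_len > cap:  # lone gene longer than the cap
                    logger.warning(
                        "segment exceeds cap on branch %s; event skipped", branch_ids[node]
                    )
                    continue
                _insert_segment(g, fams, gaps, rng)
                truth.true_event_log.append(
                    (branch_ids[node], tuple(fams), bool(phage_event), float(seg_len))
                )
                for i in range(len(fams)):
                    for j in range(i + 1, len(fams)):
                        truth.true_cotransfer_pairs.add(frozenset((fams[i], fams[j])))
        genomes[node] = g

    leaf_ids = tree.leaf_indices()
    leaf_genomes = {tree.labels[i]: genomes[i] for i in leaf_ids}
    presence = pd.DataFrame(
        0,
        index=pd.Index(universe.ids, name="family_id"),
        columns=[tree.labels[i] for i in leaf_ids],
        dtype=np.int8,
    )
    for gid, g in leaf_genomes.items():
        presence.loc[sorted(set(g.order)), gid] = 1
    genome_lengths = {gid: g.total_length(universe) for gid, g in leaf_genomes.items()}
    return presence, leaf_genomes, genome_lengths, truth


def genome_to_table(
    genome: Genome, genome_id: str, universe: FamilyUniverse, rng=None
) -> pd.DataFrame:
    """Coordinate table for one genome; a random rotation moves the origin so
    wrap-around genes occur (end > genome_length)."""
    L = genome.total_length(universe)
    starts, cur = [], 0.0
    for f, gap in zip(genome.order, genome.gap_after):
        starts.append(cur)
        cur += universe.length_of(f) + gap
    off = float(rng.uniform(0, L)) if rng is not None else 0.0
    rows = []
    for f, s in zip(genome.order, starts):
        s2 = (s + off) % L
        rows.append(
            {
                "family_id": f,
                "genome_id": genome_id,
                "start": int(s2),
                "end": int(s2 + universe.length_of(f)),
                "strand": "+" if (rng is None or rng.random() < 0.5) else "-",
                "product_text": universe.products[f],
                "mobile_element": int(f in universe.mobile),
            }
        )
    return pd.DataFrame(rows)


def leaf_operons(universe: FamilyUniverse, leaf_genomes: dict) -> dict:
    """Operon membership per leaf genome: the root operon structure filtered
    to families present in that genome (>= 2 members required)."""
    out = {}
    for gid, g in leaf_genomes.items():
        present = set(g.order)
        ops = []
        for c_ops in universe.operons_of_cluster:
            for op in c_ops:
                kept = [f for f in op if f in present]
                if len(kept) >= 2:
                    ops.append(kept)
        out[gid] = ops
    return out


# ----------------------------------------------------------------------
# panel profiles


def simulate_panel_profiles(
    universe: FamilyUniverse, config: SimulationConfig
) -> pd.DataFrame:
    """Binary presence profiles across the species panel.

    Hierarchical retention: a species carries a cluster with probability
    ``cluster_panel_prob``; given the cluster, each operon is retained with
    probability ``operon_panel_prob``; independent flip noise is applied on
    top. Singletons are independent coin flips, so cross-cluster MI is ~0
    while same-operon MI exceeds same-cluster MI.
    """
    rng = np.random.default_rng(config.seed + 3)
    S = config.n_panel_species
    X = np.zeros((len(universe.ids), S), dtype=np.int8)
    idx = universe.index
    for s in range(S):
        for c, members in enumerate(universe.cluster_members):
            if rng.random() < config.cluster_panel_prob:
                for op in universe.operons_of_cluster[c]:
                    if rng.random() < config.operon_panel_prob:
                        for f in op:
                            X[idx[f], s] = 1
    clustered = set(universe.cluster_of)
    for f in universe.ids:
        if f not in clustered:
            X[idx[f], :] = rng.random(S) < config.singleton_panel_prob
    flip = rng.random(X.shape) < config.panel_flip_noise
    X = np.where(flip, 1 - X, X)
    return pd.DataFrame(
        X, index=pd.Index(universe.ids, name="family_id"),
        columns=[f"sp{j:03d}" for j in range(S)],
    )


# ----------------------------------------------------------------------
# one-call bundle


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    tree: Phylogeny
    universe: FamilyUniverse
    presence: pd.DataFrame
    genes: pd.DataFrame  # all leaf genomes, concatenated
    genome_lengths: dict
    operons: dict
    profiles: pd.DataFrame
    truth: GroundTruth

    @property
    def go_map(self) -> dict:
        return universe_go(self.universe)

    def write(self, outdir) -> None:
        from pathlib import Path

        from . import annotation as ann

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.tree.write_newick(out / "tree.nwk")
        self.presence.to_csv(out / "presence.tsv", sep="\t")
        self.genes.to_csv(out / "genes.tsv", sep="\t", index=False)
        pd.Series(self.genome_lengths, name="genome_length").rename_axis("genome_id").to_csv(
            out / "genome_lengths.tsv", sep="\t"
        )
        ann.write_go_table(self.go_map, out / "go.tsv")
        ann.write_operon_table(self.operons, out / "operons.tsv")
        self.profiles.to_csv(out / "panel_profiles.tsv", sep="\t")
        (out / "truth.json").write_text(self.truth.to_json())
        (out / "config.json").write_text(json.dumps(asdict(self.config), indent=1))


def universe_go(universe: FamilyUniverse) -> dict:
    return {f: set(t) for f, t in universe.go_map.items() if t}


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Run the whole generator: tree, root genome, evolution, panel."""
    tree = simulate_tree(config)
    universe, root, truth = simulate_root_genome(config)
    presence, leaf_genomes, genome_lengths, truth = evolve_genomes(
        tree, universe, root, config, truth
    )
    rng = np.random.default_rng(config.seed + 4)
    genes = pd.concat(
        [
            genome_to_table(leaf_genomes[gid], gid, universe, rng)
            for gid in sorted(leaf_genomes)
        ],
        ignore_index=True,
    )
    operons = leaf_operons(universe, leaf_genomes)
    profiles = simulate_panel_profiles(universe, config)
    return SimulatedDataset(
        config=config,
        tree=tree,
        universe=universe,
        presence=presence,
        genes=genes,
        genome_lengths=genome_lengths,
        operons=operons,
        profiles=profiles,
        truth=truth,
    )
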