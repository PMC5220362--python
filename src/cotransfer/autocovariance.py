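"""Supra-operonic cluster (SOC) delineation via genomic autocovariance.

For one genome, the autocovariance of co-occurring (CO-AC) or co-functioning
(GO-AC) gene pairs measures, for a nucleotide site i inside a gene A, the
probability that the site at i + x (circular) lies inside a *different* gene
B such that the pair (A, B) qualifies — co-occurring when the profile mutual
information exceeds ``mi_cutoff``, co-functioning when the families share at
least ``n_go`` GO terms. Phage-associated genes and genes overlapping mobile
elements are excluded. With N the set of the n considered sites,

    G(x) = (1/n) * sum_{i in N} g_i(x)

The curve decomposes into a cluster part plus a flat background G0;
rescaling G_tilde(x) = (G(x) - <G>) / (max G - <G>) makes it peak at 1 and
decay to ~0. Log-binning, truncation at the first non-positive bin after the
peak, removal of the low-distance noise bins, and renormalisation turn
G_tilde into an estimate of the pair-distance distribution within clusters,
G_cluster(x).

Sites and offsets are evaluated on a sliding lattice (default 10 bp) to keep
the computation cheap; ``frame=1`` is the exact mode used by oracle tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .annotation import ASSOCIATED
from .distances import DistanceDistribution, circular_distance


@dataclass
class PairQualifier:
    mode: str  # "CO" | "GO"
    mi_cutoff: float = 0.0001
    n_go: int = 1
    operon_restricted: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("CO", "GO"):
            raise ValueError("mode must be 'CO' or 'GO'")
        if self.mode == "CO" and self.mi_cutoff <= 0:
            raise ValueError("mi_cutoff must be > 0")
        if self.mode == "GO" and self.n_go <= 0:
            raise ValueError("n_go must be > 0")


def qualify_pairs(
    genes: pd.DataFrame,
    qualifier: PairQualifier,
    phage_status: pd.Series,
    mi: pd.DataFrame | None = None,
    go_map: dict | None = None,
    operons: list | None = None,
) -> tuple[set, set]:
    """Qualifying family pairs on one genome.

    Returns ``(pairs, eligible_families)``: the unordered family pairs
    meeting the cutoff, and the families eligible for the site set N
    (present on the genome, non-phage, not overlapping mobile elements, and
    carrying the data the mode needs). ``operons`` (list of ordered
    family-id lists for this genome) restricts pairs to same-operon
    membership when the qualifier says so.
    """
    fams = []
    for fam, sub in genes.groupby("family_id"):
        if phage_status.get(fam) == ASSOCIATED:
            continue
        if sub["mobile_element"].any():
            continue
        fams.append(fam)

    if qualifier.mode == "GO":
        if go_map is None:
            raise ValueError("GO mode needs go_map")
        fams = [f for f in fams if go_map.get(f)]
    else:
        if mi is None:
            raise ValueError("CO mode needs an MI matrix")
        fams = [f for f in fams if f in mi.index]

    same_operon = None
    if qualifier.operon_restricted:
        same_operon = set()
        for op in operons or []:
            for a, b in combinations(op, 2):
                same_operon.add(frozenset((a, b)))

    pairs = set()
    if qualifier.mode == "GO":
        # inverted index on GO terms, then count shared terms per pair
        from collections import Counter

        term_to_fams: dict = {}
        for f in fams:
            for term in go_map[f]:
                term_to_fams.setdefault(term, []).append(f)
        shared: Counter = Counter()
        for members in term_to_fams.values():
            for a, b in combinations(sorted(members), 2):
                shared[(a, b)] += 1
        for (a, b), cnt in shared.items():
            if cnt >= qualifier.n_go:
                pairs.add(frozenset((a, b)))
    else:
        sub = mi.loc[fams, fams].to_numpy()
        iu, ju = np.triu_indices(len(fams), k=1)
        hit = sub[iu, ju] >= qualifier.mi_cutoff
        arr = np.asarray(fams, dtype=object)
        for a, b in zip(arr[iu[hit]], arr[ju[hit]]):
            pairs.add(frozenset((a, b)))

    if same_operon is not None:
        pairs = {p for p in pairs if p in same_operon}
    return pairs, set(fams)


@dataclass
class AcCurve:
    """Autocovariance curve on a distance lattice."""

    x: np.ndarray  # offsets, bp
    G: np.ndarray
    n_sites: int
    frame: int

    @property
    def G_tilde(self) -> np.ndarray:
        g0 = self.G.mean()
        peak = self.G.max()
        if peak <= g0:
            raise DegenerateCurveError("flat autocovariance curve (max G = <G>)")
        return (self.G - g0) / (peak - g0)


class DegenerateCurveError(ValueError):
    pass


def compute_ac(
    genes: pd.DataFrame,
    pairs: set,
    eligible_families: set,
    genome_length: float,
    frame: int = 10,
    x_max: float | None = None,
) -> AcCurve:
    """Autocovariance G(x) of qualifying gene pairs on one circular genome.

    The site set N consists of the lattice sites (spacing ``frame``) inside
    genes of eligible families; g_i(x) = 1 iff site i + x (circular) falls
    inside a different gene whose family forms a qualifying pair with the
    family at site i.
    """
    L = int(genome_length)
    if x_max is None:
        x_max = min(L / 4, 200_000.0)
    n_lat = L // frame
    site_gene = np.full(n_lat, -1, dtype=np.int64)
    sub = genes[genes["family_id"].isin(eligible_families)].reset_index(drop=True)
    fam_list = sorted(eligible_families)
    fam_idx = {f: i for i, f in enumerate(fam_list)}
    gene_fam = np.array([fam_idx[f] for f in sub["family_id"]], dtype=np.int64)
    for gi, row in sub.iterrows():
        first = int(np.ceil(row.start / frame))
        last = int(np.ceil(row.end / frame))  # half-open end
        lat = np.arange(first, last)
        site_gene[lat % n_lat] = gi

    sites = np.nonzero(site_gene >= 0)[0]
    n = len(sites)
    K = int(x_max // frame)
    x = np.arange(1, K + 1) * frame
    if n == 0 or not pairs:
        return AcCurve(x=x, G=np.zeros(K), n_sites=n, frame=frame)

    Q = np.zeros((len(fam_list), len(fam_list)), dtype=bool)
    for p in pairs:
        a, b = tuple(p)
        if a in fam_idx and b in fam_idx:
            Q[fam_idx[a], fam_idx[b]] = Q[fam_idx[b], fam_idx[a]] = True

    site_gene_i = site_gene[sites]
    site_fam_i = gene_fam[site_gene_i]
    G = np.zeros(K)
    for kk in range(1, K + 1):
        j = (sites + kk) % n_lat
        gj = site_gene[j]
        valid = (gj >= 0) & (gj != site_gene_i)
        if valid.any():
            fj = gene_fam[np.where(valid, gj, 0)]
            hit = valid & Q[site_fam_i, fj]
            G[kk - 1] = hit.mean()
    return AcCurve(x=x, G=G, n_sites=n, frame=frame)


@dataclass
class SocDistribution:
    """Log-binned, truncated, normalised G_cluster(x) estimate."""

    bin_left: np.ndarray
    bin_right: np.ndarray
    mass: np.ndarray
    cum: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        total = self.mass.sum()
        if total <= 0:
            raise DegenerateCurveError("no positive mass after truncation")
        self.mass = self.mass / total
        self.cum = np.cumsum(self.mass)

    def cdf(self, x) -> np.ndarray:
        """Piecewise-linear CDF within bins."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        out = np.zeros(len(x))
        lo = np.concatenate([[0.0], self.cum[:-1]])
        for i, (l, r) in enumerate(zip(self.bin_left, self.bin_right)):
            inside = (x >= l) & (x < r)
            out[inside] = lo[i] + (x[inside] - l) / (r - l) * self.mass[i]
        out[x >= self.bin_right[-1]] = 1.0
        out[x < self.bin_left[0]] = 0.0
        return out

    @property
    def median(self) -> float:
        i = int(np.searchsorted(self.cum, 0.5))
        lo = 0.0 if i == 0 else self.cum[i - 1]
        l, r = self.bin_left[i], self.bin_right[i]
        return float(l + (0.5 - lo) / self.mass[i] * (r - l))

    @property
    def support_max(self) -> float:
        return float(self.bin_right[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"bin_left": self.bin_left, "bin_right": self.bin_right,
             "mass": self.mass, "cdf": self.cum}
        )


def rescale_and_bin(curve: AcCurve, bins_per_decade: int = 25) -> SocDistribution:
    """Turn an AC curve into a distance distribution.

    Rescale to peak at 1 with background ~0; geometric bins
    (``bins_per_decade`` per decade) of the lattice values; the binned curve
    is truncated at the first non-positive bin after its peak, leading bins
    below the first local maximum (low-distance noise from ignoring
    intra-gene pairs) are dropped, and the remaining per-bin summed mass is
    normalised to 1.
    """
    gt = curve.G_tilde
    x = curve.x
    lo, hi = np.log10(x[0]), np.log10(x[-1])
    n_bins = max(int(np.ceil((hi - lo) * bins_per_decade)), 1)
    edges = np.logspace(lo, hi, n_bins + 1)
    edges[0] = x[0] - 0.5  # include first lattice point
    idx = np.digitize(x, edges) - 1
    idx = np.clip(idx, 0, n_bins - 1)
    means = np.full(n_bins, np.nan)
    sums = np.zeros(n_bins)
    for b in range(n_bins):
        sel = idx == b
        if sel.any():
            means[b] = gt[sel].mean()
            sums[b] = gt[sel].sum()
    keep = ~np.isnan(means)
    means, sums = means[keep], sums[keep]
    lefts, rights = edges[:-1][keep], edges[1:][keep]

    peak = int(np.nanargmax(means))
    # leading noise: drop bins before the first local maximum
    lead = 0
    while lead < peak and means[lead + 1] >= means[lead]:
        lead += 1
    first_max = lead
    # truncate at the first non-positive bin after the peak
    after = np.nonzero(means[peak:] <= 0)[0]
    stop = peak + int(after[0]) if after.size else len(means)
    sl = slice(first_max, stop)
    mass = np.clip(sums[sl], 0.0, None)
    return SocDistribution(bin_left=lefts[sl], bin_right=rights[sl], mass=mass)


def operon_distance_distribution(
    operons: dict, genes: pd.DataFrame, genome_lengths: dict
) -> DistanceDistribution:
    """All within-operon pairwise gene distances, pooled across genomes."""
    vals = []
    for gid, ops in operons.items():
        sub = genes[genes["genome_id"] == gid]
        coords = {
            f: (g["start"].iloc[0], g["end"].iloc[0])
            for f, g in sub.groupby("family_id")
        }
        L = genome_lengths[gid]
        for op in ops:
            for a, b in combinations(op, 2):
                if a in coords and b in coords:
                    sa, ea = coords[a]
                    sb, eb = coords[b]
                    vals.append(circular_distance(sa, ea, sb, eb, L))
    return DistanceDistribution(np.array(vals), mode="occurrence", filter="operon")


def compare_distributions(dist_a, dist_b) -> dict:
    """Two-sample KS distance between two distance distributions.

    Accepts any mix of empirical (`DistanceDistribution`) and binned
    (`SocDistribution`) distributions; CDFs are evaluated on the merged
    breakpoint grid.
    """
    def breakpoints(d):
        if isinstance(d, SocDistribution):
            return np.concatenate([d.bin_left, d.bin_right])
        return d.values

    grid = np.unique(np.concatenate([breakpoints(dist_a), breakpoints(dist_b)]))
    # evaluate just below and at each breakpoint to capture step jumps
    grid = np.unique(np.concatenate([grid, np.nextafter(grid, -np.inf)]))
    ks = float(np.max(np.abs(dist_a.cdf(grid) - dist_b.cdf(grid))))
    return {"ks": ks, "median_a": dist_a.median, "median_b": dist_b.median}
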