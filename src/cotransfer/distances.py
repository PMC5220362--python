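"""Genomic distances of co-gained gene-family pairs on circular chromosomes.

Distance between two genes is the gap between their nearest boundaries along
the shorter arc of the circle (0 if the features overlap); with this
convention two adjacent co-transferred genes are at distance ~0 and "no
intervening genes" coincides with small distances. For a family pair the
distance in one genome is the minimum over all allele pairs (paralogs), and
the pair's overall distance is the minimum over genomes — a lower bound on
the pair's separation at transfer time. The per-occurrence variant keeps one
value per genome where both families occur instead of the overall minimum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .annotation import ASSOCIATED, NOT_ASSOCIATED


def circular_distance(start_a, end_a, start_b, end_b, genome_length) -> float:
    """Nearest-boundary gap between two gene arcs on a circle.

    Coordinates are 0-based half-open; wrap-around genes have
    ``end > genome_length``. Returns 0 when the arcs overlap.
    """
    L = float(genome_length)
    la, lb = end_a - start_a, end_b - start_b
    if la <= 0 or lb <= 0 or la >= L or lb >= L:
        raise ValueError("gene arcs must have 0 < length < genome_length")
    sa, sb = start_a % L, start_b % L
    # overlap iff one start falls inside the other arc
    if (sb - sa) % L < la or (sa - sb) % L < lb:
        return 0.0
    gap1 = (sb - (sa + la)) % L  # arc from end of A to start of B
    gap2 = (sa - (sb + lb)) % L  # arc from end of B to start of A
    return float(min(gap1, gap2))


@dataclass
class _GenomeIndex:
    starts: np.ndarray
    lengths: np.ndarray
    families: np.ndarray
    phage: np.ndarray  # boolean per gene: family phage-associated
    L: float

    def arc_gene_stats(self, arc_start: float, arc_len: float, exclude: tuple):
        """Count genes fully inside the open arc and the phage fraction."""
        rel = (self.starts - arc_start) % self.L
        inside = (rel + self.lengths) <= arc_len
        if exclude:
            mask = np.ones(len(self.starts), dtype=bool)
            mask[list(exclude)] = False
            inside &= mask
        n = int(inside.sum())
        frac = float(self.phage[inside].mean()) if n else np.nan
        return n, frac


def _index_genomes(genes: pd.DataFrame, genome_lengths: dict, phage_status: pd.Series | None):
    idx = {}
    for gid, sub in genes.groupby("genome_id"):
        starts = sub["start"].to_numpy(float)
        lengths = (sub["end"] - sub["start"]).to_numpy(float)
        fams = sub["family_id"].to_numpy()
        if phage_status is not None:
            phage = phage_status.reindex(fams).eq(ASSOCIATED).to_numpy()
        else:
            phage = np.zeros(len(fams), dtype=bool)
        idx[gid] = _GenomeIndex(starts, lengths, fams, phage, float(genome_lengths[gid]))
    return idx


def pair_occurrence_records(
    pairs,
    genes: pd.DataFrame,
    genome_lengths: dict,
    phage_status: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-occurrence distance records for family pairs.

    For every genome where both families of a pair are present, records the
    minimum allele-pair distance, the number of genes fully inside the
    shorter-arc gap between the closest allele pair, and the fraction of
    those intervening genes that are phage-associated (NaN when there are
    none). Pairs never co-present yield no rows.
    """
    index = _index_genomes(genes, genome_lengths, phage_status)
    rows = []
    for fam_a, fam_b in pairs:
        for gid, gi in index.items():
            ia = np.nonzero(gi.families == fam_a)[0]
            ib = np.nonzero(gi.families == fam_b)[0]
            if len(ia) == 0 or len(ib) == 0:
                continue
            best, best_pair = np.inf, None
            for i in ia:
                for j in ib:
                    d = circular_distance(
                        gi.starts[i], gi.starts[i] + gi.lengths[i],
                        gi.starts[j], gi.starts[j] + gi.lengths[j], gi.L,
                    )
                    if d < best:
                        best, best_pair = d, (i, j)
            i, j = best_pair
            if best == 0.0:
                n_int, frac = 0, np.nan
            else:
                ea = gi.starts[i] + gi.lengths[i]
                eb = gi.starts[j] + gi.lengths[j]
                gap1 = (gi.starts[j] - ea) % gi.L
                gap2 = (gi.starts[i] - eb) % gi.L
                if gap1 <= gap2:
                    arc_start, arc_len = ea % gi.L, gap1
                else:
                    arc_start, arc_len = eb % gi.L, gap2
                n_int, frac = gi.arc_gene_stats(arc_start, arc_len, exclude=(i, j))
            rows.append(
                {
                    "family_a": fam_a,
                    "family_b": fam_b,
                    "genome_id": gid,
                    "distance": best,
                    "n_intervening_genes": n_int,
                    "frac_intervening_phage": frac,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "family_a", "family_b", "genome_id", "distance",
            "n_intervening_genes", "frac_intervening_phage",
        ],
    )


def min_family_distance(records: pd.DataFrame) -> pd.Series:
    """Minimum-over-genomes distance per family pair (from occurrence records)."""
    return records.groupby(["family_a", "family_b"])["distance"].min()


def per_occurrence_distances(records: pd.DataFrame) -> np.ndarray:
    return records["distance"].to_numpy(float)


@dataclass
class DistanceDistribution:
    """Empirical distance distribution (sorted sample + step CDF)."""

    values: np.ndarray
    mode: str = "min"  # or "occurrence"
    filter: str = "all"  # or "non_phage"

    def __post_init__(self) -> None:
        self.values = np.sort(np.asarray(self.values, dtype=float))

    def __len__(self) -> int:
        return len(self.values)

    def cdf(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if len(self.values) == 0:
            return np.full(x.shape, np.nan)
        return np.searchsorted(self.values, x, side="right") / len(self.values)

    @property
    def median(self) -> float:
        return float(np.median(self.values)) if len(self.values) else np.nan

    @property
    def support_max(self) -> float:
        return float(self.values[-1]) if len(self.values) else np.nan


def non_phage_pairs(pairs, phage_status: pd.Series):
    """Pairs whose members are both strictly ``not_associated`` (uncertain
    families are excluded: the filter keeps pairs *known* to be non-phage)."""
    return [
        (a, b)
        for a, b in pairs
        if phage_status.get(a) == NOT_ASSOCIATED and phage_status.get(b) == NOT_ASSOCIATED
    ]


def build_distribution(
    records: pd.DataFrame, mode: str = "min", filter: str = "all"
) -> DistanceDistribution:
    if mode == "min":
        vals = min_family_distance(records).to_numpy()
    elif mode == "occurrence":
        vals = per_occurrence_distances(records)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return DistanceDistribution(vals, mode=mode, filter=filter)


def intervening_phage_stats(
    records: pd.DataFrame, close_bound: float = 30_000, far_bound: float = 70_000
) -> dict:
    """Compare intervening phage-gene fractions of close vs distant occurrences.

    Occurrences with no intervening genes are excluded from the fraction
    comparison; close = distance < close_bound, distant = close_bound <=
    distance < far_bound. Returns group means (percent), a two-sided
    Wilcoxon rank-sum p-value (mid-ranked ties), and the share of distant
    occurrences with at least one intervening phage gene.
    """
    distant_all = records[
        (records["distance"] >= close_bound) & (records["distance"] < far_bound)
    ]
    with_genes = records[records["n_intervening_genes"] > 0]
    close = with_genes[with_genes["distance"] < close_bound]["frac_intervening_phage"]
    distant = with_genes[
        (with_genes["distance"] >= close_bound) & (with_genes["distance"] < far_bound)
    ]["frac_intervening_phage"]
    out = {
        "n_close": int(len(close)),
        "n_distant": int(len(distant)),
        "close_mean_pct": float(close.mean() * 100) if len(close) else np.nan,
        "distant_mean_pct": float(distant.mean() * 100) if len(distant) else np.nan,
        "p_value": np.nan,
        "distant_with_phage_pct": np.nan,
    }
    if len(distant_all):
        has_phage = (
            (distant_all["n_intervening_genes"] > 0)
            & (distant_all["frac_intervening_phage"] > 0)
        )
        out["distant_with_phage_pct"] = float(has_phage.mean() * 100)
    if len(close) and len(distant):
        out["p_value"] = float(
            mannwhitneyu(close, distant, alternative="two-sided").pvalue
        )
    return out
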