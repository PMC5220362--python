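"""Mutual information of phylogenetic profiles across a species panel.

A family's phylogenetic profile is its binary presence/absence vector across
the panel species. For two profiles the four joint patterns [0,0], [1,0],
[0,1], [1,1] have plug-in probabilities p1..p4 (pattern count / number of
species); with marginal presence probabilities qA = p2 + p4 and qB = p3 + p4
the co-occurrence strength is the mutual information

    I(A:B) = H(A) + H(B) - H(A,B)

with base-2 entropies (0·log 0 := 0). Base 2 makes 0 <= I <= 1 for binary
profiles, 0 meaning independence and 1 perfect co-occurrence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr


def _entropy(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, -p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    return terms.sum(axis=-1)


@dataclass
class PatternCounts:
    p1: float  # [0,0]
    p2: float  # [1,0]
    p3: float  # [0,1]
    p4: float  # [1,1]

    @property
    def qA(self) -> float:
        return self.p2 + self.p4

    @property
    def qB(self) -> float:
        return self.p3 + self.p4

    @property
    def H_A(self) -> float:
        return float(_entropy(np.array([1 - self.qA, self.qA])))

    @property
    def H_B(self) -> float:
        return float(_entropy(np.array([1 - self.qB, self.qB])))

    @property
    def H_AB(self) -> float:
        return float(_entropy(np.array([self.p1, self.p2, self.p3, self.p4])))

    @property
    def mi(self) -> float:
        return max(self.H_A + self.H_B - self.H_AB, 0.0)


def pattern_counts(a, b) -> PatternCounts:
    a = np.asarray(a, dtype=np.int8)
    b = np.asarray(b, dtype=np.int8)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("profiles must be 1-D of equal length")
    if len(a) < 2:
        raise ValueError("need at least 2 species")
    n = len(a)
    n11 = int(np.sum((a == 1) & (b == 1)))
    n10 = int(np.sum((a == 1) & (b == 0)))
    n01 = int(np.sum((a == 0) & (b == 1)))
    n00 = n - n11 - n10 - n01
    return PatternCounts(n00 / n, n10 / n, n01 / n, n11 / n)


def mutual_information(a, b) -> float:
    return pattern_counts(a, b).mi


def mi_matrix(profiles: pd.DataFrame) -> pd.DataFrame:
    """All-pairs MI for a families x species binary profile matrix.

    Vectorised through pattern-count matrix products; the diagonal holds
    each family's marginal entropy H(A) = I(A:A).
    """
    X = profiles.to_numpy(dtype=float)
    if not np.isin(X, (0, 1)).all():
        raise ValueError("profile matrix must be binary")
    n = X.shape[1]
    if n < 2:
        raise ValueError("need at least 2 species")
    N11 = X @ X.T
    k = X.sum(axis=1)
    N10 = k[:, None] - N11
    N01 = k[None, :] - N11
    N00 = n - N11 - N10 - N01
    H_joint = _entropy(np.stack([N00, N10, N01, N11], axis=-1) / n)
    q = k / n
    H_marg = _entropy(np.stack([1 - q, q], axis=-1))
    I = np.maximum(H_marg[:, None] + H_marg[None, :] - H_joint, 0.0)
    return pd.DataFrame(I, index=profiles.index, columns=profiles.index)


def mi_pair_table(profiles: pd.DataFrame) -> pd.DataFrame:
    """Long-form unordered-pair MI table (family_a, family_b, mi)."""
    M = mi_matrix(profiles)
    iu, ju = np.triu_indices(len(M), k=1)
    fams = M.index.to_numpy()
    return pd.DataFrame(
        {"family_a": fams[iu], "family_b": fams[ju], "mi": M.to_numpy()[iu, ju]}
    )


def go_mi_correlation(n_go: np.ndarray, mi: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation (mid-rank ties) between the number of
    shared GO terms and profile MI, restricted to pairs with n_go > 0."""
    n_go = np.asarray(n_go, dtype=float)
    mi = np.asarray(mi, dtype=float)
    if n_go.shape != mi.shape:
        raise ValueError("n_go and mi must align")
    keep = n_go > 0
    if keep.sum() < 3:
        raise ValueError("need at least 3 pairs with n_go > 0")
    rho, p = spearmanr(n_go[keep], mi[keep])
    return float(rho), float(p)
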