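"""Nonparametric group comparison and qRT-PCR expression normalization.

Group readouts (per-eye mean solidity, normalized densities, OCT ratios)
are compared with the Mann-Whitney U test for two groups, or Kruskal-Wallis
for more, matching the small per-group sample sizes (n = 5-15) these
experiments produce.  qRT-PCR results are expressed as
``2^(-Ct_mean_GOI) / 2^(-Ct_mean_NOR)``, the expression ratio of the gene
of interest over the housekeeping normalizers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "KruskalResult",
    "ExpressionRatio",
    "mann_whitney",
    "kruskal_wallis",
    "expression_ratio",
    "EXACT_MAX_N",
]

# Exact enumeration of the U distribution is used up to this combined
# sample size when there are no ties; beyond it (or with ties) the normal
# approximation with tie and continuity corrections takes over.
EXACT_MAX_N = 12


@dataclass(frozen=True)
class GroupComparison:
    n_a: int
    n_b: int
    u_statistic: float
    p_value: float
    method: str  # "exact" | "normal-approx"

    def __post_init__(self) -> None:
        if not (0 <= self.u_statistic <= self.n_a * self.n_b):
            raise ValueError("U must lie in [0, n_a * n_b]")
        if not (0 < self.p_value <= 1):
            raise ValueError("p must lie in (0, 1]")


@dataclass(frozen=True)
class KruskalResult:
    h_statistic: float
    p_value: float
    df: int
    degenerate: bool = False


@dataclass(frozen=True)
class ExpressionRatio:
    ct_goi: tuple[float, ...]
    ct_nor: tuple[float, ...]
    ratio: float


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> GroupComparison:
    """Two-sided Mann-Whitney U test with midrank ties.

    The reported U is the statistic of the first sample.  The p-value is
    exact (full enumeration of rank assignments) when the combined sample
    size is at most 12 and there are no ties; otherwise the normal
    approximation with tie correction and continuity correction is used.
    The method actually applied is recorded in the result.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    exact = (a.size + b.size <= EXACT_MAX_N) and not has_ties
    method = "exact" if exact else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    p = min(float(res.pvalue), 1.0)
    return GroupComparison(
        n_a=int(a.size),
        n_b=int(b.size),
        u_statistic=float(res.statistic),
        p_value=p,
        method="exact" if exact else "normal-approx",
    )


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> KruskalResult:
    """Midrank-tie-corrected Kruskal-Wallis H with chi-square p (k-1 df).

    When every observation is identical the statistic is undefined; the
    result is reported as degenerate (H = 0, p = 1) rather than raising.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=np.float64) for g in groups]
    if any(g.size == 0 for g in arrays):
        raise ValueError("all groups must be non-empty")
    df = len(arrays) - 1
    pooled = np.concatenate(arrays)
    if np.unique(pooled).size == 1:
        return KruskalResult(h_statistic=0.0, p_value=1.0, df=df, degenerate=True)
    h, p = sps.kruskal(*arrays)
    return KruskalResult(h_statistic=float(h), p_value=float(p), df=df)


def expression_ratio(ct_goi: Sequence[float], ct_nor: Sequence[float]) -> ExpressionRatio:
    """qRT-PCR expression ratio ``2^(-mean Ct_GOI) / 2^(-mean Ct_NOR)``.

    Ct values of multiple normalizer genes (e.g. GAPDH and snU6) are pooled
    into a single mean before the formula.  The ratio is invariant to
    adding a constant cycle offset to both lists; a one-cycle decrease of
    the GOI mean doubles it.
    """
    goi = np.asarray(ct_goi, dtype=np.float64)
    nor = np.asarray(ct_nor, dtype=np.float64)
    if goi.size == 0 or nor.size == 0:
        raise ValueError("both Ct lists must be non-empty")
    if not (np.all(np.isfinite(goi)) and np.all(np.isfinite(nor))):
        raise ValueError("Ct values must be finite")
    ratio = float(2.0 ** (nor.mean() - goi.mean()))
    return ExpressionRatio(ct_goi=tuple(goi), ct_nor=tuple(nor), ratio=ratio)
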