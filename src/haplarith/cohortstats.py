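"""Cohort-level statistics for pregnancy-loss genome analyses.

Covers the extrapolated prevalence of genomic abnormality (combining
karyotyping and haplotype-based reanalysis of karyotypically normal
cases), the standard group comparisons (Welch's t from summary data,
Wilcoxon signed-rank, Fisher's exact, Mann-Whitney U), a paired Wilcoxon
sample-size calculation via the asymptotic-relative-efficiency correction
of the paired t test, and the qPCR fold-change arithmetic used to validate
copy-number calls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats


@dataclass
class CohortCounts:
    """Karyotyping / haplotyping tallies feeding the extrapolation formula.

    AK/NK: abnormal/normal by conventional karyotyping; AH: abnormal by
    haplotype analysis; TH: total re-analysed; TK: total karyotyped.
    """

    AK: int
    NK: int
    AH: int
    TH: int
    TK: int

    def __post_init__(self) -> None:
        for name in ("AK", "NK", "AH", "TH", "TK"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer")
        if self.AK + self.NK != self.TK:
            raise ValueError("AK + NK must equal TK")
        if self.AH > self.TH:
            raise ValueError("AH cannot exceed TH")


@dataclass
class SummaryStats:
    """Mean, standard deviation and size of one group."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.n < 2:
            raise ValueError("n must be >= 2")


def extrapolate_abnormality_rate(c: CohortCounts) -> float:
    """Extrapolated percentage of genomically abnormal cases.

    ((AK + NK * AH / TH) * 100) / TK, reported to one decimal: the
    karyotypically normal fraction is assumed to hide abnormality at the
    rate seen in the re-analysed subset.
    """
    if c.TH == 0 or c.TK == 0:
        raise ValueError("TH and TK must be positive")
    rate = ((c.AK + c.NK * c.AH / c.TH) * 100.0) / c.TK
    return round(rate, 1)


def welch_t(a: SummaryStats, b: SummaryStats) -> tuple[float, float, float]:
    """Two-sided Welch's t-test from summary statistics.

    Returns (t, Welch-Satterthwaite df, two-sided p).
    """
    res = stats.ttest_ind_from_stats(
        a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=False
    )
    va, vb = a.sd**2 / a.n, b.sd**2 / b.n
    df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def wilcoxon_signed_rank(pairs: Sequence[tuple[float, float]]) -> float:
    """Two-sided Wilcoxon signed-rank p for paired observations.

    Exact null enumeration for n <= 25 nonzero differences (no ties),
    normal approximation with continuity correction above.  A single pair
    yields the exact p = 1; all-zero differences are an error.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be (n, 2)")
    d = arr[:, 0] - arr[:, 1]
    d = d[d != 0]
    if len(d) == 0:
        raise ValueError("all differences are zero")
    n = len(d)
    ranks_tied = len(np.unique(np.abs(d))) < n
    if n <= 25 and not ranks_tied:
        method = "exact"
        res = stats.wilcoxon(d, alternative="two-sided", method=method)
    else:
        res = stats.wilcoxon(
            d, alternative="two-sided", method="approx", correction=True
        )
    return float(min(res.pvalue, 1.0))


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher's exact p (sum of probabilities <= observed)."""
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        raise ValueError("table entries must be non-negative integers")
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def chi_squared_2x2(table: Sequence[Sequence[int]], correction: bool = True) -> float:
    """Chi-squared test p for a 2x2 contingency table."""
    t = np.asarray(table)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("table must be a non-negative 2x2 array")
    return float(stats.chi2_contingency(t, correction=correction)[1])


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Mann-Whitney U p.

    Exact when the smaller sample has <= 8 observations and there are no
    ties across samples; otherwise the normal approximation with tie and
    continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if min(len(x), len(y)) <= 8 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(min(res.pvalue, 1.0))


# ---------------------------------------------------------------------------
# Paired Wilcoxon sample size (A.R.E. method)
# ---------------------------------------------------------------------------

WILCOXON_ARE_NORMAL = 3.0 / math.pi


def _paired_t_power(n_eff: float, dz: float, alpha: float) -> float:
    """Two-sided paired-t power at effective sample size ``n_eff``."""
    df = n_eff - 1.0
    if df <= 1:
        return 0.0
    ncp = dz * math.sqrt(n_eff)
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    return float(
        stats.nct.sf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp)
    )


def paired_wilcoxon_sample_size(
    delta: float,
    sd_a: float,
    sd_b: float,
    rho: float,
    alpha: float = 0.05,
    power: float = 0.80,
    are: float = WILCOXON_ARE_NORMAL,
    n_max: int = 100_000,
) -> int:
    """Total pairs needed for a two-sided matched-pairs Wilcoxon test.

    The paired-difference scale is sd_diff = sqrt(sd_a^2 + sd_b^2 -
    2*rho*sd_a*sd_b) and the effect size dz = delta / sd_diff.  The
    noncentral-t power of the paired t test is evaluated at the
    A.R.E.-discounted effective size n * are (3/pi under a normal parent
    distribution), and the smallest n reaching the target power is
    returned.
    """
    if delta <= 0:
        raise ValueError("delta must be > 0")
    if sd_a <= 0 or sd_b <= 0:
        raise ValueError("standard deviations must be > 0")
    if not -1 < rho < 1:
        raise ValueError("rho must lie in (-1, 1)")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    sd_diff = math.sqrt(sd_a**2 + sd_b**2 - 2 * rho * sd_a * sd_b)
    if sd_diff == 0:
        raise ValueError("difference scale is zero for the given rho")
    dz = delta / sd_diff
    for n in range(4, n_max + 1):
        if _paired_t_power(n * are, dz, alpha) >= power:
            return n
    raise ValueError("no sample size below n_max reaches the target power")


# ---------------------------------------------------------------------------
# qPCR fold change
# ---------------------------------------------------------------------------

def qpcr_fold_change(
    ct_test: float,
    ct_ref: float,
    slope_test: float,
    logqt_control: float,
) -> tuple[float, str]:
    """Copy-number fold change from qPCR threshold cycles.

    logQT = (Ct_test - Ct_ref) / slope; fold change =
    10**(logQT_test - logQT_control).  Interpretation bands: 0.8-1.2 two
    copies, <= 0.7 deletion, 1.3-1.7 duplication (1.33 is four copies
    against a triploid three-copy reference); anything else inconclusive.
    """
    if slope_test == 0:
        raise ValueError("slope must be nonzero")
    logqt = (ct_test - ct_ref) / slope_test
    fc = 10.0 ** (logqt - logqt_control)
    if 0.8 <= fc <= 1.2:
        label = "two_copies"
    elif fc <= 0.7:
        label = "deletion"
    elif 1.3 <= fc <= 1.7:
        label = "duplication"
    else:
        label = "inconclusive"
    return fc, label
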