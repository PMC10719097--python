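"""Trio haplotyping and haplarithm construction.

The pipeline: (1) classify informative SNPs (one parent heterozygous, the
other homozygous); (2) deduce the transmitted allele of the heterozygous
parent Mendelianly from the chorionic-villi (CV) genotype, which seeds the
parental phase; (3) assign each informative SNP to a haplarithm
subcategory -- paternal P1/P2 or maternal M1/M2 -- according to whether the
transmitted allele of the heterozygous parent equals the homozygous
parent's allele (P1/M1) or not (P2/M2); (4) mirror BAF values around 0.5
where the heterozygous parent's phased genotype is BA (transmitted allele
B); (5) segment each mirrored BAF series by exact piecewise constant
fitting (PCF).

In a clean disomy this places P1/M1 at 0 and P2/M2 at 0.5; copy-number
changes displace the P2/M2 band, e.g. a non-mosaic maternal trisomy moves
the paternal P2 band to 2/3 and the maternal M2 band to 1/3.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .arrayio import TrioQuartet

#: PCF penalty per breakpoint, applied to the noise-standardized series.
DEFAULT_GAMMA = 14.0
#: Minimum informative SNPs per series per chromosome to emit segments.
MIN_SNPS_PER_SERIES = 20
#: Genome-wide Mendelian inconsistency fraction above which phasing aborts.
MENDELIAN_ERROR_LIMIT = 0.05
#: Floor for the robust noise estimate (BAF units) so that noise-free
#: series remain segmentable.
SIGMA_FLOOR = 0.005

CATEGORY_LABELS = (
    "paternal_informative", "maternal_informative", "both_het",
    "uninformative", "missing",
)
SERIES_NAMES = ("P1", "P2", "M1", "M2")


class PhasingError(ValueError):
    """Raised when the quartet cannot be phased (e.g. non-paternity)."""


# ---------------------------------------------------------------------------
# Informative-SNP classification
# ---------------------------------------------------------------------------

def classify_informative_snps(
    mother_gt: np.ndarray, father_gt: np.ndarray
) -> np.ndarray:
    """Label each SNP by trio informativity.

    A SNP is paternal-informative iff the father is AB and the mother
    homozygous, maternal-informative in the symmetric case; double
    heterozygotes are excluded from haplarithms and any no-call makes the
    SNP missing.
    """
    mother_gt = np.asarray(mother_gt, dtype="<U2")
    father_gt = np.asarray(father_gt, dtype="<U2")
    out = np.full(mother_gt.shape, "uninformative", dtype="<U24")
    m_hom = np.isin(mother_gt, ("AA", "BB"))
    f_hom = np.isin(father_gt, ("AA", "BB"))
    m_het = mother_gt == "AB"
    f_het = father_gt == "AB"
    out[f_het & m_hom] = "paternal_informative"
    out[m_het & f_hom] = "maternal_informative"
    out[m_het & f_het] = "both_het"
    out[(mother_gt == "NC") | (father_gt == "NC")] = "missing"
    return out


# ---------------------------------------------------------------------------
# CV-seeded phasing
# ---------------------------------------------------------------------------

@dataclass
class PhaseResult:
    """Per-SNP phasing state shared by the CV and EM haplarithms."""

    category: np.ndarray  # labels from CATEGORY_LABELS
    subcategory: np.ndarray  # P1/P2/M1/M2/none
    transmitted: np.ndarray  # int8: seed-transmitted allele of the het
    #                          parent (0=A, 1=B, -1 unknown)
    mirror: np.ndarray  # bool, step-(4) mirror flag
    inconsistent: np.ndarray  # bool, Mendelian-impossible CV genotype
    error_rate: float  # genome-wide inconsistency fraction


_ALLELE_COUNT = {"AA": 0, "AB": 1, "BB": 2}


def phase_with_seed(quartet: TrioQuartet) -> PhaseResult:
    """Phase the parental genomes using the CV genotype as the seed.

    At each informative SNP the transmitted allele of the heterozygous
    parent follows Mendelianly from the CV call and the homozygous
    parent's allele.  Mendelian-impossible SNPs are flagged and excluded;
    if more than ``MENDELIAN_ERROR_LIMIT`` of checkable SNPs are
    inconsistent genome-wide, a :class:`PhasingError` is raised
    (non-paternity or gross contamination).
    """
    m_gt, f_gt, cv_gt = (
        quartet.mother.genotype, quartet.father.genotype, quartet.cv.genotype
    )
    n = len(m_gt)
    category = classify_informative_snps(m_gt, f_gt)
    subcategory = np.full(n, "none", dtype="<U4")
    transmitted = np.full(n, -1, dtype=np.int8)
    mirror = np.zeros(n, dtype=bool)
    inconsistent = np.zeros(n, dtype=bool)

    cv_b = np.full(n, -9, dtype=np.int8)
    for g, k in _ALLELE_COUNT.items():
        cv_b[cv_gt == g] = k
    for cat, hom_gt in (
        ("paternal_informative", m_gt),
        ("maternal_informative", f_gt),
    ):
        sel = (category == cat) & (cv_b >= 0)
        hom_allele = (hom_gt == "BB").astype(np.int8)
        # disomic expectation: CV = hom parent's allele + transmitted
        t = cv_b - hom_allele
        ok = sel & ((t == 0) | (t == 1))
        inconsistent |= sel & ~ok
        transmitted[ok] = t[ok]
        prefix = "P" if cat == "paternal_informative" else "M"
        subcategory[ok & (t == hom_allele)] = prefix + "1"
        subcategory[ok & (t != hom_allele) & (t >= 0)] = prefix + "2"
        mirror[ok & (t == 1)] = True
    checkable = np.isin(
        category, ("paternal_informative", "maternal_informative")
    ) & (cv_gt != "NC")
    rate = float(inconsistent.sum() / max(checkable.sum(), 1))
    # Non-paternity/gross contamination affects every chromosome, whereas a
    # genuine whole-chromosome loss or isodisomy concentrates Mendelian
    # impossibilities on one chromosome: judge the cleanest chromosome.
    chrom_rates = []
    for chrom in quartet.probe_map.chromosomes():
        cmask = quartet.probe_map.chrom_mask(chrom)
        n_check = (checkable & cmask).sum()
        if n_check:
            chrom_rates.append((inconsistent & cmask).sum() / n_check)
    min_rate = float(np.min(chrom_rates)) if chrom_rates else 0.0
    if min_rate > MENDELIAN_ERROR_LIMIT:
        raise PhasingError(
            f"{min_rate:.1%} of informative SNPs are Mendelian-"
            "inconsistent even on the cleanest chromosome; the CV sample "
            "is incompatible with the stated parents"
        )
    return PhaseResult(category, subcategory, transmitted, mirror,
                       inconsistent, rate)


def mirror_baf(baf, mirror_flag):
    """Reflect BAF around the 0.5 axis where the flag is set."""
    baf = np.asarray(baf, dtype=float)
    flag = np.asarray(mirror_flag, dtype=bool)
    return np.where(flag, 1.0 - baf, baf)


# ---------------------------------------------------------------------------
# Piecewise constant fitting
# ---------------------------------------------------------------------------

@dataclass
class Segment:
    """One constant-level stretch of a haplarithm series."""

    chromosome: str
    start: int  # series index, inclusive
    end: int  # series index, inclusive
    start_bp: int
    end_bp: int
    mean: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("segment start > end")
        if not np.isfinite(self.mean):
            raise ValueError("segment mean must be finite")

    @property
    def n_snps(self) -> int:
        return self.end - self.start + 1


def robust_sigma(values: np.ndarray) -> float:
    """Noise scale from the median absolute successive difference."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        return SIGMA_FLOOR
    d = np.diff(values)
    mad = np.median(np.abs(d - np.median(d)))
    return max(mad / (0.6744897501960817 * np.sqrt(2.0)), SIGMA_FLOOR)


def pcf_segment(
    series: Sequence[float],
    gamma: float,
    sigma: Optional[float] = None,
    positions: Optional[Sequence[int]] = None,
    chromosome: str = "",
) -> list[Segment]:
    """Exact least-squares segmentation with a per-breakpoint penalty.

    Minimizes ``sum_segments SSE/sigma^2 + gamma * (#breakpoints)`` by
    dynamic programming (O(n^2)); the optimum is exact and ties are broken
    toward fewer segments.  ``sigma`` defaults to a
    median-absolute-deviation estimate of the series noise, so ``gamma``
    is expressed in standardized units.
    """
    y = np.asarray(series, dtype=float)
    if y.ndim != 1 or len(y) == 0:
        raise ValueError("series must be a non-empty 1-D sequence")
    if not np.all(np.isfinite(y)):
        raise ValueError("series must be finite")
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    if sigma is None:
        sigma = robust_sigma(y)
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    n = len(y)
    s1 = np.concatenate(([0.0], np.cumsum(y)))
    s2 = np.concatenate(([0.0], np.cumsum(y * y)))
    inv = 1.0 / (sigma * sigma)

    # cost[j] = best cost of y[:j]; nseg[j] tie-break bookkeeping
    cost = np.empty(n + 1)
    nseg = np.empty(n + 1, dtype=int)
    back = np.empty(n + 1, dtype=int)
    cost[0], nseg[0], back[0] = -gamma, 0, 0
    lengths_all = np.arange(n + 1, dtype=float)
    for j in range(1, n + 1):
        i = np.arange(j)
        seg_sum = s1[j] - s1[i]
        seg_sq = s2[j] - s2[i]
        lengths = lengths_all[j - i]
        sse = seg_sq - seg_sum * seg_sum / lengths
        total = cost[i] + sse * inv + gamma
        k = int(np.argmin(total))
        best = total[k]
        # prefer fewer segments among (near-)ties
        ties = np.flatnonzero(total <= best + 1e-9)
        if len(ties) > 1:
            k = int(ties[np.argmin(nseg[ties])])
            best = total[k]
        cost[j], nseg[j], back[j] = best, nseg[k] + 1, k

    bounds = []
    j = n
    while j > 0:
        i = back[j]
        bounds.append((i, j - 1))
        j = i
    bounds.reverse()
    if positions is None:
        positions = np.arange(n)
    positions = np.asarray(positions)
    return [
        Segment(
            chromosome=chromosome,
            start=i,
            end=j,
            start_bp=int(positions[i]),
            end_bp=int(positions[j]),
            mean=float(y[i:j + 1].mean()),
        )
        for i, j in bounds
    ]


# ---------------------------------------------------------------------------
# Haplarithm assembly
# ---------------------------------------------------------------------------

@dataclass
class HaplarithmSeries:
    """One of the four phased BAF series on a chromosome."""

    name: str
    snp_index: np.ndarray  # global probe indices
    positions: np.ndarray
    baf: np.ndarray  # mirrored BAF values
    segments: list[Segment] = field(default_factory=list)
    informative: bool = True


@dataclass
class Haplarithm:
    """Paternal (P1, P2) and maternal (M1, M2) series for one chromosome."""

    chromosome: str
    series: dict[str, HaplarithmSeries]

    def informative(self, name: str) -> bool:
        s = self.series.get(name)
        return s is not None and s.informative


def build_haplarithm(
    quartet: TrioQuartet,
    target: str = "CV",
    gamma: float = DEFAULT_GAMMA,
    phase: Optional[PhaseResult] = None,
    min_snps: int = MIN_SNPS_PER_SERIES,
) -> dict[str, Haplarithm]:
    """Build per-chromosome haplarithms of the target tissue (CV or EM).

    The EM sample is interpreted against the CV-seeded parental phase.  A
    series with fewer than ``min_snps`` phased SNPs on a chromosome (or a
    chromosome whose target genotypes are all no-calls) is marked
    uninformative and carries no segments.
    """
    if target not in ("CV", "EM"):
        raise ValueError("target must be 'CV' or 'EM'")
    sample = quartet.cv if target == "CV" else quartet.em
    if sample is None:
        raise ValueError("quartet has no EM sample")
    if phase is None:
        phase = phase_with_seed(quartet)
    pm = quartet.probe_map
    out: dict[str, Haplarithm] = {}
    for chrom in pm.chromosomes():
        cmask = pm.chrom_mask(chrom)
        all_nc = bool(np.all(sample.genotype[cmask] == "NC"))
        series: dict[str, HaplarithmSeries] = {}
        for name in SERIES_NAMES:
            idx = np.flatnonzero(cmask & (phase.subcategory == name)
                                 & ~phase.inconsistent)
            baf = mirror_baf(sample.baf[idx], phase.mirror[idx])
            positions = pm.position[idx]
            s = HaplarithmSeries(name, idx, positions, baf)
            if all_nc or len(idx) < min_snps:
                s.informative = False
            else:
                s.segments = pcf_segment(
                    baf, gamma, positions=positions, chromosome=chrom
                )
            series[name] = s
        out[chrom] = Haplarithm(chrom, series)
    return out


def export_haplarithm_tsv(haplarithms: dict[str, Haplarithm], path) -> None:
    """Tidy per-SNP export (chromosome, position, series, baf, segment_mean)."""
    import pandas as pd

    rows = []
    for chrom, hap in haplarithms.items():
        for name, s in hap.series.items():
            seg_mean = np.full(len(s.baf), np.nan)
            for seg in s.segments:
                seg_mean[seg.start:seg.end + 1] = seg.mean
            for pos, b, m in zip(s.positions, s.baf, seg_mean):
                rows.append((chrom, int(pos), name, float(b), m))
    pd.DataFrame(
        rows, columns=["chromosome", "position", "series", "baf", "segment_mean"]
    ).to_csv(path, sep="\t", index=False)
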