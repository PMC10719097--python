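"""Aberration calling from parental haplarithms.

Copy state and parental origin follow from the joint pattern of the
paternal band separation d_pat = |P1 - P2|, the maternal separation
d_mat = |M1 - M2| and the interval mean logR.  With the CV-seeded phase
the P1/M1 bands of a clean disomy sit at 0 and the P2/M2 bands at 0.5, so
the heterozygous-band shift Delta = |band - 0.5| carries the mosaic
fraction f of the aberrant cell line:

    gain (trisomy):      band (1+f)/(2+f)  ->  f = 4*Delta/(1 - 2*Delta)
    loss (monosomy):     band (1-f)/(2-f)  ->  f = 4*Delta/(1 + 2*Delta)
    isodisomic UPD:      band (1+-f)/2     ->  f = 2*Delta

A maternal-origin imbalance displaces the *paternal* series (the mother is
homozygous at paternal-informative SNPs, so those SNPs report the maternal
copy count cleanly) and vice versa; losses are labelled with the parent
whose homolog is lost.  The segregational origin of a gain is read from
the gaining parent's own series around the centromere: both parental
homologs present (BPH, band above 0.5) at the centromere indicates a
meiosis I error, BPH only distal to a crossover indicates meiosis II, and
a single homolog (SPH) along the whole chromosome indicates a mitotic
error.  Non-mosaic losses and isodisomies Mendelianly exclude the
heterozygous-band SNPs altogether; such chromosomes are recognised by
series depletion plus genotype collapse and the retained parent is
identified by genotype concordance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .arrayio import TrioQuartet
from .core import (
    DEFAULT_GAMMA,
    Haplarithm,
    MIN_SNPS_PER_SERIES,
    PhaseResult,
    build_haplarithm,
    pcf_segment,
    phase_with_seed,
)
from .genome import AUTOSOMES, CENTROMERES, CHROM_LENGTHS

# Template-matching tolerances: band units and logR units.
TOL_D = 0.08
TOL_LOGR = 0.15
# Minimum band deviation / logR deviation that triggers a candidate call.
D_TRIGGER = 0.025
LOGR_TRIGGER = 0.10
# Calls below this mosaic fraction are suppressed (stated sensitivity floor).
MIN_MOSAIC_FRACTION = 0.10
# Minimum span and informative SNPs for a segmental candidate.
MIN_SEGMENT_BP = 100_000
MIN_SEGMENT_SNPS = 20
# Share of a chromosome's probe span above which a call is 'chromosomal'.
WHOLE_CHROM_SHARE = 0.90
# Autosome count sharing one signature that promotes it to genome-wide.
GENOME_WIDE_AUTOSOMES = 20
# Depletion threshold on the P2/M2 SNP share (expected ~0.5 in disomy).
DEPLETION_SHARE = 0.15
# Complete-maternal-contamination thresholds.
CONTAMINATION_FLAG_C = 0.95
CONTAMINATION_FLAG_CONCORDANCE = 0.95


@dataclass
class DValues:
    """Band separations and mean logR over one interval."""

    d_pat: float  # |P1 - P2|, NaN if ND
    d_mat: float  # |M1 - M2|, NaN if ND
    mean_logr: float
    levels: dict = field(default_factory=dict)  # per-series band level
    counts: dict = field(default_factory=dict)  # per-series SNPs in interval
    segment_levels: dict = field(default_factory=dict)  # per-series
    #   [(segment mean, SNPs in interval), ...] for structure checks


@dataclass
class AberrationCall:
    """One genomic imbalance with its full annotation."""

    chromosome: str
    start: int  # bp, 1-based inclusive
    end: int
    size_class: str  # segmental | chromosomal | genome_wide
    copy_state: str  # gain | loss | neutral_UPD
    parental_origin: str  # maternal | paternal | ND
    segregational_origin: str  # MI | MII | mitotic | ND
    mosaic_fraction: float
    tissue: str  # CV | EM
    evidence: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.mosaic_fraction <= 1.0:
            raise ValueError("mosaic_fraction must lie in [0, 1]")
        if self.size_class == "segmental" and self.end - self.start + 1 < MIN_SEGMENT_BP:
            raise ValueError("segmental calls must span >= 100 kb")


@dataclass
class CentromereMap:
    """Per-chromosome centromere coordinate."""

    positions: dict[str, int] = field(default_factory=lambda: dict(CENTROMERES))

    def __post_init__(self) -> None:
        for chrom, pos in self.positions.items():
            if not 1 <= pos <= CHROM_LENGTHS.get(chrom, pos):
                raise ValueError(f"centromere outside chromosome {chrom}")

    def __getitem__(self, chrom: str) -> int:
        return self.positions[chrom]


# ---------------------------------------------------------------------------
# d values
# ---------------------------------------------------------------------------

def _series_level(series, start: int, end: int) -> tuple[float, int, list]:
    """Median fitted level, SNP count and per-segment (mean, n) within
    [start, end] of one series."""
    if series is None or not series.informative:
        return math.nan, 0, []
    sel = (series.positions >= start) & (series.positions <= end)
    count = int(sel.sum())
    if count == 0:
        return math.nan, 0, []
    per_snp = np.full(len(series.baf), np.nan)
    seg_levels = []
    for seg in series.segments:
        per_snp[seg.start:seg.end + 1] = seg.mean
        n_in = int(sel[seg.start:seg.end + 1].sum())
        if n_in > 0:
            seg_levels.append((float(seg.mean), n_in))
    vals = per_snp[sel]
    vals = vals[np.isfinite(vals)]
    if len(vals) == 0:
        return math.nan, count, seg_levels
    return float(np.median(vals)), count, seg_levels


def compute_d_values(
    haplarithm: Haplarithm,
    interval: tuple[int, int],
    logr_values: Optional[np.ndarray] = None,
    logr_positions: Optional[np.ndarray] = None,
) -> DValues:
    """Band separations d_pat/d_mat and mean logR within an interval.

    Each parental d is the separation of its two fitted band levels; with
    one band only the separation is 0, and with no informative band the d
    is ND (NaN).
    """
    start, end = interval
    levels: dict[str, float] = {}
    counts: dict[str, int] = {}
    seg_levels: dict[str, list] = {}
    for name in ("P1", "P2", "M1", "M2"):
        levels[name], counts[name], seg_levels[name] = _series_level(
            haplarithm.series.get(name), start, end
        )
    ds = {}
    for d_name, a, b in (("d_pat", "P1", "P2"), ("d_mat", "M1", "M2")):
        la, lb = levels[a], levels[b]
        if math.isnan(la) and math.isnan(lb):
            ds[d_name] = math.nan
        elif math.isnan(la) or math.isnan(lb):
            ds[d_name] = 0.0  # one band only
        else:
            ds[d_name] = abs(la - lb)
    mean_logr = math.nan
    if logr_values is not None:
        sel = (logr_positions >= start) & (logr_positions <= end)
        if sel.any():
            mean_logr = float(np.mean(logr_values[sel]))
    return DValues(ds["d_pat"], ds["d_mat"], mean_logr, levels, counts,
                   seg_levels)


# ---------------------------------------------------------------------------
# Copy-state classification
# ---------------------------------------------------------------------------

def expected_bands(state: str, origin: str, f: float, extra: int = 1):
    """Template (d_pat, d_mat, logR) for a state at mosaic fraction f.

    Derived by allele-count enumeration of the mixture bands; ``extra`` is
    the number of extra copies for gains (1 = trisomy, 2 = tetrasomy).
    The d of the gaining parent's own series assumes SPH (see module
    docstring).
    """
    k = extra
    if state == "gain":
        d_other = (1 + k * f) / (2 + k * f)
        d_own = 1 / (2 + k * f)
        logr = math.log2((2 + k * f) / 2)
    elif state == "loss":
        d_own = 1 / (2 - f)  # the LOST parent's series rises
        d_other = (1 - f) / (2 - f)
        logr = math.log2((2 - f) / 2)
    elif state == "neutral_UPD":
        d_other = (1 + f) / 2
        d_own = (1 - f) / 2
        logr = 0.0
    elif state == "disomy":
        return 0.5, 0.5, 0.0
    else:
        raise ValueError(f"unknown state {state!r}")
    # d_own belongs to the origin parent's series, d_other to the other's
    if origin == "maternal":
        return d_other, d_own, logr
    return d_own, d_other, logr


def _mosaic_from_clean_d(state: str, origin: str, dvals: DValues,
                         extra: int = 1) -> float:
    """Invert the band templates for the mosaic fraction.

    Delta is measured on the heterozygous-band (P2/M2) levels only: the
    homozygous bands at 0 are biased upward by BAF clipping under noise,
    whereas the displaced 0.5-bands are unbiased.
    """
    lv = dvals.levels
    rising = {
        ("gain", "maternal"): "P2", ("gain", "paternal"): "M2",
        ("loss", "maternal"): "M2", ("loss", "paternal"): "P2",
        ("neutral_UPD", "maternal"): "P2", ("neutral_UPD", "paternal"): "M2",
    }[(state, origin)]
    falling = "M2" if rising == "P2" else "P2"
    deltas = [lv[rising] - 0.5]
    if state != "gain" and not math.isnan(lv.get(falling, math.nan)):
        deltas.append(0.5 - lv[falling])
    delta = float(np.mean(deltas))
    if state == "gain":
        f = (4 if extra == 1 else 2) * delta / max(1 - 2 * delta, 1e-9)
    elif state == "loss":
        f = 4 * delta / (1 + 2 * delta)
    else:  # neutral_UPD
        f = 2 * delta
    return float(np.clip(f, 0.0, 1.0))


def classify_copy_state(
    dvals: DValues,
    tol_d: float = TOL_D,
    tol_logr: float = TOL_LOGR,
) -> tuple[str, str, float, int]:
    """Nearest-template classification of one interval.

    Returns ``(copy_state, parental_origin, mosaic_fraction, extra_copies)``
    with ``("disomy", "", 0.0, 0)`` for no call and ``("ND", "ND", nan, 0)``
    when no template lies within tolerance.
    """
    d_pat, d_mat, logr = dvals.d_pat, dvals.d_mat, dvals.mean_logr
    if math.isnan(d_pat) and math.isnan(d_mat):
        return "ND", "ND", math.nan, 0

    have_logr = not math.isnan(logr)
    deviates = False
    for d in (d_pat, d_mat):
        if not math.isnan(d) and abs(d - 0.5) > D_TRIGGER:
            deviates = True
    if have_logr and abs(logr) > LOGR_TRIGGER:
        deviates = True
    if not deviates:
        return "disomy", "", 0.0, 0

    def share1(side: str) -> float:
        a = dvals.counts.get(side + "1", 0)
        b = dvals.counts.get(side + "2", 0)
        return a / (a + b) if (a + b) else math.nan

    def seg_means(name: str, min_snps: int = 10) -> list[float]:
        return [m for m, n in dvals.segment_levels.get(name, []) if n >= min_snps]

    candidates = []
    for state in ("gain", "loss", "neutral_UPD"):
        for origin in ("maternal", "paternal"):
            for extra in (1, 2) if state == "gain" else (1,):
                # the series whose "2"-band rises and carries the clean signal
                rising = {
                    ("gain", "maternal"): "P",
                    ("gain", "paternal"): "M",
                    ("loss", "maternal"): "M",
                    ("loss", "paternal"): "P",
                    ("neutral_UPD", "maternal"): "P",
                    ("neutral_UPD", "paternal"): "M",
                }[(state, origin)]
                clean = d_pat if rising == "P" else d_mat
                if math.isnan(clean) or clean <= 0.5:
                    continue
                f = _mosaic_from_clean_d(state, origin, dvals, extra)
                if f <= 0:
                    continue
                e_pat, e_mat, e_logr = expected_bands(state, origin, f, extra)
                e_rise = e_pat if rising == "P" else e_mat
                errs = [abs(clean - (e_rise))/ tol_d]
                other_d = d_mat if rising == "P" else d_pat
                e_other = e_mat if rising == "P" else e_pat
                if state != "gain" and not math.isnan(other_d):
                    errs.append(abs(other_d - e_other) / tol_d)
                if have_logr:
                    errs.append(abs(logr - e_logr) / tol_logr)
                err = max(errs) if errs else math.inf
                if err > 1.0:
                    continue
                # the rising "2" band must be uniform at its template level
                rise_band = (1 + extra * f) / (2 + extra * f) if state == "gain" \
                    else (1 / (2 - f) if state == "loss" else (1 + f) / 2)
                rise_levels = seg_means(rising + "2")
                if rise_levels and max(
                    abs(m - rise_band) for m in rise_levels
                ) > 1.5 * tol_d:
                    continue
                if state == "gain":
                    # the gaining parent's own series must show SPH
                    # (band at 1/(2+kf)), BPH structure (sub-0.5 segments
                    # absent but "1"-band depleted), or a mix
                    own = "M" if origin == "maternal" else "P"
                    own_share = share1(own)
                    own_levels = seg_means(own + "2")
                    sph_band = 1 / (2 + extra * f)
                    own_ok = (
                        (not math.isnan(own_share) and own_share < 0.40)
                        or any(abs(m - sph_band) <= 1.5 * tol_d
                               for m in own_levels)
                        or not own_levels
                    )
                    if not own_ok:
                        continue
                candidates.append((err, state, origin, f, extra))
    if not candidates:
        return "ND", "ND", math.nan, 0
    err, state, origin, f, extra = min(candidates, key=lambda c: c[0])
    return state, origin, f, extra


def estimate_mosaic_fraction(het_band_shift: float, copy_state: str) -> float:
    """Mosaic fraction from the heterozygous-band shift Delta.

    Delta is |band level - 0.5| measured on heterozygous-informative SNPs
    within the called interval; the closed forms invert the allele-count
    mixture bands.  The result is clipped to [0, 1].
    """
    delta = float(het_band_shift)
    aliases = {"trisomy": "gain", "monosomy": "loss", "upd": "neutral_UPD"}
    state = aliases.get(copy_state, copy_state)
    if not 0.0 <= delta <= 0.5:
        raise ValueError("het band shift must lie in [0, 0.5]")
    if state == "gain":
        if delta >= 0.5:
            raise ValueError("Delta >= 0.5 is impossible for a gain")
        f = 4 * delta / (1 - 2 * delta)
    elif state == "loss":
        f = 4 * delta / (1 + 2 * delta)
    elif state == "neutral_UPD":
        f = 2 * delta
    else:
        raise ValueError(f"unknown copy state {copy_state!r}")
    return float(np.clip(f, 0.0, 1.0))


# ---------------------------------------------------------------------------
# Segregational origin
# ---------------------------------------------------------------------------

def infer_segregational_origin(
    haplarithm: Haplarithm,
    call: AberrationCall,
    centromeres: Optional[CentromereMap] = None,
    min_region_snps: int = 10,
    bph_margin: float = 0.03,
) -> str:
    """MI / MII / mitotic from the gaining parent's series.

    Within the gaining parent's heterozygous-band series, segments above
    0.5 mark regions where both of that parent's homologs are present
    (BPH) and segments below 0.5 mark a single homolog (SPH).  BPH at the
    centromere indicates meiosis I, BPH only distal to a crossover
    meiosis II, SPH throughout a mitotic (post-zygotic) event.  Losses and
    isodisomies are SPH by construction and labelled mitotic; an
    uninformative series yields ND.
    """
    if call.parental_origin not in ("maternal", "paternal"):
        return "ND"
    if call.copy_state in ("loss", "neutral_UPD"):
        return "mitotic"
    if centromeres is None:
        centromeres = CentromereMap()
    own = "M2" if call.parental_origin == "maternal" else "P2"
    series = haplarithm.series.get(own)
    if series is None or not series.informative:
        return "ND"
    cen = centromeres[call.chromosome]
    bph_regions = []
    sph_regions = []
    for seg in series.segments:
        if seg.end_bp < call.start or seg.start_bp > call.end:
            continue
        if seg.n_snps < min_region_snps:
            continue
        if seg.mean > 0.5 + bph_margin:
            bph_regions.append(seg)
        elif seg.mean < 0.5 - bph_margin:
            sph_regions.append(seg)
    if not bph_regions and not sph_regions:
        return "ND"
    # MI-type full-BPH chromosomes may leave the "1"-band series empty; the
    # centromere test below handles both mixed and pure patterns.
    for seg in bph_regions:
        if seg.start_bp <= cen <= seg.end_bp:
            return "MI"
    if bph_regions:
        # flanking case: centromere falls between informative SNPs
        left = max((s for s in bph_regions if s.end_bp < cen),
                   key=lambda s: s.end_bp, default=None)
        right = min((s for s in bph_regions if s.start_bp > cen),
                    key=lambda s: s.start_bp, default=None)
        nearer_sph = any(
            s.start_bp <= cen <= s.end_bp for s in sph_regions
        )
        if not nearer_sph and (left or right):
            gap_ok = False
            for cand in (left, right):
                if cand is None:
                    continue
                between = [
                    s for s in sph_regions
                    if (cand.end_bp < s.start_bp <= cen
                        or cen <= s.end_bp < cand.start_bp)
                ]
                if not between:
                    gap_ok = True
            if gap_ok:
                return "MI"
        return "MII"
    return "mitotic"


# ---------------------------------------------------------------------------
# Maternal-cell contamination
# ---------------------------------------------------------------------------

def estimate_maternal_contamination(
    quartet: TrioQuartet,
    target: str = "CV",
    grid_step: float = 0.01,
    trim: float = 0.10,
) -> tuple[float, bool, str]:
    """Grid-search estimate of the maternal-DNA fraction in a fetal sample.

    At parental-informative SNPs the observed BAF clusters are a known
    function of the contamination fraction c (e.g. the paternal-informative
    heterozygous cluster moves from 0.5 to (1-c)/2 when the mother is AA).
    The estimate minimises the trimmed squared distance to the nearest
    predicted cluster over c in [0, 1].  Returns ``(c_hat, complete_flag,
    note)``; the flag fires when c_hat exceeds 0.95 and the target
    genotypes match the mother's.
    """
    sample = quartet.cv if target == "CV" else quartet.em
    if sample is None:
        raise ValueError("quartet has no EM sample")
    m_gt, f_gt = quartet.mother.genotype, quartet.father.genotype
    auto = np.isin(quartet.probe_map.chromosome, AUTOSOMES)
    pat = auto & (f_gt == "AB") & np.isin(m_gt, ("AA", "BB"))
    mat = auto & (m_gt == "AB") & np.isin(f_gt, ("AA", "BB"))
    baf_p = sample.baf[pat]
    hom_p = (m_gt[pat] == "BB").astype(float)  # maternal allele as 0/1
    baf_m = sample.baf[mat]

    cs = np.arange(0.0, 1.0 + 1e-9, grid_step)
    scores = np.empty(len(cs))
    for i, c in enumerate(cs):
        # paternal-informative: child is hom (at the maternal allele, which
        # contamination does not move) or het (0.5 pulled toward it)
        hom_cluster = hom_p
        het_cluster = (1 - c) * 0.5 + c * hom_p
        d_p = np.minimum(
            (baf_p - hom_cluster) ** 2, (baf_p - het_cluster) ** 2
        )
        # maternal-informative: maternal signal is het (0.5)
        lo = c * 0.5
        hi = 1 - c * 0.5
        d_m = np.minimum.reduce(
            [(baf_m - lo) ** 2, (baf_m - 0.5) ** 2, (baf_m - hi) ** 2]
        )
        resid = np.concatenate([d_p, d_m])
        if trim > 0 and len(resid) > 20:
            cut = np.quantile(resid, 1 - trim)
            resid = resid[resid <= cut]
        scores[i] = resid.mean() if len(resid) else np.inf
    c_hat = float(cs[int(np.argmin(scores))])
    if c_hat >= 0.85:
        # near-complete contamination leaves the objective almost flat
        # near c = 1; resolve near-ties toward the larger c
        best = scores.min()
        c_hat = float(cs[np.flatnonzero(scores <= best * 1.05 + 1e-9)].max())

    both = (sample.genotype != "NC") & (m_gt != "NC")
    concordance = float(
        np.mean(sample.genotype[both] == m_gt[both])) if both.any() else 0.0
    flag = (c_hat >= CONTAMINATION_FLAG_C - 1e-9
            and concordance > CONTAMINATION_FLAG_CONCORDANCE)
    note = (
        f"c_hat={c_hat:.2f} from {int(pat.sum() + mat.sum())} informative "
        f"SNPs; mother-concordance={concordance:.2f}"
    )
    if flag:
        note += "; complete maternal contamination - sample excluded"
    return c_hat, flag, note


# ---------------------------------------------------------------------------
# Degenerate (non-mosaic loss / isodisomy) route
# ---------------------------------------------------------------------------

def _het_band(state: str, origin: str, f: float, side: str) -> float:
    """Raw heterozygous-band position at informative SNPs (hom parent AA).

    ``side`` is 'P' for paternal-informative SNPs (mother homozygous) or
    'M' for maternal-informative; the band mirrors to 1-x when the
    homozygous parent is BB.
    """
    own = (origin == "maternal") == (side == "M")
    if state == "loss":
        # own = the lost parent's informative side
        return (1 - f) / (2 - f) if own else 1 / (2 - f)
    if state == "neutral_UPD":
        return (1 + f) / 2 if own else (1 - f) / 2
    raise ValueError(state)


def _fit_loss_upd(
    quartet: TrioQuartet, sample, chrom: str, state: str,
    interval: Optional[tuple[int, int]] = None,
) -> tuple[str, float, float]:
    """Joint (origin, mosaic fraction) fit for a loss or isodisomy.

    Fits the raw BAF of all informative SNPs on the chromosome against the
    allele-count cluster model of the state, avoiding the no-call
    selection bias that hits phased series at intermediate fractions.
    Returns (origin, f, mean squared residual).
    """
    pm = quartet.probe_map
    cmask = pm.chrom_mask(chrom)
    if interval is not None:
        cmask = cmask & (pm.position >= interval[0]) \
            & (pm.position <= interval[1])
    m_gt, f_gt = quartet.mother.genotype, quartet.father.genotype
    pat = cmask & (f_gt == "AB") & np.isin(m_gt, ("AA", "BB"))
    mat = cmask & (m_gt == "AB") & np.isin(f_gt, ("AA", "BB"))
    baf_p, hom_p = sample.baf[pat], (m_gt[pat] == "BB").astype(float)
    baf_m, hom_m = sample.baf[mat], (f_gt[mat] == "BB").astype(float)
    best = ("ND", math.nan, math.inf)
    for origin in ("maternal", "paternal"):
        for f in np.arange(0.0, 1.0 + 1e-9, 0.01):
            xp = _het_band(state, origin, f, "P")
            xm = _het_band(state, origin, f, "M")
            # clusters: hom band at the hom parent's allele, het band
            # mirrored around 0.5 when that allele is B
            dp = np.minimum(
                (baf_p - hom_p) ** 2,
                (baf_p - (hom_p + (1 - 2 * hom_p) * xp)) ** 2,
            )
            dm = np.minimum(
                (baf_m - hom_m) ** 2,
                (baf_m - (hom_m + (1 - 2 * hom_m) * xm)) ** 2,
            )
            resid = np.concatenate([dp, dm])
            if len(resid) > 40:
                resid = resid[resid <= np.quantile(resid, 0.95)]
            score = float(resid.mean()) if len(resid) else math.inf
            if score < best[2]:
                best = (origin, float(f), score)
    return best


def _genotype_route(
    quartet: TrioQuartet, sample, chrom: str, dvals: DValues,
    interval: Optional[tuple[int, int]] = None,
) -> Optional[tuple[str, str, float]]:
    """Recognise high-fraction losses and isodisomies from genotype collapse.

    High-fraction losses/UPDs Mendelianly exclude (or push into the
    no-call zone) the heterozygous-band SNPs, leaving both P2 and M2
    series depleted; the copy state follows from logR and the parent and
    fraction from a cluster-model fit of the raw BAF.
    """
    counts = dvals.counts
    tot_p = counts["P1"] + counts["P2"]
    tot_m = counts["M1"] + counts["M2"]
    if tot_p < MIN_SNPS_PER_SERIES or tot_m < MIN_SNPS_PER_SERIES:
        return None
    share_p = counts["P2"] / tot_p
    share_m = counts["M2"] / tot_m
    if min(share_p, share_m) > 2 * DEPLETION_SHARE or \
            max(share_p, share_m) > 0.45:
        return None
    pm = quartet.probe_map
    cmask = pm.chrom_mask(chrom)
    if interval is not None:
        cmask = cmask & (pm.position >= interval[0]) \
            & (pm.position <= interval[1])
    s_gt = sample.genotype
    het = cmask & (s_gt == "AB")
    called = cmask & (s_gt != "NC")
    het_share = het.sum() / max(called.sum(), 1)
    if het_share > 0.25:
        return None
    logr = dvals.mean_logr
    if math.isnan(logr):
        return None
    if logr < -0.25:
        state = "loss"
    elif abs(logr) <= 0.2:
        state = "neutral_UPD"
    else:
        return None
    origin, f, score = _fit_loss_upd(quartet, sample, chrom, state, interval)
    if not math.isfinite(score):
        return None
    if state == "loss":
        # parent_of_origin labels the LOST parent (already from the fit)
        f_logr = float(np.clip(2.0 - 2.0 ** (1.0 + logr), 0.0, 1.0))
        if abs(f - f_logr) > 0.25:
            return None
    return state, origin, f


# ---------------------------------------------------------------------------
# End-to-end calling
# ---------------------------------------------------------------------------

def _merge_spans(spans: list[tuple[int, int]], gap: int) -> list[tuple[int, int]]:
    if not spans:
        return []
    spans = sorted(spans)
    merged = [list(spans[0])]
    for s, e in spans[1:]:
        if s <= merged[-1][1] + gap:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _call_interval(
    quartet: TrioQuartet,
    sample,
    haplarithm: Haplarithm,
    chrom: str,
    interval: tuple[int, int],
    tissue: str,
    centromeres: CentromereMap,
    size_class: str,
) -> Optional[AberrationCall]:
    pm = quartet.probe_map
    cidx = pm.chrom_indices(chrom)
    pos = pm.position[cidx]
    dvals = compute_d_values(
        haplarithm, interval, sample.logr[cidx], pos
    )
    state, origin, f, extra = classify_copy_state(dvals)
    evidence = {
        "d_pat": None if math.isnan(dvals.d_pat) else round(dvals.d_pat, 4),
        "d_mat": None if math.isnan(dvals.d_mat) else round(dvals.d_mat, 4),
        "mean_logr": None if math.isnan(dvals.mean_logr)
        else round(dvals.mean_logr, 4),
        "snp_counts": dvals.counts,
    }
    if state in ("disomy",):
        return None
    if state == "ND":
        degenerate = _genotype_route(quartet, sample, chrom, dvals, interval)
        if degenerate is None:
            return None
        state, origin, f = degenerate
        extra = 1
        evidence["route"] = "genotype_collapse"
    else:
        evidence["route"] = "band_template"
        evidence["extra_copies"] = extra
    if f < MIN_MOSAIC_FRACTION:
        return None
    call = AberrationCall(
        chromosome=chrom,
        start=interval[0],
        end=interval[1],
        size_class=size_class,
        copy_state=state,
        parental_origin=origin,
        segregational_origin="ND",
        mosaic_fraction=round(float(f), 4),
        tissue=tissue,
        evidence=evidence,
    )
    call.segregational_origin = infer_segregational_origin(
        haplarithm, call, centromeres
    )
    return call


def call_aberrations(
    quartet: TrioQuartet,
    gamma: float = DEFAULT_GAMMA,
    centromeres: Optional[CentromereMap] = None,
    check_contamination: bool = True,
) -> tuple[list[AberrationCall], dict]:
    """Call aberrations in CV and EM; returns (calls, report).

    The report records the contamination estimate and exclusion flag per
    tissue.  A tissue flagged as complete maternal contamination yields no
    calls.
    """
    if centromeres is None:
        centromeres = CentromereMap()
    pm = quartet.probe_map
    report: dict = {"tissues": {}}
    calls: list[AberrationCall] = []
    phase: Optional[PhaseResult] = None

    tissues = [("CV", quartet.cv)]
    if quartet.em is not None:
        tissues.append(("EM", quartet.em))
    for tissue, sample in tissues:
        if check_contamination:
            c_hat, flagged, note = estimate_maternal_contamination(
                quartet, tissue
            )
        else:
            c_hat, flagged, note = 0.0, False, "contamination check skipped"
        report["tissues"][tissue] = {
            "maternal_contamination": c_hat,
            "excluded": flagged,
            "note": note,
        }
        if flagged:
            continue
        if phase is None:
            phase = phase_with_seed(quartet)
        haplarithms = build_haplarithm(
            quartet, tissue, gamma=gamma, phase=phase
        )
        tissue_calls: list[AberrationCall] = []
        for chrom in pm.chromosomes():
            hap = haplarithms[chrom]
            cidx = pm.chrom_indices(chrom)
            pos = pm.position[cidx]
            span = (int(pos[0]), int(pos[-1]))
            whole = _call_interval(
                quartet, sample, hap, chrom, span, tissue, centromeres,
                "chromosomal",
            )
            if whole is not None:
                tissue_calls.append(whole)
                continue
            # segmental candidates from deviating series / logR segments
            spans: list[tuple[int, int]] = []
            for name in ("P2", "M2"):
                s = hap.series.get(name)
                if s is None or not s.informative:
                    continue
                for seg in s.segments:
                    if (
                        abs(seg.mean - 0.5) > D_TRIGGER + 0.005
                        and seg.n_snps >= MIN_SEGMENT_SNPS
                        and seg.end_bp - seg.start_bp + 1 >= MIN_SEGMENT_BP
                    ):
                        spans.append((seg.start_bp, seg.end_bp))
            logr_segs = pcf_segment(
                sample.logr[cidx], gamma, positions=pos, chromosome=chrom
            )
            for seg in logr_segs:
                if (
                    abs(seg.mean) > LOGR_TRIGGER
                    and seg.n_snps >= MIN_SEGMENT_SNPS
                    and seg.end_bp - seg.start_bp + 1 >= MIN_SEGMENT_BP
                ):
                    spans.append((seg.start_bp, seg.end_bp))
            median_gap = int(np.median(np.diff(pos))) if len(pos) > 1 else 1
            for s, e in _merge_spans(spans, gap=3 * median_gap):
                share = (e - s + 1) / (span[1] - span[0] + 1)
                size_class = "chromosomal" if share >= WHOLE_CHROM_SHARE \
                    else "segmental"
                cand = _call_interval(
                    quartet, sample, hap, chrom, (s, e), tissue, centromeres,
                    size_class,
                )
                if cand is not None:
                    tissue_calls.append(cand)
        calls.extend(_promote_genome_wide(tissue_calls, tissue))
    return calls, report


def _promote_genome_wide(
    calls: list[AberrationCall], tissue: str
) -> list[AberrationCall]:
    """Collapse a shared >=20-autosome gain signature into one call."""
    chromosomal_gains = [
        c for c in calls
        if c.copy_state == "gain" and c.size_class == "chromosomal"
        and c.chromosome in AUTOSOMES
    ]
    by_origin: dict[str, list[AberrationCall]] = {}
    for c in chromosomal_gains:
        by_origin.setdefault(c.parental_origin, []).append(c)
    for origin, group in by_origin.items():
        if len(group) >= GENOME_WIDE_AUTOSOMES:
            member_chroms = {c.chromosome for c in group}
            rest = [c for c in calls if c not in group]
            gw = AberrationCall(
                chromosome="ALL",
                start=1,
                end=1,
                size_class="genome_wide",
                copy_state="gain",
                parental_origin=origin,
                segregational_origin=_majority(
                    [c.segregational_origin for c in group]
                ),
                mosaic_fraction=round(float(np.median(
                    [c.mosaic_fraction for c in group]
                )), 4),
                tissue=tissue,
                evidence={
                    "chromosomes": sorted(member_chroms, key=_chrom_key),
                    "n_autosomes": len(member_chroms),
                },
            )
            return rest + [gw]
    return calls


def _majority(labels: Sequence[str]) -> str:
    vals, counts = np.unique(np.asarray(labels, dtype=object), return_counts=True)
    return str(vals[int(np.argmax(counts))])


def _chrom_key(c: str):
    return (0, int(c)) if c.isdigit() else (1, c)
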