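"""Synthetic family-quartet simulator with known ground truth.

Generates mother/father/CV/EM SNP-array data for a product of conception
carrying a configurable chromosomal aberration: whole-chromosome trisomy or
monosomy (meiosis I, meiosis II or mitotic origin), segmental gains/losses,
isodisomic uniparental disomy, triploidy and tetrasomy, each with
tissue-specific mosaic fractions, additive Gaussian BAF/logR noise and
optional maternal-cell contamination.

The signal model is an allele-count mixture: for a SNP covered by cell
lines with mixture fractions w_k, the noise-free B-allele frequency is
(sum_k w_k * B_k) / (sum_k w_k * N_k) where B_k/N_k are the B-allele and
total copy counts of line k, and logR is log2 of the weighted mean copy
number over 2.  A fully trisomic heterozygous SNP with two B copies
therefore sits at 2/3 and its chromosome at logR = log2(3/2) ~ 0.58.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from . import arrayio
from .genome import AUTOSOMES, CENTROMERES, CHROM_LENGTHS, CHROMOSOMES

# Genotype-call bands applied to the noise-free BAF.  The heterozygous band
# is wide enough to cover polysomic allelic ratios (1/3, 2/3, 1/4, 3/4),
# which production cluster-based callers genotype as AB.
GT_AA_MAX = 0.15
GT_BB_MIN = 0.85
GT_AB_LO = 0.25
GT_AB_HI = 0.75

ABERRATION_TYPES = (
    "trisomy", "monosomy", "segmental_gain", "segmental_loss",
    "upd_iso", "triploidy", "tetrasomy", "none",
)
SEGREGATIONAL_ORIGINS = ("MI", "MII", "mitotic")
_ROLE_SEEDS = {"mother": 11, "father": 12, "CV": 13, "EM": 14}


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ProbeMap:
    """The shared SNP scaffold: id, chromosome, 1-based position, MAF."""

    probe_id: np.ndarray
    chromosome: np.ndarray
    position: np.ndarray
    pop_baf: np.ndarray

    def __post_init__(self) -> None:
        self.probe_id = np.asarray(self.probe_id, dtype=object)
        self.chromosome = np.asarray(self.chromosome, dtype=object)
        self.position = np.asarray(self.position, dtype=np.int64)
        self.pop_baf = np.asarray(self.pop_baf, dtype=float)
        n = len(self.probe_id)
        if n == 0:
            raise ValueError("probe map is empty")
        if not (len(self.chromosome) == len(self.position) == len(self.pop_baf) == n):
            raise ValueError("probe map field lengths differ")
        if len(set(self.probe_id)) != n:
            raise ValueError("probe ids are not unique")
        if self.pop_baf.min() < 0 or self.pop_baf.max() > 1:
            raise ValueError("pop_baf must lie in [0, 1]")
        for chrom in self.chromosomes():
            pos = self.position[self.chrom_mask(chrom)]
            if np.any(np.diff(pos) <= 0):
                raise ValueError(
                    f"positions not strictly increasing on chromosome {chrom}"
                )

    def __len__(self) -> int:
        return len(self.probe_id)

    def chromosomes(self) -> list[str]:
        seen = dict.fromkeys(self.chromosome)
        return [c for c in CHROMOSOMES if c in seen]

    def chrom_mask(self, chrom: str) -> np.ndarray:
        return self.chromosome == chrom

    def chrom_indices(self, chrom: str) -> np.ndarray:
        return np.flatnonzero(self.chrom_mask(chrom))


def make_probe_map(
    snps_per_chrom: int = 2000,
    chromosomes: Sequence[str] = CHROMOSOMES,
    pop_baf: float = 0.5,
) -> ProbeMap:
    """Evenly spaced scaffold over the requested chromosomes.

    The default (2,000 SNPs per chromosome, population B-allele frequency
    0.5 everywhere) is a reduced-density stand-in for a genome-wide
    genotyping array that keeps every simulation desk-scale.
    """
    ids, chroms, pos, baf = [], [], [], []
    for chrom in chromosomes:
        length = CHROM_LENGTHS[chrom]
        p = np.unique(np.linspace(1, length, snps_per_chrom).astype(np.int64))
        ids.extend(f"rs{chrom}_{i}" for i in range(len(p)))
        chroms.extend([chrom] * len(p))
        pos.append(p)
        baf.append(np.full(len(p), pop_baf))
    return ProbeMap(
        probe_id=np.array(ids, dtype=object),
        chromosome=np.array(chroms, dtype=object),
        position=np.concatenate(pos),
        pop_baf=np.concatenate(baf),
    )


@dataclass
class ParentalGenome:
    """Two phased haplotypes (H1, H2) per chromosome over a probe map."""

    probe_map: ProbeMap
    haplotypes: dict[str, np.ndarray]  # chrom -> (2, n) uint8, 0=A 1=B

    def __post_init__(self) -> None:
        for chrom, hap in self.haplotypes.items():
            n = len(self.probe_map.chrom_indices(chrom))
            if hap.shape != (2, n):
                raise ValueError(
                    f"haplotype shape {hap.shape} != (2, {n}) on chromosome {chrom}"
                )


@dataclass
class AberrationSpec:
    """Ground-truth description of one genomic aberration."""

    type: str = "none"
    chromosome: Optional[str] = None
    interval: Optional[tuple[int, int]] = None  # 1-based inclusive
    parent_of_origin: str = "maternal"
    segregational_origin: str = "mitotic"
    mosaic_fraction_em: float = 1.0
    mosaic_fraction_cv: float = 1.0

    def __post_init__(self) -> None:
        if self.type not in ABERRATION_TYPES:
            raise ValueError(f"unknown aberration type {self.type!r}")
        if self.type != "none":
            if self.parent_of_origin not in ("maternal", "paternal"):
                raise ValueError("parent_of_origin must be maternal or paternal")
            if self.segregational_origin not in SEGREGATIONAL_ORIGINS:
                raise ValueError("invalid segregational_origin")
        for f in (self.mosaic_fraction_em, self.mosaic_fraction_cv):
            if not 0.0 <= f <= 1.0:
                raise ValueError("mosaic fractions must lie in [0, 1]")
        if self.type in ("segmental_gain", "segmental_loss"):
            if self.chromosome is None or self.interval is None:
                raise ValueError("segmental aberrations require chromosome+interval")
            s, e = self.interval
            if e - s + 1 < 100_000:
                raise ValueError("segmental aberrations must span >= 100 kb")
        elif self.type in ("trisomy", "monosomy", "upd_iso", "tetrasomy"):
            if self.chromosome is None:
                raise ValueError(f"{self.type} requires a chromosome")
            if self.interval is not None:
                s, e = self.interval
                if s != 1 or e != CHROM_LENGTHS[self.chromosome]:
                    raise ValueError(
                        f"{self.type} must span the whole chromosome"
                    )
        elif self.type == "triploidy":
            if self.chromosome is not None:
                raise ValueError("triploidy is genome-wide; chromosome must be None")
            if self.segregational_origin == "mitotic":
                raise ValueError("triploidy requires a meiotic origin (MI or MII)")
        if self.type in ("monosomy", "segmental_loss", "upd_iso",
                         "segmental_gain", "tetrasomy"):
            if self.segregational_origin != "mitotic":
                raise ValueError(
                    f"{self.type} is modeled post-zygotically; origin must be mitotic"
                )


@dataclass
class NoiseModel:
    """Additive Gaussian noise plus maternal-cell contamination."""

    baf_sd: float = 0.03
    logr_sd: float = 0.10
    maternal_contamination: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baf_sd < 0 or self.logr_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if not 0.0 <= self.maternal_contamination <= 1.0:
            raise ValueError("maternal_contamination must lie in [0, 1]")


@dataclass
class CellLine:
    """One conceptus cell line: per chromosome, a list of homolog copies.

    Each copy is a (parent, alleles, present) triple; ``present`` masks out
    segmentally deleted stretches and ``alleles`` is 0/1 per probe.
    """

    probe_map: ProbeMap
    copies: dict[str, list[tuple[str, np.ndarray, np.ndarray]]] = field(
        default_factory=dict
    )

    def b_count(self, chrom: str) -> np.ndarray:
        n = len(self.probe_map.chrom_indices(chrom))
        out = np.zeros(n)
        for _, alleles, present in self.copies.get(chrom, []):
            out += alleles * present
        return out

    def copy_number(self, chrom: str) -> np.ndarray:
        n = len(self.probe_map.chrom_indices(chrom))
        out = np.zeros(n)
        for _, _, present in self.copies.get(chrom, []):
            out += present
        return out


# ---------------------------------------------------------------------------
# Parental genomes and meiosis
# ---------------------------------------------------------------------------

def simulate_parent_haplotypes(
    probe_map: ProbeMap, seed: int
) -> tuple[ParentalGenome, ParentalGenome]:
    """Draw mother and father genomes; alleles are Bernoulli(pop_baf)."""
    rng = np.random.default_rng(seed)
    genomes = []
    for _ in range(2):
        haps: dict[str, np.ndarray] = {}
        for chrom in probe_map.chromosomes():
            p = probe_map.pop_baf[probe_map.chrom_mask(chrom)]
            haps[chrom] = (rng.random((2, len(p))) < p).astype(np.uint8)
        genomes.append(ParentalGenome(probe_map, haps))
    mother, father = genomes
    return mother, father


def _chromatids(
    hap: np.ndarray, positions: np.ndarray, crossovers: Sequence[int]
) -> list[tuple[np.ndarray, int]]:
    """All four post-recombination chromatids with their homolog-of-origin
    index as a function of position (returned lazily via switch counts).

    Returns a list of (allele vector, origin-at-position function input),
    where the origin at base-pair coordinate x for the exchanged chromatids
    is determined by the number of crossovers at or below x.
    """
    switches = np.zeros(len(positions), dtype=int)
    for x in crossovers:
        switches += positions >= x
    r1 = np.where(switches % 2 == 0, hap[0], hap[1]).astype(np.uint8)
    r2 = np.where(switches % 2 == 0, hap[1], hap[0]).astype(np.uint8)
    return [(hap[0].copy(), 0), (hap[1].copy(), 1), (r1, 2), (r2, 3)]


def _origin_at(kind: int, pos: int, crossovers: Sequence[int]) -> int:
    """Homolog of origin (0 or 1) of a chromatid at base-pair ``pos``."""
    if kind in (0, 1):
        return kind
    k = sum(1 for x in crossovers if pos >= x)
    base = 0 if kind == 2 else 1
    return (base + k) % 2


def simulate_meiosis(
    parent: ParentalGenome,
    chromosome: str,
    crossover_positions: Sequence[int],
    error: str = "none",
    seed: int = 0,
) -> list[np.ndarray]:
    """Transmit one (or, under a segregation error, two) homologs.

    ``error='MI'`` returns two homologs whose centromeric segments derive
    from different parental homologs; ``'MII'`` returns two sharing the
    centromeric segment but differing distal to at least one crossover;
    ``'none'`` returns a single recombinant homolog.
    """
    if error not in ("none", "MI", "MII"):
        raise ValueError(f"invalid meiotic error {error!r}")
    idx = parent.probe_map.chrom_indices(chromosome)
    positions = parent.probe_map.position[idx]
    span_hi = CHROM_LENGTHS[chromosome]
    for x in crossover_positions:
        if not 1 <= x <= span_hi:
            raise ValueError(f"crossover position {x} outside chromosome span")
    if error == "MII" and len(crossover_positions) == 0:
        raise ValueError(
            "MII error requires at least one crossover; without one it is "
            "indistinguishable from a mitotic duplication"
        )
    rng = np.random.default_rng(seed)
    hap = parent.haplotypes[chromosome]
    chromatids = _chromatids(hap, positions, crossover_positions)
    cen = CENTROMERES[chromosome]

    if error == "none":
        vec, _ = chromatids[rng.integers(len(chromatids))]
        return [vec]

    pairs = []
    for i in range(len(chromatids)):
        for j in range(i + 1, len(chromatids)):
            oi = _origin_at(chromatids[i][1], cen, crossover_positions)
            oj = _origin_at(chromatids[j][1], cen, crossover_positions)
            same_cen = oi == oj
            differs = bool(np.any(chromatids[i][0] != chromatids[j][0]))
            if error == "MI" and not same_cen:
                pairs.append((i, j))
            elif error == "MII" and same_cen and differs:
                # exclude the two sister copies of the same unexchanged
                # chromatid only via the `differs` requirement above
                pairs.append((i, j))
    if not pairs:
        raise ValueError(f"no chromatid pair realizes a {error} error")
    i, j = pairs[rng.integers(len(pairs))]
    return [chromatids[i][0], chromatids[j][0]]


# ---------------------------------------------------------------------------
# Conceptus assembly
# ---------------------------------------------------------------------------

def _whole(n: int) -> np.ndarray:
    return np.ones(n, dtype=bool)


def assemble_conceptus(
    maternal_gametes: dict[str, list[np.ndarray]],
    paternal_gametes: dict[str, list[np.ndarray]],
    spec: AberrationSpec,
    probe_map: ProbeMap,
) -> tuple[CellLine, Optional[CellLine]]:
    """Combine transmitted homologs into a euploid and, for aberrant specs,
    an aberrant cell line.

    Meiotic trisomies/triploidies consume the two homologs transmitted by
    the erroneous meiosis (the euploid line keeps the first: a post-zygotic
    rescue); mitotic events duplicate or drop an already-transmitted
    homolog, so the aberrant line is single-homolog (SPH) throughout.
    """
    euploid = CellLine(probe_map, {})
    meiotic = spec.type in ("trisomy", "triploidy") and spec.segregational_origin in (
        "MI", "MII",
    )
    for chrom in probe_map.chromosomes():
        n = len(probe_map.chrom_indices(chrom))
        mg, pg = maternal_gametes[chrom], paternal_gametes[chrom]
        affected = spec.type == "triploidy" or chrom == spec.chromosome
        for parent, gametes in (("maternal", mg), ("paternal", pg)):
            expected = 1
            if meiotic and affected and parent == spec.parent_of_origin:
                expected = 2
            if len(gametes) != expected:
                raise ValueError(
                    f"{parent} gamete count {len(gametes)} on chromosome "
                    f"{chrom} inconsistent with spec (expected {expected})"
                )
        euploid.copies[chrom] = [
            ("maternal", mg[0].astype(np.uint8), _whole(n)),
            ("paternal", pg[0].astype(np.uint8), _whole(n)),
        ]

    if spec.type == "none":
        return euploid, None

    aberrant = CellLine(
        probe_map,
        {c: [(p, a.copy(), m.copy()) for p, a, m in lines]
         for c, lines in euploid.copies.items()},
    )

    def own_copy(chrom: str) -> tuple[str, np.ndarray, np.ndarray]:
        for entry in aberrant.copies[chrom]:
            if entry[0] == spec.parent_of_origin:
                return entry
        raise ValueError(f"no {spec.parent_of_origin} copy on chromosome {chrom}")

    if spec.type == "trisomy":
        chrom = spec.chromosome
        n = len(probe_map.chrom_indices(chrom))
        if meiotic:
            extra = (maternal_gametes if spec.parent_of_origin == "maternal"
                     else paternal_gametes)[chrom][1]
        else:
            extra = own_copy(chrom)[1]
        aberrant.copies[chrom].append(
            (spec.parent_of_origin, extra.astype(np.uint8), _whole(n))
        )
    elif spec.type == "tetrasomy":
        chrom = spec.chromosome
        n = len(probe_map.chrom_indices(chrom))
        extra = own_copy(chrom)[1]
        for _ in range(2):
            aberrant.copies[chrom].append(
                (spec.parent_of_origin, extra.astype(np.uint8), _whole(n))
            )
    elif spec.type == "monosomy":
        # parent_of_origin names the parent whose homolog is LOST
        chrom = spec.chromosome
        aberrant.copies[chrom] = [
            e for e in aberrant.copies[chrom] if e[0] != spec.parent_of_origin
        ]
    elif spec.type == "upd_iso":
        chrom = spec.chromosome
        n = len(probe_map.chrom_indices(chrom))
        kept = own_copy(chrom)
        aberrant.copies[chrom] = [
            kept,
            (kept[0], kept[1].copy(), _whole(n)),
        ]
    elif spec.type == "segmental_gain":
        chrom = spec.chromosome
        idx = probe_map.chrom_indices(chrom)
        pos = probe_map.position[idx]
        s, e = spec.interval
        mask = (pos >= s) & (pos <= e)
        src = own_copy(chrom)
        aberrant.copies[chrom].append(
            (spec.parent_of_origin, src[1].copy(), mask)
        )
    elif spec.type == "segmental_loss":
        chrom = spec.chromosome
        idx = probe_map.chrom_indices(chrom)
        pos = probe_map.position[idx]
        s, e = spec.interval
        mask = (pos >= s) & (pos <= e)
        parent, alleles, present = own_copy(chrom)
        present[mask] = False
    elif spec.type == "triploidy":
        src = (maternal_gametes if spec.parent_of_origin == "maternal"
               else paternal_gametes)
        for chrom in probe_map.chromosomes():
            n = len(probe_map.chrom_indices(chrom))
            aberrant.copies[chrom].append(
                (spec.parent_of_origin, src[chrom][1].astype(np.uint8), _whole(n))
            )
    return euploid, aberrant


# ---------------------------------------------------------------------------
# Array rendering
# ---------------------------------------------------------------------------

def call_genotype(noise_free_baf: np.ndarray) -> np.ndarray:
    """Threshold noise-free BAF into AA/AB/BB/NC calls."""
    baf = np.asarray(noise_free_baf, dtype=float)
    out = np.full(baf.shape, "NC", dtype="<U2")
    out[baf <= GT_AA_MAX] = "AA"
    out[baf >= GT_BB_MIN] = "BB"
    out[(baf >= GT_AB_LO) & (baf <= GT_AB_HI)] = "AB"
    return out


def render_array(
    cell_lines: Sequence[CellLine],
    fractions: Sequence[float],
    mother: ParentalGenome,
    noise: NoiseModel,
    sample_role: str = "CV",
) -> arrayio.SampleArray:
    """Render the BAF/logR/genotype tracks of a bulk-DNA sample.

    The sample is a mixture of ``cell_lines`` at ``fractions`` (must sum to
    one), further mixed with the maternal diploid signal at the
    contamination fraction; Gaussian noise is then added and BAF clipped to
    [0, 1].  Genotype calls are thresholded on the noise-free (but
    contaminated) BAF, mimicking a cluster-based caller.
    """
    fractions = np.asarray(fractions, dtype=float)
    if len(fractions) != len(cell_lines):
        raise ValueError("one fraction per cell line required")
    if np.any(fractions < 0) or np.any(fractions > 1):
        raise ValueError("fractions must lie in [0, 1]")
    if abs(fractions.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    pm = cell_lines[0].probe_map
    c = noise.maternal_contamination
    rng = np.random.default_rng([noise.seed, _ROLE_SEEDS.get(sample_role, 99)])

    baf_out = np.empty(len(pm))
    logr_out = np.empty(len(pm))
    gt_out = np.empty(len(pm), dtype="<U2")
    for chrom in pm.chromosomes():
        idx = pm.chrom_indices(chrom)
        b = np.zeros(len(idx))
        t = np.zeros(len(idx))
        for frac, line in zip(fractions, cell_lines):
            if frac == 0:
                continue
            b += frac * line.b_count(chrom)
            t += frac * line.copy_number(chrom)
        if c > 0:
            mhap = mother.haplotypes[chrom]
            b = (1 - c) * b + c * (mhap[0] + mhap[1]).astype(float)
            t = (1 - c) * t + c * 2.0
        with np.errstate(divide="ignore", invalid="ignore"):
            baf_clean = np.where(t > 0, b / np.where(t > 0, t, 1.0), 0.5)
            logr_clean = np.log2(np.maximum(t, 1e-3) / 2.0)
        gt = call_genotype(baf_clean)
        gt[t == 0] = "NC"
        baf = baf_clean + rng.normal(0.0, noise.baf_sd, len(idx))
        logr = logr_clean + rng.normal(0.0, noise.logr_sd, len(idx))
        baf_out[idx] = np.clip(baf, 0.0, 1.0)
        logr_out[idx] = logr
        gt_out[idx] = gt
    return arrayio.SampleArray(gt_out, baf_out, logr_out, sample_role)


def _parent_cell_line(genome: ParentalGenome, label: str) -> CellLine:
    pm = genome.probe_map
    copies = {}
    for chrom, hap in genome.haplotypes.items():
        n = hap.shape[1]
        copies[chrom] = [
            (label, hap[0].astype(np.uint8), _whole(n)),
            (label, hap[1].astype(np.uint8), _whole(n)),
        ]
    return CellLine(pm, copies)


# ---------------------------------------------------------------------------
# Quartet orchestration
# ---------------------------------------------------------------------------

def default_crossovers(
    chromosome: str, rng: np.random.Generator,
    arm_fractions: Optional[Sequence[float]] = None,
) -> list[int]:
    """One crossover per chromosome arm.

    Positions are drawn uniformly on each arm unless ``arm_fractions``
    pins them at fixed fractions of the arm length.
    """
    cen = CENTROMERES[chromosome]
    length = CHROM_LENGTHS[chromosome]
    out = []
    arms = [(1, cen), (cen, length)]
    for k, (lo, hi) in enumerate(arms):
        if hi - lo < 1_000_000:
            continue
        if arm_fractions is not None:
            x = lo + int(arm_fractions[k % len(arm_fractions)] * (hi - lo))
        else:
            x = int(rng.integers(lo + (hi - lo) // 10, hi - (hi - lo) // 10))
        out.append(x)
    return sorted(out)


def simulate_quartet(
    spec: AberrationSpec,
    probe_map: Optional[ProbeMap] = None,
    noise: Optional[NoiseModel] = None,
    seed: int = 0,
    crossover_arm_fractions: Optional[Sequence[float]] = None,
    snps_per_chrom: int = 2000,
    chromosomes: Sequence[str] = CHROMOSOMES,
) -> tuple[arrayio.TrioQuartet, dict]:
    """End-to-end quartet simulation; returns the quartet and ground truth.

    The conceptus is female (two X copies) so the X chromosome behaves
    like an autosome throughout.
    """
    if probe_map is None:
        probe_map = make_probe_map(snps_per_chrom, chromosomes)
    if noise is None:
        noise = NoiseModel(seed=seed)
    rng = np.random.default_rng([seed, 7])
    mother, father = simulate_parent_haplotypes(probe_map, seed)

    crossovers: dict[tuple[str, str], list[int]] = {}
    gametes = {"maternal": {}, "paternal": {}}
    for chrom in probe_map.chromosomes():
        for parent, genome in (("maternal", mother), ("paternal", father)):
            xo = default_crossovers(chrom, rng, crossover_arm_fractions)
            crossovers[(parent, chrom)] = xo
            error = "none"
            if spec.type in ("trisomy", "triploidy") and \
                    spec.segregational_origin in ("MI", "MII") and \
                    parent == spec.parent_of_origin and \
                    (spec.type == "triploidy" or chrom == spec.chromosome):
                error = spec.segregational_origin
            gametes[parent][chrom] = simulate_meiosis(
                genome, chrom, xo, error=error,
                seed=int(rng.integers(2**31)),
            )
    euploid, aberrant = assemble_conceptus(
        gametes["maternal"], gametes["paternal"], spec, probe_map
    )

    def tissue(role: str, f: float) -> arrayio.SampleArray:
        if aberrant is None or f == 0:
            return render_array([euploid], [1.0], mother, noise, role)
        if f == 1:
            return render_array([aberrant], [1.0], mother, noise, role)
        return render_array([euploid, aberrant], [1 - f, f], mother, noise, role)

    parent_noise = replace(noise, maternal_contamination=0.0)
    quartet = arrayio.TrioQuartet(
        probe_map=probe_map,
        mother=render_array(
            [_parent_cell_line(mother, "maternal")], [1.0], mother,
            parent_noise, "mother",
        ),
        father=render_array(
            [_parent_cell_line(father, "paternal")], [1.0], mother,
            parent_noise, "father",
        ),
        cv=tissue("CV", spec.mosaic_fraction_cv if spec.type != "none" else 0.0),
        em=tissue("EM", spec.mosaic_fraction_em if spec.type != "none" else 0.0),
    )
    truth = {
        "spec": {
            "type": spec.type,
            "chromosome": spec.chromosome,
            "interval": list(spec.interval) if spec.interval else None,
            "parent_of_origin": spec.parent_of_origin,
            "segregational_origin": spec.segregational_origin,
            "mosaic_fraction_cv": spec.mosaic_fraction_cv,
            "mosaic_fraction_em": spec.mosaic_fraction_em,
        },
        "seed": seed,
        "noise": {
            "baf_sd": noise.baf_sd,
            "logr_sd": noise.logr_sd,
            "maternal_contamination": noise.maternal_contamination,
        },
        "crossovers": {f"{p}:{c}": v for (p, c), v in crossovers.items()},
    }
    return quartet, truth
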