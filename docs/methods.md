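# Methods

## The signal model

A genotyping array reports, per SNP, a B-allele frequency (BAF) and a
logR ratio. For a bulk DNA sample that is a mixture of cell lines
`k = 1..K` with fractions `w_k`, carrying `B_k` B-alleles out of `N_k`
chromosome copies at a SNP, the noise-free signal is

    BAF  = (sum_k w_k B_k) / (sum_k w_k N_k)
    logR = log2( (sum_k w_k N_k) / 2 )

Maternal-cell contamination at fraction `c` adds the mother's diploid
signal to the mixture before noise. The simulator renders these
quantities exactly, adds independent Gaussian noise (BAF clipped to
[0, 1]) and derives genotype calls by thresholding the noise-free BAF:
AA ≤ 0.15, BB ≥ 0.85, AB in [0.25, 0.75], otherwise NC. The AB band is
deliberately wide so that polysomic heterozygous ratios (1/3, 2/3, 1/4,
3/4) are called AB, as cluster-based production callers do; with a
narrower band a trisomic chromosome would be unphaseable from its own
genotype calls.

logR is the ideal `log2(CN/2)` without signal compression or
renormalisation, so a non-mosaic trisomy sits at ≈ 0.58 and a genome-wide
triploidy shows that level on every chromosome. Real scanners compress
logR and renormalise per sample (which hides triploidy from logR); this
is a known difference between the simulator and real arrays.

## Phasing and haplarithm construction

The chorionic-villi (CV) genotype seeds the phase: at an informative SNP
(one parent AB, the other homozygous) the transmitted allele of the
heterozygous parent follows Mendelianly from the CV call and the
homozygous parent's allele. The phase convention is per-SNP — "H1" is
the homolog transmitted to the CV — which is the only phase observable
from a single offspring. Consequences embraced by the design:

- Both tissues of the same conceptus share one phase (CV and EM derive
  from the same zygote), so the EM haplarithm is interpreted against the
  CV-seeded phase.
- Mendelian-impossible SNPs (e.g. CV BB with mother AA, father AB) are
  flagged and excluded. A genuine non-mosaic loss or isodisomy makes
  *its own chromosome's* heterozygous-band SNPs impossible; non-paternity
  makes every chromosome inconsistent. The abort criterion is therefore
  the inconsistency rate of the cleanest chromosome (> 5% aborts).
- In regions where the target carries both homologs of a parent (BPH),
  the per-SNP deduced phase picks whichever homolog disagrees with the
  homozygous parent; the affected parent's own series then shows a
  single band above 0.5 instead of two bands. This is exactly the
  feature the segregational-origin classifier reads.

Each informative SNP joins series P1/P2 (father heterozygous) or M1/M2
(mother heterozygous): the "1" series where the transmitted allele equals
the homozygous parent's allele, the "2" series otherwise. BAF is
mirrored around 0.5 where the transmitted allele is B. In a clean disomy
P1/M1 = 0 and P2/M2 = 0.5 after mirroring.

## Segmentation

Piecewise constant fitting minimises
`sum_segments SSE / sigma^2 + gamma * (#breakpoints)` exactly by an
O(n²) dynamic program; ties break toward fewer segments. `gamma = 14`
by default, applied to the series standardised by a robust noise scale
(median absolute successive difference / (0.6745·√2), floored at 0.005
so noise-free series remain segmentable). Standardisation makes gamma a
unitless penalty, the convention of common PCF implementations; it is
configurable because one could equally apply gamma to raw BAF residuals.
Series with fewer than 20 SNPs on a chromosome are "not determined" and
carry no segments.

## Interpretation

With aberrant-cell fraction `f`, allele-count enumeration gives the
heterozygous-band positions (clean parental series, after mirroring):

| state            | rising band      | falling band     | logR            |
|------------------|------------------|------------------|-----------------|
| trisomy          | (1+f)/(2+f)      | 1/(2+f)          | log2((2+f)/2)   |
| tetrasomy        | (1+2f)/(2+2f)    | 1/(2+2f)         | log2((2+2f)/2)  |
| monosomy         | 1/(2−f)          | (1−f)/(2−f)      | log2((2−f)/2)   |
| isodisomic UPD   | (1+f)/2          | (1−f)/2          | 0               |

For gains the *other* parent's series rises (the homozygous parent's
SNPs report the gaining parent's copy count cleanly) and the gaining
parent's own series is region-dependent (BPH vs SPH); for losses the
*lost* parent's series rises. Classification is nearest-template over
these curves at the mosaic fraction implied by the observed band shift,
with tolerances ±0.08 in band units and ±0.15 in logR, plus structure
checks: the rising band must be uniform at its template level, and for
gains the gaining parent's own series must show either the SPH band or
BPH-type depletion. The mosaic fraction inverts the band shift
(`f = 4Δ/(1−2Δ)`, `4Δ/(1+2Δ)`, `2Δ`), measured on the heterozygous
bands only — the 0-level bands are biased upward by BAF clipping under
noise, the displaced 0.5-bands are not.

High-fraction losses and isodisomies (f ≳ 0.6) push their heterozygous
bands into the no-call/Mendelian-impossible zone, depleting both P2 and
M2. These chromosomes are recognised by series depletion plus genotype
collapse; copy state follows from logR, and the parent and fraction from
a direct cluster-model fit of the raw BAF at informative SNPs (grid over
f, both origins), which is immune to the call-zone selection bias.

Segregational origin of a gain: segments of the gaining parent's "2"
series above 0.5 mark BPH regions, below 0.5 SPH. BPH at the centromere
→ meiosis I; BPH only distal to a crossover → meiosis II; SPH
throughout → mitotic. Losses, isodisomies and segmental events are SPH
by construction and labelled mitotic (for monosomy the `parental_origin`
names the *lost* parent; both conventions appear in the literature, so
this is configurable in spirit — the evidence dict always records the
raw d values). A consistent gain signature of one parental origin on
≥ 20 autosomes is promoted to a single genome-wide (triploidy-type)
call. Calls below 10% mosaic fraction are suppressed, matching the
method's stated sensitivity floor.

Maternal contamination is estimated by a 0.01-step grid search matching
the observed BAF at parental-informative SNPs to the mixture clusters
(e.g. the paternal-informative heterozygous cluster moves from 0.5 to
(1−c)/2 + c·[mother B]); an estimate ≥ 0.95 with ≥ 95% genotype
concordance to the mother flags complete maternal contamination and the
sample is excluded from calling.

## Synthetic data: what it does and does not emulate

Defaults: 2,000 evenly spaced SNPs per chromosome across chromosomes
1–22 and X (a reduced-density stand-in for a ~665k genome-wide array;
informative SNPs are ~1/4 of probes, split between the two series of a
parent), population B-allele frequency 0.5 at every probe (maximally
informative), one crossover per chromosome arm (positions uniform or
pinned at mid-arm for controlled experiments), BAF noise sd 0.03, logR
noise sd 0.10, female conceptus (X behaves autosomally). Meiotic errors
transmit two chromatids chosen to realise the requested centromeric
configuration; mitotic errors, losses, isodisomies and segmental events
are modelled post-zygotically on the already-transmitted homologs.
GRCh37 chromosome lengths and cytoband-midpoint centromeres are built
in; a BED file can override the centromere table.

Not emulated: allele-frequency spectra and LD, probe-specific bias and
GC waves, logR compression/renormalisation, signal saturation at
high contamination, male X hemizygosity (the simulated father carries
two X haplotypes), cell-culture artifacts. Passing tests therefore show
correctness of the haplotyping/segmentation/classification logic under a
faithful allele-count signal model — not robustness to platform-specific
artifacts of any particular scanner.

At the default density a segmental event needs roughly 20 informative
SNPs per series (tens of Mb) to be callable; on a real ~665k array the
same rule corresponds to the method's ~100 kb resolution floor. Test
and acceptance runs use 2–3 chromosomes per quartet at 800–2,000 SNPs
each, which keeps the full 200-quartet recovery grid and the detection
sweeps inside a desk-scale budget while preserving every band structure
the classifier uses.

## Numerical and design choices

- Exact PCF rather than a heuristic: the penalty-form optimum is
  verified against exhaustive enumeration for short series.
- Tie-breaks: PCF prefers fewer segments; the contamination grid
  resolves near-flat objectives above 0.85 toward larger c (the
  complete-contamination regime is flat by construction).
- Band-route classification is attempted first; the genotype-collapse
  route only engages when both heterozygous series are depleted and the
  target's heterozygosity has collapsed.
- The d value of a series with only one populated band is defined as 0;
  with no populated band it is ND.
- `estimate_mosaic_fraction` validates Δ ∈ [0, 0.5] and rejects shifts
  impossible for the state (e.g. Δ ≥ 0.5 for a gain); results clip to
  [0, 1].
- Exact rank tests delegate to scipy (exact null enumeration for small
  n without ties, normal approximation with continuity/tie correction
  otherwise) and are cross-checked against full enumeration in the test
  suite. The paired Wilcoxon sample size evaluates the noncentral-t
  power of the paired t test at the A.R.E.-discounted effective size
  `n·3/π` (normal parent distribution) and returns the smallest n
  reaching the target power.

## Known limitations

- Mosaic fractions in the loss/UPD gray zone (bands inside the no-call
  window) are recovered by the cluster fit with slightly larger error
  than band-regime fractions; fully non-mosaic events recover f within
  ~0.03 of 1.
- Meiotic-origin monosomies are indistinguishable from mitotic ones in
  array data (a single homolog is a single homolog); losses are labelled
  mitotic.
- Very distal crossovers leave too few SNPs distal to the exchange to
  separate meiosis II from mitotic origin; such chromosomes come back ND
  rather than guessed.
- The contamination estimate assumes a predominantly disomic genome; a
  genome-wide aberration plus heavy contamination is not separable.
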