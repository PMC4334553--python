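# Methods

## The problem

A heterozygous mouse dam should transmit each of her two alleles to half of
her offspring.  At the *R2d2* locus on chromosome 2, dams heterozygous for a
WSB/EiJ-derived allele carrying a large copy-number expansion of a 127 kb
repeat unit transmit that allele far more than half the time — up to ~95% —
while heterozygous sires transmit fairly.  Two mechanisms could produce such
maternal transmission ratio distortion (TRD): female meiotic drive
(preferential segregation of the allele to the egg during asymmetric
meiosis) or genotype-linked embryonic lethality (selective death of
non-carrier embryos).  drivekit implements the statistics that detect TRD,
the litter-size models that discriminate the two mechanisms, and the
genomic analyses (read-depth copy-number calling, qPCR calibration,
QTL scans, haplotype interval mapping) that localize and quantify the
causal copy-number expansion.

## Transmission-ratio statistics (`trd_stats`)

The transmission ratio is TR = W/(W+N), with W and N the carrier and
non-carrier offspring counts.  Aggregate counts are tested with the
two-cell chi-square goodness-of-fit statistic

    X² = (W − N)² / (W + N),   1 df,

i.e. both genotype cells compared against their expectation (W+N)/2.
Per-dam counts (typically under 50 offspring) are tested with the exact
binomial test, one-sided toward carrier excess by default because that is
the direction a drive candidate predicts; the two-sided variant doubles the
smaller tail.  Confidence intervals are Clopper–Pearson, which reproduces
the published 2-decimal intervals.  Heterogeneity of TR across units is a
K×2 contingency chi-square without continuity correction.  No
multiple-testing correction is applied anywhere.

Severity labels follow the conventional scheme: `U` for fewer than 10
offspring, `N` for TR < 0.6 or p ≥ 0.1, `L` for TR ≥ 0.6 with p > 0.05,
`H` for TR ≥ 0.92 with p ≤ 0.05, `M` otherwise.  The printed-precision
helper rounds half away from zero, the convention of the published tables.

## Lethality-only litter model (`drive_lethality`)

If lethality alone explains an observed TR t ≥ 0.5 under fair segregation,
the non-carrier death rate must be d = 2 − 1/t, and the expected litter
shrinks to ALS_exp/(2t), where ALS_exp is the mean litter size of
unaffected dams (default 8.4 pups, the observed mean of non-distorted
outbred dams; overridable).  Dams are tested against this prediction with a
Wilcoxon signed-rank test of the paired differences between each dam's
observed mean litter and her own prediction.  The alternative is one-sided
("observed greater than predicted") because every comparison of interest
asks whether litters are too large for lethality to explain; the direction
is a parameter.  Observed litters exceeding the prediction indicate drive.

Drive uniquely raises the *absolute* number of carrier pups per litter
(E[carriers/litter] = λ·m under drive strength m, versus λ/2 under
lethality of any severity), so per-dam carrier means are compared between
distorted and Mendelian groups with a Welch one-tailed t-test.  Welch
(unequal-variance) t-tests are used throughout since group variances are
not assumed equal.  Mid-gestation resorption counts are compared two-sided.
Dams with no recorded litters are dropped with a logged warning.

## Read-depth copy-number calling (`cnv_depth`)

Per-base depth is normalized by the genome-wide mean, averaged in
consecutive 100 bp windows, and maximal runs of windows at least 2× the
genome-wide mean are called as expansions.  Runs separated by at most
5 kb of sub-threshold windows are merged into one call by default: the
reference copy of the repeat contains LINE insertions absent from the
expanded copies, which produce internal coverage gaps that would otherwise
split the call.  `max_gap=0` restores strict "consecutive windows"
semantics.  Haploid copy number is the mode of the integer-rounded
normalized per-base depth over the call; ties break toward the smaller
value (conservative).  Partial terminal windows participate in calling but
are flagged.  Coordinates are 0-based half-open internally and 1-based
inclusive in output.

At mean depth μ ≥ 20 the mode estimator recovers haploid copy numbers in
{2, 11, 24, 34, 36} exactly in ≥95% of simulated replicates, and call
boundaries land within one window (100 bp) of the planted truth; single-copy
sequence produces no call.  Below μ ≈ 1 calls become unreliable and the
generator warns.

## TaqMan ΔCt normalization and calibration (`taqman_cn`)

ΔCt = Ct_reference − Ct_target rises one cycle per doubling of target copy
number under perfect amplification efficiency.  Technical offsets (batch,
target–reference pairing) are estimated from control samples of known copy
number replicated in every batch: control ΔCt values are centred on their
genotype grand means, two-way additive batch and assay effects are
backfitted, shrunk toward zero with method-of-moments variance components,
and subtracted from every well.  Full REML machinery is unnecessary for the
balanced control design — the contract is offset recovery (≥90% reduction
of between-batch control variance in simulation), which the shrinkage
estimator meets.  Batches without controls are passed through un-normalized
and flagged.

Copy number is opt-in: log2(CN) is regressed on normalized ΔCt over
calibrator samples (the fitted slope is ~1 under perfect efficiency and
serves as an efficiency diagnostic) and predictions are reported as reals,
with an optional integer-rounding flag, because constant log-scale noise
grows exponentially on the linear scale.  ΔCt remains the primary reported
scale.  Two-class genotyping from ΔCt uses 1-d 2-means clustering and
refuses to call when the silhouette falls below 0.5.

## QTL scans (`qtl_scan`)

All scanned populations are treated as backcrosses: genotype codes are
1 (heterozygous focal) or 0 (homozygous non-focal).  The genome is
partitioned into disjoint intervals at the union of all observed
recombination breakpoints, so no individual recombines within an interval;
an equal-size grid builder (`grid_intervals`, e.g. 1,000 intervals) is
provided as the alternative used when markers rather than breakpoints
define the scan.  Quantitative phenotypes use Haley–Knott regression:
LOD = (n/2)·log10(RSS₀/RSS₁).  Binary phenotypes use the logistic analog,
LOD = (ℓ₁ − ℓ₀)/ln 10; with a single binary regressor the logistic MLE
fits each genotype class's proportion exactly, so both log-likelihoods have
closed forms and complete separation leaves LOD finite (the boundary
likelihood), flagged `separation` — no penalized fallback is needed.
Missing codes are dropped per locus (complete cases); loci with fewer than
5 informative individuals or a monomorphic code score 0 and are flagged.
A zero-residual fit is capped at LOD 10⁴ and flagged `perfect_fit`.

Significance thresholds come from unrestricted permutation of the
phenotype vector (no strata), taking the empirical (1−α) quantile of
per-permutation genome-wide maximum LOD.  The seed is a required argument
and fixes the threshold bit-for-bit.

The array sum-intensity phenotype is the per-sample sum of intensities over
the probes tracking the repeat; the transform applied to raw intensities is
a pluggable hook defaulting to identity, since proprietary array contrast
transforms are upstream of this package's scope.

## Haplotype interval mapping (`haplotype_interval`)

Overlap mapping intersects the focal-founder coverage of all
phenotype-positive individuals; unknown-phenotype and unaffected mosaics
are excluded because heterozygosity is necessary but not sufficient for the
phenotype (unlinked distorter loci can silence it).  Reported boundaries
are the outermost positions flanked by non-focal evidence, i.e. each
boundary coincides with a defining recombination.  Critical-recombinant
refinement intersects the focal coverage of individuals whose quantitative
readout says they carry the element with the complement of the coverage of
those who lack it; a focal run touching the described end of a mosaic is
treated as unbounded there, since no recombination bounds it.  A side with
no informative recombinant is reported unbounded with a warning.

The consistent-SNP scan counts, per non-overlapping window (default 1 kb),
SNPs at which all affected strains share one non-missing allele (*shared*)
and no unaffected strain carries it (*consistent*; any missing call
disqualifies, conservatively).  Windows with ≥90% consistent SNPs are
flagged.  Mean spacing is region length divided by consistent-SNP count.

## Synthetic data (`synthetic_data`)

The generator encodes the generative model the analyses assume.  Litters:
O ~ Poisson(λ) ovulated oocytes; each carries the focal allele with
probability m (gamete-level drive, the simplest mechanism consistent with
preferential segregation; chromatid-level drive is not modeled);
non-carrier embryos die with probability d; all embryos die with
probability a.  Closed forms: E[TR] = m/(m+(1−m)(1−d)) and
E[litter] = λ(1−a)(m+(1−m)(1−d)).  Litter counts are Poisson because the
source data report means ± s.d. only; defaults are λ = 8.4 (the observed
no-distortion mean) and 5 litters per dam (≈42 offspring, matching the
"typically fewer than 50 per dam" scale of the real crosses).

Named scenarios fix the study conditions: `mendelian` (m = 0.5, d = 0),
`pure_drive_094` (m = 0.94), `pure_lethality_075` (d = 2/3, forcing
TR = 0.75), and `mixed_do_g13` (m = 0.5643, d = 0.6348, λ = 9.4, jointly
solving TR = 0.78 with mean litter 6.8 against a 9.4 no-distortion mean).

Depth is Poisson(μ·CN) per base.  Array intensity is
base + slope·log2(CN) + Gaussian noise.  TaqMan wells follow perfect
doubling with batch offsets ~N(0, batch_sd) and per-well noise
~N(0, 0.15 cycles); each sample is assayed with two target–reference pairs
in duplicate wells and each batch carries the control panel (haploid CN
1, 2, 17, 33) in duplicate, mirroring standard real-time CNV practice.
Backcross gametes recombine between adjacent markers with the Haldane map
function (no interference).  Mosaics plant a causal interval whose
boundaries coincide with the first two carriers' breakpoints, so overlap
mapping can recover the truth exactly; an optional unlinked-distorter
probability relabels carriers as unaffected.

What the generator does *not* emulate: litter-size over-dispersion beyond
Poisson, array probe-specific effects, qPCR efficiency drift, haplotype
reconstruction error, or recombination interference.  Passing tests
therefore demonstrate correctness of the estimators under the stated
model, not robustness to these real-data complications.

## Numerical choices and degenerate inputs

* Zero offspring counts raise an explicit empty-data error everywhere.
* All-zero paired differences in the signed-rank test return p = 1 with a
  warning; zero variance in both groups of a t-test reports p = 1 with a
  warning; zero variance in either correlation variable is an error.
* Copy-number mode ties break toward the smaller value; the mode is floored
  at 1 inside a call.
* Permutation thresholds use the default (linear-interpolation) empirical
  quantile; with a fixed seed the result is bit-reproducible.
* Monte-Carlo test sizes in the suite (e.g. 200 depth replicates, 40 scan
  replicates, 10,000 simulated dams for size calibration) were chosen to
  keep Monte-Carlo error a small fraction of the asserted margins.

## Known limitations

* The exact binomial test is conservative at per-dam sample sizes
  (measured size ≈ 0.035–0.04 at nominal 0.05 for n ≈ 42); the chi-square
  test is calibrated at aggregate sizes.
* The lethality model assumes lethality acts only on non-carriers; a
  genotype-independent loss component changes litter size but not TR and
  is exposed separately in the simulator (parameter `a`), so either
  aneuploidy-style or genotype-targeted loss can be expressed.
* Reported copy numbers above ~30 are increasingly uncertain on the linear
  scale; ΔCt is the recommended reporting scale.
* Interval mapping assumes correctly reconstructed mosaics; no HMM
  haplotype inference or phasing is performed.
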