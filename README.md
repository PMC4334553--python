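# drivekit

Statistical toolkit for detecting **transmission ratio distortion (TRD)**
and dissecting **female meiotic drive** in mouse crosses.

A heterozygous parent should transmit each allele to half of its offspring.
At the *R2d2* locus on mouse chromosome 2, females heterozygous for a
WSB/EiJ-derived allele carrying a large copy-number expansion of a 127 kb
repeat transmit that allele to up to ~95% of their pups, while heterozygous
males transmit fairly.  drivekit implements, as a reusable library plus a
CLI, the full analysis chain for such a system:

* **`trd_stats`** — transmission ratios TR = W/(W+N); the two-cell 1-df
  goodness-of-fit test X² = (W−N)²/(W+N); one-sided exact binomial tests
  for small per-dam counts; Clopper–Pearson confidence intervals; K×2
  heterogeneity tests; N/L/M/H/U severity classification.
* **`drive_lethality`** — the lethality-only litter model
  ALS_obs = ALS_exp/(2·TR) and its inverse d = 2 − 1/TR; signed-rank tests
  of observed vs predicted litters; per-allele absolute-count comparisons
  (only drive raises the *absolute* number of carrier pups per litter);
  resorption comparisons; TR–litter-size correlation.
* **`cnv_depth`** — copy-number calling from sequencing depth: normalize by
  genome-wide mean, 100 bp windows, ≥2× threshold runs with gap merging,
  haploid copy number as the modal rounded per-base depth.
* **`taqman_cn`** — qPCR ΔCt = Ct_ref − Ct_target; batch/assay offset
  removal via a shrinkage random-effects fit on replicated controls;
  log2-linear calibration to copy number; two-class genotyping from ΔCt.
* **`qtl_scan`** — Haley–Knott regression over recombination-defined
  genome intervals, LOD = (n/2)·log10(RSS₀/RSS₁); a logistic analog for
  binary traits; unrestricted permutation thresholds; array sum-intensity
  phenotypes.
* **`haplotype_interval`** — candidate intervals from founder-haplotype
  overlap among affected individuals; critical-recombinant boundary
  refinement; phenotype-consistent SNP window scans.
* **`synthetic_data`** — seeded generators for every input above
  (Poisson ovulation, gamete-level drive m, non-carrier lethality d,
  Poisson read depth, TaqMan plates with batch effects, Haldane
  backcrosses, founder mosaics), with named scenarios pinning the study
  conditions.

## Worked example

Score the packaged table of 18 published crosses (one heterozygous F1 or
CC-hybrid parent each) and classify each cross:

```python
from drivekit import io, trd_stats

records = io.packaged_cross_counts()
by_id = {r.unit_id: r for r in records}

res = trd_stats.tr_test(by_id["cross17"])     # (WSB/EiJxC57BL/6J)F1 dams
print(f"TR = {res.tr:.3f}  CI = {res.ci_low:.2f}-{res.ci_high:.2f}  "
      f"p(chi2) = {res.p_chi2:.2g}  class = "
      f"{trd_stats.classify_trd(res.tr, res.p_binom, res.n)}")

dams  = trd_stats.pool_records([r for r in records if r.role == "dam"],  "dams",  "dam")
sires = trd_stats.pool_records([r for r in records if r.role == "sire"], "sires", "sire")
print(f"pooled dam TR  = {trd_stats.transmission_ratio(dams):.3f}")
print(f"pooled sire TR = {trd_stats.transmission_ratio(sires):.3f}")
```

This prints:

```
TR = 0.939  CI = 0.92-0.96  p(chi2) = 2.9e-92  class = H
pooled dam TR  = 0.666
pooled sire TR = 0.500
```

— extreme maternal distortion (506 of 539 pups inherited the focal allele,
class `H`), a two-thirds pooled maternal TR, and perfectly Mendelian
paternal transmission: the maternal-only signature of female meiotic drive.

Simulate the drive-vs-lethality discrimination on synthetic dams:

```python
from drivekit.synthetic_data import scenario, simulate_litters
from drivekit.drive_lethality import per_allele_litter_means
import numpy as np

drive = simulate_litters(scenario("pure_drive_094", seed=1, n_dams=1000))
mend  = simulate_litters(scenario("mendelian",      seed=2, n_dams=1000))
print(round(np.mean([r.mean_litter_size for r in drive]), 2),
      round(np.mean([r.mean_litter_size for r in mend]),  2))
print(round(per_allele_litter_means(drive, mend).carrier_mean_trd, 2))
```

```
8.39 8.37
7.88
```

Litters under pure drive are as large as Mendelian litters (8.39 vs 8.37
pups) while carrier pups per litter jump from the Mendelian ~4.2 to 7.88 —
the signature that lethality cannot produce.

The same functionality is available from the shell:

```sh
drivekit simulate pure_drive_094 --seed 5 --n-dams 50 --out sim/
drivekit tr-test   --in sim/counts.tsv      --out results.tsv
drivekit cnv-depth --in sim/depth.bedgraph  --genome-mean 30 --out calls.bed
```

## Layout

```
src/drivekit/          library modules (one per analysis stage)
src/drivekit/data/     packaged cross-count table (TSV)
tests/                 pytest suite, including end-to-end acceptance tests
scripts/acceptance.py  recomputes the headline quantities
docs/methods.md        model assumptions, parameter choices, limitations
```
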