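"""Single-locus QTL scans over recombination-defined genome intervals.

The populations handled here are effectively backcrosses: at every locus an
individual is either heterozygous for the focal founder haplotype (code 1)
or homozygous for something else (code 0).  Quantitative phenotypes (array
sum-intensity, normalized ΔCt) are scanned by Haley-Knott regression of the
phenotype on the genotype code; binary phenotypes (presence of transmission
ratio distortion) by its logistic analog.  In both cases

    LOD = (log-likelihood of the single-locus model
           - log-likelihood of the intercept-only model) / ln 10,

which for the least-squares case reduces to (n/2) log10(RSS0 / RSS1).
Genome-wide significance thresholds come from unrestricted permutation of
the phenotype vector: the (1 - alpha) quantile of the per-permutation
maximum LOD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MarkerMatrix",
    "ScanResult",
    "build_intervals",
    "hk_scan_quantitative",
    "hk_scan_binary",
    "permutation_threshold",
    "sum_intensity_phenotype",
    "grid_intervals",
    "LOD_CAP",
]

log = logging.getLogger(__name__)

# Documented ceiling for LOD at a perfect (zero-residual) fit, where the
# likelihood ratio is unbounded; such loci are additionally flagged.
LOD_CAP = 1e4

MIN_INFORMATIVE = 5  # minimum non-missing individuals per locus


@dataclass(frozen=True)
class MarkerMatrix:
    """Genotype codes (0 homozygous non-focal, 1 heterozygous focal) per locus.

    ``codes`` is individuals x loci, float, with np.nan for missing calls.
    Loci are (chrom, position) pairs sorted within chromosome.
    """

    individuals: tuple[str, ...]
    loci: tuple[tuple[str, float], ...]
    codes: np.ndarray

    def __post_init__(self) -> None:
        codes = np.asarray(self.codes, dtype=float)
        object.__setattr__(self, "codes", codes)
        object.__setattr__(self, "individuals", tuple(self.individuals))
        object.__setattr__(self, "loci", tuple(tuple(l) for l in self.loci))
        if codes.shape != (len(self.individuals), len(self.loci)):
            raise ValueError("codes must be individuals x loci")
        valid = np.isnan(codes) | (codes == 0) | (codes == 1)
        if not valid.all():
            raise ValueError("codes must be 0, 1 or missing (nan)")
        for chrom in {c for c, _ in self.loci}:
            pos = [p for c, p in self.loci if c == chrom]
            if sorted(pos) != pos:
                raise ValueError(f"loci on {chrom} must be sorted by position")


@dataclass
class ScanResult:
    """Per-locus LOD scores plus an optional permutation threshold."""

    loci: tuple[tuple[str, float], ...]
    lod: np.ndarray
    flags: list[set[str]]
    threshold: float | None = None
    alpha: float | None = None
    n_perm: int | None = None

    def peak(self) -> tuple[tuple[str, float], float]:
        i = int(np.argmax(self.lod))
        return self.loci[i], float(self.lod[i])


def build_intervals(
    breakpoints: dict[str, list[list[float]]],
    bounds: dict[str, tuple[float, float]] | None = None,
) -> list[tuple[str, float, float]]:
    """Partition each chromosome at the union of all unique breakpoints.

    ``breakpoints`` maps chromosome -> per-individual breakpoint lists; the
    returned intervals (chrom, start, end], taken together, tile each
    chromosome so that no individual recombines inside any interval.  With
    no breakpoints a chromosome yields a single interval.  ``bounds``
    optionally supplies finite chromosome ends; otherwise +/-inf are used.
    """
    intervals = []
    for chrom, per_ind in breakpoints.items():
        lo, hi = (bounds or {}).get(chrom, (-np.inf, np.inf))
        cuts = sorted({b for lst in per_ind for b in lst if lo < b < hi})
        edges = [lo, *cuts, hi]
        intervals.extend((chrom, a, b) for a, b in zip(edges[:-1], edges[1:]))
    return intervals


def grid_intervals(
    bounds: dict[str, tuple[float, float]], n_total: int = 1000
) -> list[tuple[str, float, float]]:
    """Divide the genome into ~n_total equal-size disjoint intervals."""
    total = sum(hi - lo for lo, hi in bounds.values())
    intervals = []
    for chrom, (lo, hi) in bounds.items():
        k = max(1, round(n_total * (hi - lo) / total))
        edges = np.linspace(lo, hi, k + 1)
        intervals.extend((chrom, a, b) for a, b in zip(edges[:-1], edges[1:]))
    return intervals


def _locus_groups(
    code: np.ndarray, phenotype: np.ndarray
) -> tuple[np.ndarray, np.ndarray, set[str]]:
    """Complete-case split of the phenotype by genotype code at one locus."""
    flags: set[str] = set()
    mask = ~np.isnan(code) & ~np.isnan(phenotype)
    y = phenotype[mask]
    g = code[mask]
    if y.size < MIN_INFORMATIVE:
        flags.add("too_few_informative")
    if np.unique(g).size < 2:
        flags.add("monomorphic")
    return y, g, flags


def hk_scan_quantitative(markers: MarkerMatrix, phenotype: np.ndarray) -> ScanResult:
    """Haley-Knott regression scan of a quantitative phenotype.

    Per locus, least-squares regression of the phenotype on the genotype
    code (equivalent to a two-group means model);
    LOD = (n/2) log10(RSS0/RSS1).  Monomorphic or under-informative loci
    score 0 and are flagged; a zero-residual fit is capped at ``LOD_CAP``
    and flagged ``perfect_fit``.
    """
    phenotype = np.asarray(phenotype, dtype=float)
    if phenotype.size != len(markers.individuals):
        raise ValueError("phenotype length must match number of individuals")
    lods = np.zeros(len(markers.loci))
    all_flags: list[set[str]] = []
    for j in range(len(markers.loci)):
        y, g, flags = _locus_groups(markers.codes[:, j], phenotype)
        if flags:
            all_flags.append(flags)
            continue
        n = y.size
        rss0 = float(np.sum((y - y.mean()) ** 2))
        if rss0 == 0:
            flags.add("constant_phenotype")
            all_flags.append(flags)
            continue
        rss1 = 0.0
        for val in (0.0, 1.0):
            sub = y[g == val]
            rss1 += float(np.sum((sub - sub.mean()) ** 2))
        if rss1 <= 0:
            lods[j] = LOD_CAP
            flags.add("perfect_fit")
        else:
            lods[j] = (n / 2.0) * np.log10(rss0 / rss1)
        all_flags.append(flags)
    return ScanResult(loci=markers.loci, lod=lods, flags=all_flags)


def _binom_ll(k: float, n: float) -> float:
    """Binomial log-likelihood at the MLE p = k/n, with 0 log 0 = 0."""
    if n == 0:
        return 0.0
    p = k / n
    ll = 0.0
    if k > 0:
        ll += k * np.log(p)
    if n - k > 0:
        ll += (n - k) * np.log(1 - p)
    return float(ll)


def hk_scan_binary(markers: MarkerMatrix, phenotype: np.ndarray) -> ScanResult:
    """Logistic-regression analog of the Haley-Knott scan for a binary trait.

    With a single binary regressor the logistic MLE fits each genotype
    class's phenotype proportion exactly, so the maximized log-likelihoods
    have closed forms and LOD = (l1 - l0)/ln 10 is computed directly.
    Complete separation (a class proportion of 0 or 1) leaves the
    boundary log-likelihood finite; such loci are flagged ``separation``.
    """
    phenotype = np.asarray(phenotype, dtype=float)
    if phenotype.size != len(markers.individuals):
        raise ValueError("phenotype length must match number of individuals")
    observed = phenotype[~np.isnan(phenotype)]
    if not set(np.unique(observed)) <= {0.0, 1.0}:
        raise ValueError("binary phenotype must be coded 0/1")
    if np.unique(observed).size < 2:
        raise ValueError("binary scan requires both phenotype classes present")
    lods = np.zeros(len(markers.loci))
    all_flags: list[set[str]] = []
    for j in range(len(markers.loci)):
        y, g, flags = _locus_groups(markers.codes[:, j], phenotype)
        if flags:
            all_flags.append(flags)
            continue
        n = y.size
        k = float(y.sum())
        l0 = _binom_ll(k, n)
        l1 = 0.0
        separated = False
        for val in (0.0, 1.0):
            sub = y[g == val]
            kk, nn = float(sub.sum()), float(sub.size)
            l1 += _binom_ll(kk, nn)
            if nn > 0 and kk in (0.0, nn):
                separated = True
        if separated and l1 > l0:
            flags.add("separation")
        lods[j] = max(0.0, (l1 - l0) / np.log(10.0))
        all_flags.append(flags)
    return ScanResult(loci=markers.loci, lod=lods, flags=all_flags)


def permutation_threshold(
    markers: MarkerMatrix,
    phenotype: np.ndarray,
    scan: str = "quantitative",
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int | None = None,
) -> float:
    """Genome-wide LOD threshold by unrestricted phenotype permutation.

    Permutes the phenotype vector ``n_perm`` times with the given seed,
    records the genome-wide maximum LOD of each permuted scan, and returns
    the empirical (1 - alpha) quantile.  Deterministic for a fixed seed.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 for a stable threshold")
    scan_fn = {"quantitative": hk_scan_quantitative, "binary": hk_scan_binary}.get(scan)
    if scan_fn is None:
        raise ValueError("scan must be 'quantitative' or 'binary'")
    phenotype = np.asarray(phenotype, dtype=float)
    rng = np.random.default_rng(seed)
    maxima = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(phenotype)
        maxima[i] = scan_fn(markers, perm).lod.max()
    return float(np.quantile(maxima, 1.0 - alpha))


def sum_intensity_phenotype(
    probes: pd.DataFrame,
    probe_set: list[str],
    transform=None,
) -> pd.Series:
    """Per-sample sum of (optionally transformed) probe intensities.

    ``probes`` is a probe x sample intensity matrix.  Probes tracking a
    copy-number expansion hybridize proportionally more DNA, so their summed
    intensity separates copy-number classes.  ``transform`` is a pluggable
    per-value hook (e.g. a contrast-stretching transform) defaulting to
    identity.  Missing probes raise with the full missing list.
    """
    if not probe_set:
        raise ValueError("probe_set must be non-empty")
    missing = [p for p in probe_set if p not in probes.index]
    if missing:
        raise KeyError(f"probes absent from intensity matrix: {missing}")
    block = probes.loc[probe_set]
    if transform is not None:
        block = block.apply(transform)
    return block.sum(axis=0)
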