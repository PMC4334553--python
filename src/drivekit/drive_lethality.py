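"""Discriminating female meiotic drive from embryonic lethality.

Two mechanisms can bias the transmission ratio (TR) in the progeny of a
heterozygous dam: preferential segregation of the focal allele to the egg
(meiotic drive), or selective death of non-carrier embryos (genotype-linked
lethality).  They leave different fingerprints on litter size:

* Under lethality alone, fair segregation plus a non-carrier death rate d
  gives TR = 0.5 / (0.5 + 0.5 (1 - d)) and shrinks the mean litter to
  ALS_exp / (2 TR), where ALS_exp is the mean litter size of unaffected
  dams.  Inverting, d = 2 - 1/TR.
* Under drive alone, litter size is unchanged and the *absolute* number of
  carrier pups per litter rises, because carriers replace non-carriers
  among a fixed number of ovulated eggs.

This module implements the lethality-only litter-size model, the paired
signed-rank test for deviation from it, the per-allele absolute-count
comparison, the mid-gestation resorption comparison, and the TR vs litter
size correlation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "LitterRecord",
    "LethalityModel",
    "predicted_litter_size",
    "implied_lethality",
    "lethality_deviation_test",
    "per_allele_litter_means",
    "resorption_compare",
    "tr_litter_correlation",
    "PerAlleleResult",
    "ResorptionResult",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class LitterRecord:
    """Litter-by-litter counts for one dam.

    ``litter_sizes`` are pups counted soon after birth; the per-litter
    carrier / non-carrier counts are the genotyped subsets of each litter.
    ``live_embryos`` / ``resorbed_embryos`` are optional mid-gestation
    dissection counts.
    """

    dam_id: str
    litter_sizes: tuple[int, ...]
    per_litter_carrier: tuple[int, ...]
    per_litter_noncarrier: tuple[int, ...]
    live_embryos: int | None = None
    resorbed_embryos: int | None = None

    def __post_init__(self) -> None:
        sizes = tuple(self.litter_sizes)
        carr = tuple(self.per_litter_carrier)
        nonc = tuple(self.per_litter_noncarrier)
        object.__setattr__(self, "litter_sizes", sizes)
        object.__setattr__(self, "per_litter_carrier", carr)
        object.__setattr__(self, "per_litter_noncarrier", nonc)
        if not (len(sizes) == len(carr) == len(nonc)):
            raise ValueError("per-litter lists must have equal length")
        for s, c, k in zip(sizes, carr, nonc):
            if min(s, c, k) < 0:
                raise ValueError("litter counts must be non-negative")
            if c + k > s:
                raise ValueError(
                    f"dam {self.dam_id!r}: genotyped pups ({c}+{k}) exceed litter size {s}"
                )

    @property
    def n_litters(self) -> int:
        return len(self.litter_sizes)

    @property
    def mean_litter_size(self) -> float:
        if not self.litter_sizes:
            raise ValueError(f"dam {self.dam_id!r} has no recorded litters")
        return float(np.mean(self.litter_sizes))

    @property
    def mean_carrier_per_litter(self) -> float:
        return float(np.mean(self.per_litter_carrier))

    @property
    def mean_noncarrier_per_litter(self) -> float:
        return float(np.mean(self.per_litter_noncarrier))

    @property
    def tr(self) -> float:
        w = sum(self.per_litter_carrier)
        n = sum(self.per_litter_noncarrier)
        if w + n == 0:
            raise ValueError(f"dam {self.dam_id!r} has no genotyped offspring")
        return w / (w + n)


@dataclass(frozen=True)
class LethalityModel:
    """Lethality-only model: expected litter size ALS_exp and observed TR."""

    als_exp: float
    tr: float

    def __post_init__(self) -> None:
        if self.als_exp <= 0:
            raise ValueError("als_exp must be positive")
        if not 0.5 <= self.tr <= 1.0:
            raise ValueError(
                "lethality alone cannot produce TR outside [0.5, 1]; "
                f"got tr={self.tr}"
            )


def predicted_litter_size(model: LethalityModel) -> float:
    """Mean litter size if lethality alone explains the observed TR.

    Equals ALS_exp / (2 TR): the half of the litter that starts as carrier
    survives intact, while non-carriers are culled down to restore the
    observed ratio.
    """
    return model.als_exp / (2.0 * model.tr)


def implied_lethality(tr: float) -> float:
    """Non-carrier death probability d forcing the observed TR under fair segregation.

    Solves 0.5 / (0.5 + 0.5 (1 - d)) = TR for d, giving d = 2 - 1/TR.
    """
    if not 0.5 <= tr <= 1.0:
        raise ValueError(f"tr must lie in [0.5, 1], got {tr}")
    return 2.0 - 1.0 / tr


def _dams_with_litters(
    dams: list[tuple[LitterRecord, float]],
) -> list[tuple[LitterRecord, float]]:
    kept = []
    for rec, tr in dams:
        if rec.n_litters < 1:
            log.warning("dropping dam %r: no recorded litters", rec.dam_id)
            continue
        kept.append((rec, tr))
    return kept


def lethality_deviation_test(
    dams: list[tuple[LitterRecord, float]],
    als_exp: float,
    alternative: str = "greater",
) -> float:
    """Wilcoxon signed-rank test of observed vs lethality-predicted litter size.

    For each dam the paired difference is her observed mean litter size minus
    ALS_exp / (2 TR) at her own TR.  The default one-sided alternative
    ("observed greater than predicted") is the direction indicating that
    lethality alone under-predicts the litters, i.e. that drive must be
    acting.  TRs below 0.5 are clamped to 0.5 (the model's boundary), since
    lethality cannot produce a deficit of carriers.
    """
    dams = _dams_with_litters(dams)
    if len(dams) < 2:
        raise ValueError("need at least two dams with litters and TR estimates")
    diffs = np.array(
        [
            rec.mean_litter_size
            - predicted_litter_size(LethalityModel(als_exp, max(tr, 0.5)))
            for rec, tr in dams
        ]
    )
    if np.all(diffs == 0):
        warnings.warn("all observed litters exactly match prediction; p = 1")
        return 1.0
    res = stats.wilcoxon(diffs, alternative=alternative)
    return float(res.pvalue)


@dataclass(frozen=True)
class PerAlleleResult:
    """Group means of per-litter absolute allele counts, with one-tailed test."""

    carrier_mean_trd: float
    noncarrier_mean_trd: float
    carrier_mean_control: float
    noncarrier_mean_control: float
    p_carrier_greater: float


def per_allele_litter_means(
    trd_dams: list[LitterRecord],
    control_dams: list[LitterRecord],
) -> PerAlleleResult:
    """Compare absolute carrier counts per litter between TRD and Mendelian dams.

    Only drive can raise the *absolute* number of carrier pups per litter;
    lethality merely removes non-carriers.  Per-dam means are compared with a
    Welch one-tailed t-test (alternative: TRD group greater).
    """
    if not trd_dams or not control_dams:
        raise ValueError("both groups must be non-empty")
    trd_c = [d.mean_carrier_per_litter for d in trd_dams]
    trd_n = [d.mean_noncarrier_per_litter for d in trd_dams]
    ctl_c = [d.mean_carrier_per_litter for d in control_dams]
    ctl_n = [d.mean_noncarrier_per_litter for d in control_dams]
    res = stats.ttest_ind(trd_c, ctl_c, equal_var=False, alternative="greater")
    p = float(res.pvalue)
    if np.isnan(p):  # both groups constant and equal
        p = 0.5
    return PerAlleleResult(
        carrier_mean_trd=float(np.mean(trd_c)),
        noncarrier_mean_trd=float(np.mean(trd_n)),
        carrier_mean_control=float(np.mean(ctl_c)),
        noncarrier_mean_control=float(np.mean(ctl_n)),
        p_carrier_greater=p,
    )


@dataclass(frozen=True)
class ResorptionResult:
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    p: float


def resorption_compare(
    group_a: list[LitterRecord],
    group_b: list[LitterRecord],
) -> ResorptionResult:
    """Two-sided Welch t-test of mid-gestation resorbed-embryo counts."""
    xa = [d.resorbed_embryos for d in group_a]
    xb = [d.resorbed_embryos for d in group_b]
    if any(v is None for v in xa + xb):
        raise ValueError("resorbed_embryos must be present in both groups")
    xa = np.asarray(xa, dtype=float)
    xb = np.asarray(xb, dtype=float)
    res = stats.ttest_ind(xa, xb, equal_var=False)
    p = float(res.pvalue)
    if np.isnan(p):
        warnings.warn("zero variance in both groups; reporting p = 1")
        p = 1.0
    return ResorptionResult(
        mean_a=float(xa.mean()),
        sd_a=float(xa.std(ddof=1)) if len(xa) > 1 else 0.0,
        mean_b=float(xb.mean()),
        sd_b=float(xb.std(ddof=1)) if len(xb) > 1 else 0.0,
        p=p,
    )


def tr_litter_correlation(
    dams: list[tuple[LitterRecord, float]],
) -> tuple[float, float]:
    """Pearson correlation of per-dam mean litter size with TR.

    A strong negative correlation indicates that distortion travels with
    litter-size loss (some lethality), though its slope alone cannot
    separate drive from lethality.
    """
    dams = _dams_with_litters(dams)
    if len(dams) < 3:
        raise ValueError("need at least three dams")
    sizes = np.array([rec.mean_litter_size for rec, _ in dams])
    trs = np.array([tr for _, tr in dams])
    if np.ptp(sizes) == 0 or np.ptp(trs) == 0:
        raise ValueError("zero variance in litter size or TR; correlation undefined")
    r, p = stats.pearsonr(sizes, trs)
    return float(r), float(p)
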