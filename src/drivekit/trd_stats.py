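"""Transmission-ratio estimation and tests against Mendelian expectation.

A heterozygous parent transmits its focal allele (here, the WSB/EiJ-like
high-copy allele) to a fraction TR of its genotyped offspring.  Under
Mendel's second law TR = 0.5; transmission ratio distortion (TRD) is a
significant, reproducible departure from that expectation.  This module
computes TR from raw offspring counts, tests it with a two-cell chi-square
goodness-of-fit statistic (the form appropriate for aggregate counts) and a
one-sided exact binomial test (appropriate for the small per-dam samples),
attaches Clopper-Pearson confidence intervals, tests heterogeneity of TR
across breeding units, and assigns the standard N/L/M/H/U severity labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import isfinite

from scipy import stats

__all__ = [
    "TransmissionRecord",
    "TrResult",
    "EmptyDataError",
    "transmission_ratio",
    "chi2_gof",
    "binom_exact",
    "binom_ci",
    "heterogeneity_test",
    "classify_trd",
    "tr_test",
    "pool_records",
    "round_printed",
]


class EmptyDataError(ValueError):
    """Raised when an operation requires at least one genotyped offspring."""


@dataclass(frozen=True)
class TransmissionRecord:
    """Offspring counts for one breeding unit (a dam, a sire, or a pooled cross).

    ``n_carrier`` counts offspring that inherited the focal allele from the
    heterozygous parent; ``n_noncarrier`` counts those that inherited the
    alternative allele.  ``role`` records which parent was heterozygous,
    because maternal and paternal transmission behave differently.
    """

    unit_id: str
    role: str  # "dam" or "sire"
    n_carrier: int
    n_noncarrier: int

    def __post_init__(self) -> None:
        if self.role not in ("dam", "sire"):
            raise ValueError(f"role must be 'dam' or 'sire', got {self.role!r}")
        for name in ("n_carrier", "n_noncarrier"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool):
                raise TypeError(f"{name} must be an integer, got {v!r}")
            if v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")

    @property
    def n(self) -> int:
        return self.n_carrier + self.n_noncarrier


@dataclass(frozen=True)
class TrResult:
    """Transmission ratio with its tests and confidence interval."""

    unit_id: str
    tr: float
    chi2: float
    p_chi2: float
    p_binom: float
    ci_low: float
    ci_high: float
    n: int

    def __post_init__(self) -> None:
        if not (self.ci_low - 1e-12 <= self.tr <= self.ci_high + 1e-12):
            raise ValueError("confidence interval must bracket the point estimate")


def _require_nonempty(rec: TransmissionRecord) -> int:
    n = rec.n
    if n == 0:
        raise EmptyDataError(f"unit {rec.unit_id!r} has zero genotyped offspring")
    return n


def transmission_ratio(rec: TransmissionRecord) -> float:
    """Fraction of offspring inheriting the focal allele, W / (W + N)."""
    n = _require_nonempty(rec)
    return rec.n_carrier / n


def chi2_gof(rec: TransmissionRecord) -> tuple[float, float]:
    """Two-cell chi-square goodness-of-fit test against equal transmission.

    Both genotype classes are compared with their expectation n/2, giving the
    1-df statistic (W - N)^2 / n.  Returns ``(statistic, p)`` with p the
    upper-tail chi-square probability.
    """
    n = _require_nonempty(rec)
    statistic = (rec.n_carrier - rec.n_noncarrier) ** 2 / n
    p = float(stats.chi2.sf(statistic, df=1))
    return float(statistic), p


def binom_exact(rec: TransmissionRecord, side: str = "carrier-excess") -> float:
    """Exact binomial test of TR = 0.5.

    ``side='carrier-excess'`` (the usual question for a drive candidate)
    returns P(X >= W | n, 1/2); ``side='two-sided'`` doubles the smaller
    tail, capped at 1.
    """
    n = _require_nonempty(rec)
    if side == "carrier-excess":
        alternative = "greater"
    elif side == "two-sided":
        alternative = "two-sided"
    else:
        raise ValueError(f"side must be 'carrier-excess' or 'two-sided', got {side!r}")
    res = stats.binomtest(rec.n_carrier, n, p=0.5, alternative=alternative)
    if side == "two-sided":
        # enforce the stated doubled-smaller-tail convention
        lower = stats.binom.cdf(rec.n_carrier, n, 0.5)
        upper = stats.binom.sf(rec.n_carrier - 1, n, 0.5)
        return float(min(1.0, 2.0 * min(lower, upper)))
    return float(res.pvalue)


def binom_ci(rec: TransmissionRecord, level: float = 0.95) -> tuple[float, float]:
    """Clopper-Pearson exact confidence interval for the transmission ratio."""
    n = _require_nonempty(rec)
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    ci = stats.binomtest(rec.n_carrier, n).proportion_ci(
        confidence_level=level, method="exact"
    )
    return float(ci.low), float(ci.high)


def heterogeneity_test(recs: list[TransmissionRecord]) -> tuple[float, float]:
    """K x 2 contingency chi-square for equality of TR across units (df = K-1)."""
    if len(recs) < 2:
        raise ValueError("heterogeneity test requires at least two units")
    table = []
    for rec in recs:
        _require_nonempty(rec)
        table.append([rec.n_carrier, rec.n_noncarrier])
    res = stats.chi2_contingency(table, correction=False)
    return float(res.statistic), float(res.pvalue)


def classify_trd(tr: float, p: float, n: int) -> str:
    """Assign a TRD severity label from TR, its p-value and the sample size.

    Labels: ``U`` unclassifiable (n < 10), ``N`` no distortion
    (TR < 0.6 or p >= 0.1), ``L`` low (TR >= 0.6 but p > 0.05),
    ``H`` high (TR >= 0.92 with p <= 0.05), ``M`` intermediate otherwise.
    """
    if n < 10:
        return "U"
    if tr < 0.6 or p >= 0.1:
        return "N"
    if p > 0.05:
        return "L"
    if tr >= 0.92:
        return "H"
    return "M"


def tr_test(
    rec: TransmissionRecord,
    side: str = "carrier-excess",
    level: float = 0.95,
) -> TrResult:
    """Full per-unit summary: TR, chi-square and binomial tests, and CI."""
    tr = transmission_ratio(rec)
    chi2_stat, p_chi2 = chi2_gof(rec)
    p_binom = binom_exact(rec, side=side)
    low, high = binom_ci(rec, level=level)
    return TrResult(
        unit_id=rec.unit_id,
        tr=tr,
        chi2=chi2_stat,
        p_chi2=p_chi2,
        p_binom=p_binom,
        ci_low=low,
        ci_high=high,
        n=rec.n,
    )


def pool_records(
    recs: list[TransmissionRecord], unit_id: str, role: str
) -> TransmissionRecord:
    """Pool counts across units into one aggregate record."""
    return TransmissionRecord(
        unit_id=unit_id,
        role=role,
        n_carrier=sum(r.n_carrier for r in recs),
        n_noncarrier=sum(r.n_noncarrier for r in recs),
    )


def round_printed(x: float, decimals: int = 3) -> float:
    """Round half away from zero, the convention used in printed TR tables."""
    if not isfinite(x):
        return x
    scale = 10**decimals
    shifted = x * scale
    rounded = int(shifted + 0.5) if shifted >= 0 else -int(-shifted + 0.5)
    return rounded / scale
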