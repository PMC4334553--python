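"""Real-time PCR (TaqMan) copy-number estimation on the ΔCt scale.

A TaqMan copy-number assay reports the cycle threshold (Ct) at which a
target amplicon and a single-copy reference amplicon cross a fluorescence
threshold.  Under doubling-per-cycle amplification the relative cycle
threshold ΔCt = Ct_reference - Ct_target rises by one cycle for each
doubling of target copy number, so ΔCt is linear in log2(copy number).
Raw ΔCt values are, however, offset by the assay batch (plate, reagent lot)
and by the target-reference pairing.  Those technical offsets are estimated
from control samples of known copy number that are replicated in every
batch, using a two-way additive random-effects fit with shrinkage toward
zero, and subtracted from every sample's raw ΔCt.  ΔCt is the primary
reported scale; extrapolated copy number (via a log2-linear calibration)
is opt-in, because constant noise on the log scale grows exponentially on
the linear scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CtRecord",
    "NormalizedDCt",
    "Calibration",
    "SeparationError",
    "delta_ct",
    "batch_normalize",
    "calibrate_cn",
    "genotype_by_dct",
]

log = logging.getLogger(__name__)


class SeparationError(RuntimeError):
    """Raised when ΔCt values cannot be split into two genotype classes."""


@dataclass(frozen=True)
class CtRecord:
    """One well: target and reference cycle thresholds plus batch/assay labels."""

    sample_id: str
    batch: str
    assay_pair: str
    ct_target: float
    ct_reference: float
    is_control: bool = False
    control_cn: float | None = None

    def __post_init__(self) -> None:
        for name in ("ct_target", "ct_reference"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be positive and finite, got {v}")
        if self.is_control and self.control_cn is None:
            raise ValueError("control records must carry control_cn")


@dataclass
class NormalizedDCt:
    """Raw and batch-corrected ΔCt for one well."""

    sample_id: str
    batch: str
    assay_pair: str
    dct_raw: float
    dct_norm: float
    normalized: bool = True
    is_control: bool = False
    control_cn: float | None = None
    predicted_cn: float | None = None


def delta_ct(rec: CtRecord) -> float:
    """Relative cycle threshold, Ct_reference - Ct_target."""
    return rec.ct_reference - rec.ct_target


def _backfit_effects(
    resid: np.ndarray, batches: np.ndarray, pairs: np.ndarray, n_iter: int = 20
) -> tuple[dict[str, float], dict[str, float], float]:
    """Two-way additive effects by backfitting on genotype-centred residuals."""
    b_eff = {b: 0.0 for b in np.unique(batches)}
    p_eff = {p: 0.0 for p in np.unique(pairs)}
    for _ in range(n_iter):
        r = resid - np.array([p_eff[p] for p in pairs])
        for b in b_eff:
            b_eff[b] = float(r[batches == b].mean())
        r = resid - np.array([b_eff[b] for b in batches])
        for p in p_eff:
            p_eff[p] = float(r[pairs == p].mean())
    fitted = np.array([b_eff[b] for b in batches]) + np.array(
        [p_eff[p] for p in pairs]
    )
    resid_var = float(np.var(resid - fitted, ddof=1)) if resid.size > 2 else 0.0
    return b_eff, p_eff, resid_var


def _shrink(effects: dict[str, float], counts: dict[str, int], resid_var: float) -> dict[str, float]:
    """Method-of-moments shrinkage of raw group means toward zero."""
    raw = np.array(list(effects.values()))
    ns = np.array([counts[k] for k in effects])
    if raw.size < 2:
        return {k: 0.0 for k in effects}
    var_between = max(0.0, float(np.var(raw, ddof=1)) - resid_var * float(np.mean(1.0 / ns)))
    return {
        k: effects[k] * var_between / (var_between + resid_var / counts[k])
        if (var_between + resid_var / counts[k]) > 0
        else 0.0
        for k in effects
    }


def batch_normalize(records: list[CtRecord]) -> list[NormalizedDCt]:
    """Estimate and subtract batch and assay-pair offsets from raw ΔCt.

    Offsets are estimated only from control samples, after centring each
    control genotype (known copy-number class) on its grand mean so that
    genotype differences do not leak into the technical effects.  The
    two-way additive effects are shrunk toward zero by a method-of-moments
    variance-component estimator (the BLUP property for a balanced control
    design) and subtracted from every record.  Batches containing no
    controls are flagged un-normalized and passed through unchanged.
    """
    if not records:
        return []
    controls = [r for r in records if r.is_control]
    batches_all = {r.batch for r in records}
    batches_with_controls = {r.batch for r in controls}
    n_batches = len(batches_with_controls)

    b_eff: dict[str, float] = {}
    p_eff: dict[str, float] = {}
    if n_batches < 2:
        log.warning(
            "fewer than two batches with controls; ΔCt passed through unchanged"
        )
    else:
        dct = np.array([delta_ct(r) for r in controls])
        cls = np.array([r.control_cn for r in controls], dtype=float)
        batches = np.array([r.batch for r in controls])
        pairs = np.array([r.assay_pair for r in controls])
        # centre each control genotype on its grand mean across batches
        resid = dct.copy()
        for c in np.unique(cls):
            mask = cls == c
            resid[mask] -= dct[mask].mean()
        raw_b, raw_p, resid_var = _backfit_effects(resid, batches, pairs)
        b_counts = {b: int((batches == b).sum()) for b in raw_b}
        p_counts = {p: int((pairs == p).sum()) for p in raw_p}
        b_eff = _shrink(raw_b, b_counts, resid_var)
        p_eff = _shrink(raw_p, p_counts, resid_var)

    out = []
    for r in records:
        raw = delta_ct(r)
        if r.batch in batches_with_controls and n_batches >= 2:
            offset = b_eff.get(r.batch, 0.0) + p_eff.get(r.assay_pair, 0.0)
            out.append(
                NormalizedDCt(
                    r.sample_id, r.batch, r.assay_pair, raw, raw - offset,
                    normalized=True, is_control=r.is_control, control_cn=r.control_cn,
                )
            )
        else:
            if r.batch not in batches_with_controls:
                log.warning("batch %r has no controls; record left un-normalized", r.batch)
            out.append(
                NormalizedDCt(
                    r.sample_id, r.batch, r.assay_pair, raw, raw,
                    normalized=n_batches < 2, is_control=r.is_control,
                    control_cn=r.control_cn,
                )
            )
    return out


@dataclass(frozen=True)
class Calibration:
    """Least-squares fit of log2(copy number) = intercept + slope * ΔCt."""

    intercept: float
    slope: float

    def predict(self, dct_norm: float | np.ndarray) -> float | np.ndarray:
        return 2.0 ** (self.intercept + self.slope * np.asarray(dct_norm, dtype=float))


def _sample_means(norm: list[NormalizedDCt]) -> dict[str, float]:
    acc: dict[str, list[float]] = {}
    for r in norm:
        acc.setdefault(r.sample_id, []).append(r.dct_norm)
    return {s: float(np.mean(v)) for s, v in acc.items()}


def calibrate_cn(
    norm: list[NormalizedDCt],
    calibrators: list[tuple[str, float]],
    round_to_integer: bool = False,
) -> tuple[dict[str, float], Calibration]:
    """Calibrate normalized ΔCt to copy number and predict for every sample.

    ``calibrators`` are (sample_id, known copy number) pairs; at least two
    distinct copy-number levels are required.  Fits
    log2(cn) = a + b * ΔCt_norm by least squares on the per-sample mean
    ΔCt of the calibrators (b is ~1 under perfect doubling efficiency) and
    returns predicted copy numbers for every sample plus the fit itself.
    """
    means = _sample_means(norm)
    xs, ys = [], []
    for sid, cn in calibrators:
        if sid not in means:
            raise ValueError(f"calibrator sample {sid!r} absent from normalized data")
        if cn <= 0:
            raise ValueError("calibrator copy numbers must be positive")
        xs.append(means[sid])
        ys.append(np.log2(cn))
    if len({cn for _, cn in calibrators}) < 2:
        raise ValueError("need calibrators at >= 2 distinct copy-number levels")
    slope, intercept = np.polyfit(xs, ys, deg=1)
    cal = Calibration(intercept=float(intercept), slope=float(slope))
    preds = {s: float(cal.predict(m)) for s, m in means.items()}
    if round_to_integer:
        preds = {s: float(max(1, round(v))) for s, v in preds.items()}
    return preds, cal


def genotype_by_dct(
    norm: list[NormalizedDCt],
    cutpoint: float | None = None,
    min_silhouette: float = 0.5,
) -> dict[str, tuple[str, float]]:
    """Classify samples as carrying the high- or low-copy allele from ΔCt.

    With no explicit ``cutpoint``, the per-sample mean ΔCt values are split
    by two-class 1-d k-means and the silhouette of the split must reach
    ``min_silhouette``; otherwise the call is refused with a diagnostic.
    Returns per sample ``(label, margin)`` with margin the distance from the
    cutpoint in cycles.
    """
    means = _sample_means(norm)
    if cutpoint is None:
        if len(means) < 2:
            raise SeparationError("cannot cluster fewer than two samples")
        x = np.array(list(means.values())).reshape(-1, 1)
        if np.ptp(x) == 0:
            raise SeparationError("all ΔCt values identical; classes non-separable")
        from sklearn.cluster import KMeans
        from sklearn.metrics import silhouette_score

        km = KMeans(n_clusters=2, n_init=10, random_state=0).fit(x)
        if len(set(km.labels_)) < 2:
            raise SeparationError("k-means produced a single class")
        sil = float(silhouette_score(x, km.labels_))
        if sil < min_silhouette:
            raise SeparationError(
                f"ΔCt classes not separable (silhouette {sil:.2f} < {min_silhouette})"
            )
        cutpoint = float(np.mean(km.cluster_centers_))
    out = {}
    for sid, m in means.items():
        label = "high_allele" if m >= cutpoint else "low_allele"
        out[sid] = (label, abs(m - cutpoint))
    return out
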