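"""Generators for every input the pipeline consumes.

The generative model mirrors the biology of a maternal meiotic-drive
system with partially linked embryonic lethality:

* A heterozygous dam ovulates O ~ Poisson(lam) oocytes per litter; each
  functional oocyte carries the focal allele with probability m (drive
  strength; m = 0.5 is fair segregation).  Non-carrier embryos die in
  utero with probability d (genotype-linked lethality); all embryos
  additionally die with probability a (genotype-independent loss).
  Closed forms: E[TR] = m / (m + (1-m)(1-d));
  E[litter] = lam (1-a) (m + (1-m)(1-d)).
* Sequencing depth over a copy-number expansion is Poisson(depth_mu * CN).
* Array probe intensity is base + slope*log2(CN) + Gaussian noise.
* TaqMan cycle thresholds follow perfect doubling (ΔCt = const + log2 CN)
  plus batch offsets and well noise; control samples of known copy number
  ride along in duplicate in every batch.
* Backcross genotypes recombine between adjacent markers with the Haldane
  map function r = (1 - exp(-2 d_cM/100)) / 2.

Named scenarios pin the study conditions: ``mendelian`` (fair
segregation), ``pure_drive_094`` (drive only, TR 0.94),
``pure_lethality_075`` (lethality only tuned to TR 0.75) and
``mixed_do_g13`` (drive plus lethality reproducing TR 0.78 with mean
litter 6.8 against a no-distortion mean of 9.4).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .cnv_depth import DepthProfile
from .drive_lethality import LitterRecord
from .haplotype_interval import HaplotypeMosaic
from .qtl_scan import MarkerMatrix
from .taqman_cn import CtRecord

__all__ = [
    "SimConfig",
    "SCENARIOS",
    "scenario",
    "simulate_litters",
    "simulate_depth",
    "simulate_array",
    "simulate_ct",
    "simulate_backcross",
    "simulate_mosaics",
    "CONTROL_CN_PANEL",
]

log = logging.getLogger(__name__)

# Control genotypes carried in every assay batch: single-copy reference
# strain, two-copy strain, high-copy strain and its F1 with the reference
# (mean haploid copy numbers 1, 2, 17 and 33).
CONTROL_CN_PANEL = (1.0, 2.0, 17.0, 33.0)


@dataclass(frozen=True)
class SimConfig:
    """Shared parameters for all generators.  ``seed`` is mandatory."""

    seed: int
    m: float = 0.5  # drive strength: P(functional oocyte carries focal allele)
    d: float = 0.0  # death probability of non-carrier embryos
    a: float = 0.0  # genotype-independent embryo loss
    lam: float = 8.4  # mean ovulation count per litter (Poisson)
    n_dams: int = 100
    litters_per_dam: int = 5
    cn_alleles: tuple[int, ...] = (1, 2, 11, 24, 34, 36)
    depth_mu: float = 30.0  # mean per-base sequencing depth at single copy
    ct_noise_sd: float = 0.15  # per-well Ct noise, cycles
    batch_sd: float = 1.0  # sd of between-batch ΔCt offsets, cycles

    def __post_init__(self) -> None:
        for name in ("m", "d", "a"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.lam <= 0:
            raise ValueError("lam must be positive")
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("seed is mandatory and must be an integer")

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.seed, stream))

    @property
    def expected_tr(self) -> float:
        surv = self.m + (1 - self.m) * (1 - self.d)
        return self.m / surv

    @property
    def expected_litter_size(self) -> float:
        return self.lam * (1 - self.a) * (self.m + (1 - self.m) * (1 - self.d))


# Scenario parameters are study conditions, chosen once:
# pure_lethality_075 uses d = 2 - 1/0.75 = 2/3 so that lethality alone
# forces TR = 0.75; mixed_do_g13 solves E[TR] = 0.78 and
# E[litter] = 6.8 against a no-distortion mean of 9.4.
SCENARIOS: dict[str, dict] = {
    "mendelian": dict(m=0.5, d=0.0, a=0.0, lam=8.4),
    "pure_drive_094": dict(m=0.94, d=0.0, a=0.0, lam=8.4),
    "pure_lethality_075": dict(m=0.5, d=2.0 / 3.0, a=0.0, lam=8.4),
    "mixed_do_g13": dict(m=0.5643, d=0.6348, a=0.0, lam=9.4),
}


def scenario(name: str, seed: int, **overrides) -> SimConfig:
    """Named study-condition presets; ``overrides`` adjust sizes, not biology."""
    if name not in SCENARIOS:
        raise KeyError(f"unknown scenario {name!r}; choose from {sorted(SCENARIOS)}")
    params = {**SCENARIOS[name], **overrides}
    return SimConfig(seed=seed, **params)


def simulate_litters(cfg: SimConfig) -> list[LitterRecord]:
    """Litter records for ``n_dams`` dams under drive m and lethality d/a."""
    rng = cfg.rng(stream=1)
    records = []
    for i in range(cfg.n_dams):
        sizes, carr, nonc = [], [], []
        resorbed_total = 0
        for _ in range(cfg.litters_per_dam):
            oocytes = rng.poisson(cfg.lam)
            carriers = rng.binomial(oocytes, cfg.m)
            noncarriers = oocytes - carriers
            nc_dead = rng.binomial(noncarriers, cfg.d)
            nc_alive = noncarriers - nc_dead
            c_alive = rng.binomial(carriers, 1 - cfg.a)
            nc_alive = rng.binomial(nc_alive, 1 - cfg.a)
            sizes.append(c_alive + nc_alive)
            carr.append(c_alive)
            nonc.append(nc_alive)
            resorbed_total += oocytes - c_alive - nc_alive
        records.append(
            LitterRecord(
                dam_id=f"dam{i:04d}",
                litter_sizes=tuple(sizes),
                per_litter_carrier=tuple(carr),
                per_litter_noncarrier=tuple(nonc),
                live_embryos=int(sum(sizes)),
                resorbed_embryos=int(resorbed_total),
            )
        )
    return records


def simulate_depth(
    cfg: SimConfig,
    region_length: int,
    cnv_start: int,
    cnv_length: int,
    haploid_cn: int,
    chrom: str = "chr2",
) -> DepthProfile:
    """Per-base Poisson depth with a planted copy-number segment."""
    if cfg.depth_mu <= 0:
        raise ValueError("depth_mu must be positive")
    if cfg.depth_mu < 1:
        log.warning(
            "mean depth %.3g is below 1x; copy-number calls will be unreliable",
            cfg.depth_mu,
        )
    if not (0 <= cnv_start and cnv_start + cnv_length <= region_length):
        raise ValueError("planted segment must lie inside the region")
    rng = cfg.rng(stream=2)
    local_cn = np.ones(region_length)
    local_cn[cnv_start : cnv_start + cnv_length] = haploid_cn
    depths = rng.poisson(cfg.depth_mu * local_cn).astype(float)
    return DepthProfile(
        chrom=chrom, start=0, depths=depths, genome_mean=cfg.depth_mu
    )


def simulate_array(
    cfg: SimConfig,
    samples_with_cn: list[tuple[str, float]],
    n_probes: int = 3,
    base: float = 0.5,
    slope: float = 0.4,
    noise_sd: float = 0.05,
):
    """Probe x sample intensity matrix proportional to log2 copy number.

    Defaults separate copy-number classes {1, 2, 34} cleanly: class means
    differ by slope*log2 steps that are many noise sd apart.
    """
    import pandas as pd

    rng = cfg.rng(stream=3)
    probes = [f"probe{i:02d}" for i in range(n_probes)]
    data = {}
    for sid, cn in samples_with_cn:
        if cn <= 0:
            raise ValueError("copy numbers must be positive")
        mu = base + slope * np.log2(cn)
        data[sid] = mu + rng.normal(0.0, noise_sd, size=n_probes)
    return pd.DataFrame(data, index=probes)


def simulate_ct(
    cfg: SimConfig,
    samples_with_cn: list[tuple[str, float]],
    n_batches: int = 4,
    replicates: int = 2,
    assay_pairs: tuple[str, ...] = ("cwc22prox-tert", "cwc22dist-tfrc"),
    control_replicates: int = 2,
    assay_pair_sd: float = 0.3,
) -> list[CtRecord]:
    """TaqMan wells for test samples plus the control panel in every batch.

    Each sample is assayed with every target-reference pair in
    ``replicates`` wells; control genotypes (copy numbers 1, 2, 17, 33)
    ride along in every batch in duplicate.  Ct values follow perfect
    doubling: ct_target = c0 - log2(cn) + batch offset + well noise, with
    the reference sharing the batch offset so that batch effects survive
    the ΔCt subtraction only through their assay-dependent component plus
    the simulated ΔCt-scale offset.
    """
    if n_batches < 1:
        raise ValueError("need at least one batch")
    rng = cfg.rng(stream=4)
    if n_batches == 1:
        log.warning("single batch: batch effects are unidentifiable")
    batch_names = [f"batch{b:02d}" for b in range(n_batches)]
    batch_offset = rng.normal(0.0, cfg.batch_sd, size=n_batches)
    pair_offset = {p: rng.normal(0.0, assay_pair_sd) for p in assay_pairs}
    c_target, c_reference = 22.0, 24.0

    def wells(sid, cn, batch_i, is_control):
        recs = []
        for pair in assay_pairs:
            for _ in range(control_replicates if is_control else replicates):
                dct_true = (
                    np.log2(cn)
                    + batch_offset[batch_i]
                    + pair_offset[pair]
                )
                ct_t = c_target - dct_true / 2 + rng.normal(0, cfg.ct_noise_sd)
                ct_r = c_reference + dct_true / 2 + rng.normal(0, cfg.ct_noise_sd)
                # ct_r - ct_t = (c_reference - c_target) + dct_true + noise
                recs.append(
                    CtRecord(
                        sample_id=sid,
                        batch=batch_names[batch_i],
                        assay_pair=pair,
                        ct_target=ct_t,
                        ct_reference=ct_r,
                        is_control=is_control,
                        control_cn=cn if is_control else None,
                    )
                )
        return recs

    records: list[CtRecord] = []
    for b in range(n_batches):
        for cn in CONTROL_CN_PANEL:
            records.extend(wells(f"control_cn{int(cn)}", cn, b, True))
    for i, (sid, cn) in enumerate(samples_with_cn):
        records.extend(wells(sid, cn, i % n_batches, False))
    return records


def haldane_r(d_cM: float) -> float:
    """Recombination fraction between loci d_cM apart (Haldane, no interference)."""
    return 0.5 * (1.0 - np.exp(-2.0 * d_cM / 100.0))


def simulate_backcross(
    cfg: SimConfig,
    marker_map: list[tuple[str, float, float]],
    n_individuals: int,
    qtl_index: int | None = None,
    effect_size: float = 0.0,
    binary: bool = False,
    penetrance: tuple[float, float] = (0.0, 1.0),
) -> tuple[MarkerMatrix, np.ndarray]:
    """Backcross genotypes on a genetic map plus a phenotype.

    ``marker_map`` rows are (chrom, position_bp, position_cM).  Each
    individual inherits one recombinant gamete from the heterozygous
    parent: the code (1 = heterozygous focal, 0 = homozygous non-focal)
    starts fair at the first marker of each chromosome and switches between
    adjacent markers with the Haldane recombination fraction.  The
    phenotype is effect_size * code_at_qtl + N(0, 1), or, if ``binary``,
    Bernoulli with P(1) = penetrance[code].
    """
    rng = cfg.rng(stream=5)
    loci = tuple((c, float(p)) for c, p, _ in marker_map)
    cM = [float(g) for _, _, g in marker_map]
    chroms = [c for c, _, _ in marker_map]
    n_loci = len(loci)
    codes = np.empty((n_individuals, n_loci))
    codes[:, 0] = rng.integers(0, 2, size=n_individuals)
    for j in range(1, n_loci):
        if chroms[j] != chroms[j - 1]:
            codes[:, j] = rng.integers(0, 2, size=n_individuals)
            continue
        r = haldane_r(cM[j] - cM[j - 1])
        flip = rng.random(n_individuals) < r
        codes[:, j] = np.where(flip, 1 - codes[:, j - 1], codes[:, j - 1])
    markers = MarkerMatrix(
        individuals=tuple(f"ind{i:04d}" for i in range(n_individuals)),
        loci=loci,
        codes=codes,
    )
    if qtl_index is None:
        code_at_qtl = np.zeros(n_individuals)
    else:
        code_at_qtl = codes[:, qtl_index]
    if binary:
        p = np.where(code_at_qtl == 1, penetrance[1], penetrance[0])
        phenotype = (rng.random(n_individuals) < p).astype(float)
    else:
        phenotype = effect_size * code_at_qtl + rng.normal(0, 1, n_individuals)
    return markers, phenotype


def simulate_mosaics(
    cfg: SimConfig,
    truth_interval: tuple[float, float],
    n_individuals: int = 10,
    chrom: str = "chr2",
    chrom_length: float = 100.0,
    founders: tuple[str, ...] = ("A", "B", "C", "D", "E", "F", "G", "H"),
    focal: str = "H",
    distorter_suppression: float = 0.0,
) -> list[HaplotypeMosaic]:
    """Founder mosaics with a planted causal interval.

    Each individual carries a focal-haplotype segment with random
    endpoints; the phenotype is positive iff that segment covers the whole
    ``truth_interval`` — unless an unlinked distorter (probability
    ``distorter_suppression``) suppresses the phenotype, in which case a
    carrier is labeled unaffected, mimicking modifier loci that silence
    the distortion.
    """
    lo, hi = truth_interval
    if not (0 <= lo < hi <= chrom_length):
        raise ValueError("truth interval must lie inside the chromosome")
    rng = cfg.rng(stream=6)
    others = [f for f in founders if f != focal]
    mosaics = []
    n_carriers_seen = 0
    for i in range(n_individuals):
        covers = i % 2 == 0  # alternate carriers and partial carriers
        if covers:
            a = rng.uniform(0, lo) if lo > 0 else 0.0
            b = rng.uniform(hi, chrom_length) if hi < chrom_length else chrom_length
            # the first two carriers are the critical recombinants whose
            # breakpoints coincide with the causal boundaries, so the
            # carrier overlap equals the planted interval exactly
            if n_carriers_seen == 0 and lo > 0:
                a = lo
            elif n_carriers_seen == 1 and hi < chrom_length:
                b = hi
            n_carriers_seen += 1
        else:
            # focal segment that misses part of the causal interval
            if rng.random() < 0.5 and lo > 0:
                a, b = 0.0, rng.uniform(lo, hi)
            else:
                a, b = rng.uniform(lo, hi), chrom_length
        segments = []
        if a > 0:
            segments.append((0.0, a, str(rng.choice(others))))
        segments.append((a, b, focal))
        if b < chrom_length:
            segments.append((b, chrom_length, str(rng.choice(others))))
        suppressed = covers and rng.random() < distorter_suppression
        phenotype = "TRD" if covers and not suppressed else "no_TRD"
        mosaics.append(
            HaplotypeMosaic(
                individual_id=f"mosaic{i:03d}",
                chrom=chrom,
                segments=tuple(segments),
                phenotype=phenotype,
            )
        )
    return mosaics
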