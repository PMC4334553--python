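"""Candidate-interval refinement from founder haplotype mosaics.

Recombinant inbred and outbred mouse populations (Collaborative Cross,
Diversity Outbred) carry chromosomes that are mosaics of eight founder
haplotypes.  Three complementary localization strategies are implemented:

* ``overlap_interval`` — the region carried as the focal founder haplotype
  by *every* phenotype-positive individual; recombinations trim it from
  both sides, so the intersection shrinks as informative mosaics are added.
* ``critical_recombinants`` — individuals whose recombination breakpoint,
  combined with a two-class quantitative readout (e.g. array sum-intensity
  tracking a copy-number expansion), place the causal element inside their
  focal coverage (high class) or outside it (low class); the interval is
  the set intersection of those constraints.
* ``consistent_snp_scan`` — windows in which phenotype-positive strains
  share an allele that no phenotype-negative strain carries; a run of such
  windows marks a shared ancestral segment harboring the causal variant.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "HaplotypeMosaic",
    "CandidateInterval",
    "SnpMatrix",
    "NoOverlapError",
    "overlap_interval",
    "critical_recombinants",
    "consistent_snp_scan",
    "mean_snp_spacing",
]

log = logging.getLogger(__name__)


class NoOverlapError(ValueError):
    """Raised when phenotype-positive mosaics share no focal region."""


@dataclass(frozen=True)
class HaplotypeMosaic:
    """Ordered founder-labeled segments along one chromosome for one individual."""

    individual_id: str
    chrom: str
    segments: tuple[tuple[float, float, str], ...]  # (start, end, founder)
    phenotype: str = "unknown"  # "TRD" | "no_TRD" | "unknown"
    quantitative_value: float | None = None

    def __post_init__(self) -> None:
        segs = tuple((float(a), float(b), f) for a, b, f in self.segments)
        object.__setattr__(self, "segments", segs)
        if self.phenotype not in ("TRD", "no_TRD", "unknown"):
            raise ValueError(f"invalid phenotype {self.phenotype!r}")
        for a, b, _ in segs:
            if a >= b:
                raise ValueError("segments must have start < end")
        for (a0, b0, _), (a1, b1, _) in zip(segs[:-1], segs[1:]):
            if a1 < b0:
                raise ValueError("segments must be sorted and non-overlapping")

    def cover(self, founder: str) -> list[tuple[float, float]]:
        """Merged intervals carried as ``founder``."""
        ivs = [(a, b) for a, b, f in self.segments if f == founder]
        merged: list[list[float]] = []
        for a, b in ivs:
            if merged and a <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], b)
            else:
                merged.append([a, b])
        return [(a, b) for a, b in merged]


@dataclass(frozen=True)
class CandidateInterval:
    chrom: str
    proximal: float
    distal: float
    defining_individuals: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.proximal < self.distal:
            raise ValueError("proximal boundary must precede distal")

    @property
    def length(self) -> float:
        return self.distal - self.proximal


def _intersect_covers(
    covers: list[list[tuple[float, float]]],
) -> list[tuple[float, float]]:
    """Intersection of per-individual interval unions."""
    current = covers[0]
    for cov in covers[1:]:
        nxt = []
        for a, b in current:
            for c, d in cov:
                lo, hi = max(a, c), min(b, d)
                if lo < hi:
                    nxt.append((lo, hi))
        current = nxt
        if not current:
            break
    return current


def _subtract(
    intervals: list[tuple[float, float]], cut: list[tuple[float, float]]
) -> list[tuple[float, float]]:
    """Set difference intervals \\ cut."""
    out = intervals
    for c, d in cut:
        nxt = []
        for a, b in out:
            if d <= a or b <= c:
                nxt.append((a, b))
                continue
            if a < c:
                nxt.append((a, c))
            if d < b:
                nxt.append((d, b))
        out = nxt
    return out


def overlap_interval(
    mosaics: list[HaplotypeMosaic], focal: str
) -> CandidateInterval:
    """Maximal interval carried as the focal haplotype by every affected individual.

    Only phenotype-positive ("TRD") mosaics are used; unknowns and
    unaffected individuals carry no mapping information for the overlap.
    The reported boundaries are the outermost positions flanked by
    non-focal evidence: each boundary coincides with a recombination in one
    of the defining individuals.  If the intersection splits into several
    pieces the largest is returned.
    """
    affected = [m for m in mosaics if m.phenotype == "TRD"]
    if not affected:
        raise ValueError("need at least one phenotype-positive mosaic")
    chroms = {m.chrom for m in affected}
    if len(chroms) != 1:
        raise ValueError(f"mosaics span multiple chromosomes: {sorted(chroms)}")
    covers = []
    for m in affected:
        cov = m.cover(focal)
        if not cov:
            raise NoOverlapError(
                f"individual {m.individual_id!r} carries no {focal!r} segment"
            )
        covers.append(cov)
    pieces = _intersect_covers(covers)
    if not pieces:
        # name one conflicting pair for the error message
        for i, mi in enumerate(affected):
            for mj in affected[i + 1 :]:
                if not _intersect_covers([mi.cover(focal), mj.cover(focal)]):
                    raise NoOverlapError(
                        f"no shared {focal!r} region: {mi.individual_id!r} vs "
                        f"{mj.individual_id!r}"
                    )
        raise NoOverlapError(f"no region is {focal!r} in all affected individuals")
    lo, hi = max(pieces, key=lambda p: p[1] - p[0])
    defining = tuple(
        m.individual_id
        for m in affected
        if any(np.isclose(a, lo) or np.isclose(b, hi) for a, b in m.cover(focal))
    )
    return CandidateInterval(
        chrom=affected[0].chrom, proximal=lo, distal=hi,
        defining_individuals=defining,
    )


def _split_two_classes(values: list[float]) -> float:
    """Cutpoint at the midpoint of the largest gap in sorted values."""
    xs = sorted(values)
    gaps = [(b - a, (a + b) / 2) for a, b in zip(xs[:-1], xs[1:])]
    width, mid = max(gaps)
    if width == 0:
        raise ValueError("quantitative values do not separate into two classes")
    return mid


def critical_recombinants(
    mosaics: list[HaplotypeMosaic],
    focal: str,
    cutpoint: float | None = None,
    region: tuple[float, float] | None = None,
) -> CandidateInterval:
    """Bound the causal element using recombinants with a two-class readout.

    Individuals whose quantitative value is in the high class carry the
    element, so it must lie inside their focal-haplotype coverage;
    low-class individuals lack it, so it must lie outside theirs.  The
    returned interval is the largest component of

        intersection(high covers)  minus  union(low covers),

    which reproduces the four boundary-selection rules (most distal
    recombinant into focal retaining the element, most proximal recombinant
    out of focal retaining it, and their element-free counterparts).  A side
    with no informative recombinant is reported as unbounded (+/-inf) with
    a warning.
    """
    informative = [m for m in mosaics if m.quantitative_value is not None]
    if not informative:
        raise ValueError("no mosaics carry a quantitative value")
    chrom = informative[0].chrom
    if cutpoint is None:
        cutpoint = _split_two_classes([m.quantitative_value for m in informative])
    high = [m for m in informative if m.quantitative_value >= cutpoint]
    low = [m for m in informative if m.quantitative_value < cutpoint]
    if not high or not low:
        raise ValueError("both readout classes must be represented")
    lo_bound, hi_bound = region if region else (-np.inf, np.inf)
    candidate = [(lo_bound, hi_bound)]

    def unbounded_cover(m: HaplotypeMosaic) -> list[tuple[float, float]]:
        # a focal run touching the described end of the mosaic is not
        # recombination-bounded there: extend it to infinity so only true
        # breakpoints constrain the interval
        described_lo = m.segments[0][0]
        described_hi = m.segments[-1][1]
        out = []
        for a, b in m.cover(focal):
            out.append(
                (
                    -np.inf if a == described_lo else a,
                    np.inf if b == described_hi else b,
                )
            )
        return out

    high_covers = [unbounded_cover(m) for m in high]
    if any(not cov for cov in high_covers):
        missing = [m.individual_id for m, c in zip(high, high_covers) if not c]
        raise ValueError(
            f"high-class individuals without any {focal!r} segment: {missing}"
        )
    candidate = _intersect_covers([candidate, *high_covers])
    for m in low:
        candidate = _subtract(candidate, unbounded_cover(m))
    if not candidate:
        raise NoOverlapError("constraints are mutually exclusive; no interval remains")
    lo, hi = max(candidate, key=lambda p: p[1] - p[0])
    if not np.isfinite(lo) or not np.isfinite(hi):
        warnings.warn("no informative recombinant on one side; boundary unbounded")
    defining = tuple(
        m.individual_id
        for m in informative
        if any(
            np.isclose(edge, (lo, hi)).any()
            for seg in m.segments
            for edge in seg[:2]
        )
    )
    return CandidateInterval(
        chrom=chrom, proximal=float(lo), distal=float(hi),
        defining_individuals=defining,
    )


@dataclass(frozen=True)
class SnpMatrix:
    """Biallelic calls (strain x position) with a phenotype partition.

    ``alleles`` uses small integers for alleles and -1 for missing calls.
    """

    strains: tuple[str, ...]
    positions: np.ndarray
    alleles: np.ndarray
    trd_strains: tuple[str, ...]
    non_trd_strains: tuple[str, ...]

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        alle = np.asarray(self.alleles)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "alleles", alle)
        object.__setattr__(self, "strains", tuple(self.strains))
        object.__setattr__(self, "trd_strains", tuple(self.trd_strains))
        object.__setattr__(self, "non_trd_strains", tuple(self.non_trd_strains))
        if alle.shape != (len(self.strains), pos.size):
            raise ValueError("alleles must be strains x positions")
        if np.any(np.diff(pos) < 0):
            raise ValueError("positions must be sorted")
        known = set(self.strains)
        part = set(self.trd_strains) | set(self.non_trd_strains)
        if not part <= known:
            raise ValueError("partition names strains absent from the matrix")
        if set(self.trd_strains) & set(self.non_trd_strains):
            raise ValueError("partition classes must be disjoint")


def consistent_snp_scan(
    snps: SnpMatrix, window: int = 1000, flag_fraction: float = 0.9
) -> pd.DataFrame:
    """Count phenotype-consistent SNPs in non-overlapping windows.

    Per SNP: *shared* means all affected strains carry one identical,
    non-missing allele; *consistent* additionally requires that every
    unaffected strain has a non-missing call different from that allele
    (a missing call anywhere disqualifies the SNP — conservative).
    Windows are anchored at coordinate 0; those with
    fraction_consistent >= ``flag_fraction`` (and at least one SNP) are
    flagged.
    """
    if window < 1:
        raise ValueError("window must be at least 1 base")
    if not snps.trd_strains or not snps.non_trd_strains:
        raise ValueError("both partition classes must be non-empty")
    sidx = {s: i for i, s in enumerate(snps.strains)}
    trd = snps.alleles[[sidx[s] for s in snps.trd_strains], :]
    non = snps.alleles[[sidx[s] for s in snps.non_trd_strains], :]
    shared = (trd >= 0).all(axis=0) & (trd == trd[0]).all(axis=0)
    consistent = (
        shared & (non >= 0).all(axis=0) & (non != trd[0]).all(axis=0)
    )
    win_idx = (snps.positions // window).astype(int)
    rows = []
    for w in range(win_idx.min(), win_idx.max() + 1) if win_idx.size else []:
        mask = win_idx == w
        n = int(mask.sum())
        n_sh = int(shared[mask].sum())
        n_co = int(consistent[mask].sum())
        frac = n_co / n if n else 0.0
        rows.append(
            {
                "win_start": w * window,
                "win_end": (w + 1) * window,
                "n_snps": n,
                "n_shared": n_sh,
                "n_consistent": n_co,
                "fraction_consistent": frac,
                "flagged": bool(n > 0 and frac >= flag_fraction),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "win_start", "win_end", "n_snps", "n_shared",
            "n_consistent", "fraction_consistent", "flagged",
        ],
    )


def mean_snp_spacing(scan: pd.DataFrame, region: tuple[float, float]) -> float:
    """Bases per consistent SNP over a region: length / consistent count."""
    lo, hi = region
    if not lo < hi:
        raise ValueError("region must have positive length")
    inside = scan[(scan["win_start"] >= lo) & (scan["win_end"] <= hi)]
    count = int(inside["n_consistent"].sum())
    if count == 0:
        raise ValueError("region contains no consistent SNP")
    return (hi - lo) / count
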