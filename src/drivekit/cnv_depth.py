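"""Copy-number calling from sequencing read depth.

A tandem copy-number expansion shows up in short-read alignments as a
proportional rise in depth over the reference copy of the repeat unit.  The
caller here follows the classic window/threshold/mode recipe: normalize
per-base depth by the genome-wide mean, average it in consecutive 100 bp
windows, call maximal runs of windows at or above a fold-change threshold
(optionally bridging short sub-threshold gaps, e.g. reference-internal LINE
insertions that attract no reads from the expanded copies), and report the
haploid copy number of each call as the mode of the integer-rounded
normalized per-base depth.

Coordinates are 0-based half-open internally; ``CopyNumberCall`` carries
1-based inclusive output coordinates, the convention of printed genome
positions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DepthProfile",
    "CopyNumberCall",
    "normalize_depth",
    "window_means",
    "call_expansion",
    "modal_copy_number",
]


@dataclass(frozen=True)
class DepthProfile:
    """Per-base read depth over one contiguous window of a chromosome."""

    chrom: str
    start: int  # 0-based inclusive coordinate of depths[0]
    depths: np.ndarray
    genome_mean: float

    def __post_init__(self) -> None:
        d = np.asarray(self.depths, dtype=float)
        object.__setattr__(self, "depths", d)
        if d.ndim != 1:
            raise ValueError("depths must be a 1-D vector")
        if np.any(d < 0):
            raise ValueError("depths must be non-negative")
        if self.genome_mean <= 0:
            raise ValueError("genome_mean must be positive")
        if self.start < 0:
            raise ValueError("start must be non-negative")


@dataclass(frozen=True)
class CopyNumberCall:
    """One called expansion; coordinates are 1-based inclusive."""

    chrom: str
    call_start: int
    call_end: int
    haploid_cn: int
    window_means: np.ndarray
    includes_partial_window: bool = False

    def __post_init__(self) -> None:
        if self.call_start > self.call_end:
            raise ValueError("call_start must not exceed call_end")
        if self.haploid_cn < 1:
            raise ValueError("haploid_cn must be >= 1 inside a call")


def normalize_depth(profile: DepthProfile) -> np.ndarray:
    """Depth divided by the genome-wide mean; 1.0 marks single-copy sequence."""
    return profile.depths / profile.genome_mean


def window_means(norm: np.ndarray, width: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """Means of consecutive non-overlapping windows from the profile start.

    Returns ``(means, partial)`` where ``partial`` flags the final window if
    it spans fewer than ``width`` bases.  The partial window participates in
    calling but is flagged so callers can report it.
    """
    norm = np.asarray(norm, dtype=float)
    if norm.size == 0:
        raise ValueError("empty depth vector")
    if width < 1:
        raise ValueError("window width must be >= 1")
    n_full = norm.size // width
    means = []
    if n_full:
        means.append(norm[: n_full * width].reshape(n_full, width).mean(axis=1))
    tail = norm[n_full * width :]
    partial = np.zeros(n_full + (1 if tail.size else 0), dtype=bool)
    if tail.size:
        means.append(np.array([tail.mean()]))
        partial[-1] = True
    return np.concatenate(means), partial


def modal_copy_number(norm: np.ndarray) -> int:
    """Mode of the integer-rounded normalized per-base depth.

    Ties are broken toward the smaller copy number (conservative), and the
    result is floored at 1: a called expansion is by construction present.
    """
    norm = np.asarray(norm, dtype=float)
    if norm.size == 0:
        raise ValueError("empty segment")
    rounded = np.rint(norm).astype(int)
    values, counts = np.unique(rounded, return_counts=True)
    # np.unique sorts ascending, so argmax takes the smallest value on ties
    return int(max(1, values[np.argmax(counts)]))


def call_expansion(
    profile: DepthProfile,
    threshold: float = 2.0,
    max_gap: int = 5000,
    width: int = 100,
) -> list[CopyNumberCall]:
    """Call copy-number expansions from a depth profile.

    Windows with mean normalized depth >= ``threshold`` seed calls; maximal
    runs separated by at most ``max_gap`` bases of sub-threshold windows are
    merged into a single call (``max_gap=0`` enforces strictly consecutive
    windows).  Each call's haploid copy number is the modal rounded
    normalized per-base depth over its extent.
    """
    if threshold <= 1:
        raise ValueError("threshold must exceed 1 (fold change over single copy)")
    if max_gap < 0:
        raise ValueError("max_gap must be non-negative")
    norm = normalize_depth(profile)
    means, partial = window_means(norm, width=width)
    above = means >= threshold
    if not np.any(above):
        return []

    # maximal runs of above-threshold windows
    idx = np.flatnonzero(above)
    runs: list[list[int]] = [[idx[0], idx[0]]]
    for i in idx[1:]:
        if i == runs[-1][1] + 1:
            runs[-1][1] = i
        else:
            runs.append([i, i])

    # merge runs separated by <= max_gap bases of sub-threshold windows
    max_gap_windows = max_gap // width
    merged: list[list[int]] = [runs[0]]
    for lo, hi in runs[1:]:
        if lo - merged[-1][1] - 1 <= max_gap_windows:
            merged[-1][1] = hi
        else:
            merged.append([lo, hi])

    calls = []
    n = norm.size
    for lo, hi in merged:
        b0 = lo * width  # 0-based inclusive offset within profile
        b1 = min((hi + 1) * width, n)  # 0-based exclusive
        cn = modal_copy_number(norm[b0:b1])
        calls.append(
            CopyNumberCall(
                chrom=profile.chrom,
                call_start=profile.start + b0 + 1,
                call_end=profile.start + b1,
                haploid_cn=cn,
                window_means=means[lo : hi + 1],
                includes_partial_window=bool(partial[lo : hi + 1].any()),
            )
        )
    return calls
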