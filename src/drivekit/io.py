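"""Readers and writers for the tabular and genomic text formats.

TSV/CSV tables use required named headers (never positional columns),
UTF-8, and '.' for missing values.  bedGraph input follows its standard
0-based half-open convention; all genomic text *output* uses 1-based
inclusive coordinates with an explicit header comment.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .cnv_depth import CopyNumberCall, DepthProfile
from .drive_lethality import LitterRecord
from .haplotype_interval import CandidateInterval, HaplotypeMosaic
from .trd_stats import TransmissionRecord, TrResult, classify_trd

__all__ = [
    "read_counts_tsv",
    "write_counts_tsv",
    "read_litters_tsv",
    "read_bedgraph",
    "write_bedgraph",
    "read_mosaics_tsv",
    "write_calls_bed",
    "write_tr_results_tsv",
    "write_interval_json",
    "packaged_cross_counts",
    "MalformedInputError",
]

log = logging.getLogger(__name__)

MISSING = "."


class MalformedInputError(ValueError):
    """Raised for schema violations, with offending line numbers where known."""


def _require_columns(df: pd.DataFrame, required: set[str], path) -> None:
    missing = required - set(df.columns)
    if missing:
        raise MalformedInputError(
            f"{path}: missing required columns {sorted(missing)}"
        )


def read_counts_tsv(path) -> list[TransmissionRecord]:
    """Read per-unit transmission counts.

    Required columns: unit_id, role, n_carrier, n_noncarrier.  Malformed
    rows are reported with their 1-based line numbers.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if df.empty and df.columns.size == 0:
        log.warning("%s: empty file", path)
        return []
    _require_columns(df, {"unit_id", "role", "n_carrier", "n_noncarrier"}, path)
    records, errors = [], []
    for i, row in df.iterrows():
        line_no = i + 2  # header is line 1
        try:
            records.append(
                TransmissionRecord(
                    unit_id=str(row["unit_id"]),
                    role=str(row["role"]),
                    n_carrier=int(row["n_carrier"]),
                    n_noncarrier=int(row["n_noncarrier"]),
                )
            )
        except (TypeError, ValueError) as exc:
            errors.append(f"line {line_no}: {exc}")
    if errors:
        raise MalformedInputError(f"{path}: " + "; ".join(errors))
    if not records:
        log.warning("%s: no data rows", path)
    return records


def write_counts_tsv(records: list[TransmissionRecord], path) -> None:
    pd.DataFrame(
        {
            "unit_id": [r.unit_id for r in records],
            "role": [r.role for r in records],
            "n_carrier": [r.n_carrier for r in records],
            "n_noncarrier": [r.n_noncarrier for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


def write_tr_results_tsv(results: list[TrResult], path) -> None:
    """TrResult table plus the N/L/M/H/U classification (binomial p)."""
    pd.DataFrame(
        {
            "unit_id": [r.unit_id for r in results],
            "n": [r.n for r in results],
            "tr": [r.tr for r in results],
            "chi2": [r.chi2 for r in results],
            "p_chi2": [r.p_chi2 for r in results],
            "p_binom": [r.p_binom for r in results],
            "ci_low": [r.ci_low for r in results],
            "ci_high": [r.ci_high for r in results],
            "trd_class": [classify_trd(r.tr, r.p_binom, r.n) for r in results],
        }
    ).to_csv(path, sep="\t", index=False)


def read_litters_tsv(path) -> list[LitterRecord]:
    """Read long-format litters: dam_id, litter_index, n_carrier, n_noncarrier.

    Optional columns: litter_size (defaults to n_carrier + n_noncarrier)
    and n_resorbed (summed per dam).
    """
    df = pd.read_csv(path, sep="\t", na_values=[MISSING], comment="#")
    _require_columns(df, {"dam_id", "litter_index", "n_carrier", "n_noncarrier"}, path)
    records = []
    for dam_id, sub in df.groupby("dam_id", sort=False):
        sub = sub.sort_values("litter_index")
        carr = sub["n_carrier"].astype(int).tolist()
        nonc = sub["n_noncarrier"].astype(int).tolist()
        if "litter_size" in sub.columns:
            sizes = sub["litter_size"].astype(int).tolist()
        else:
            sizes = [c + k for c, k in zip(carr, nonc)]
        resorbed = None
        if "n_resorbed" in sub.columns and not sub["n_resorbed"].isna().all():
            resorbed = int(sub["n_resorbed"].fillna(0).sum())
        records.append(
            LitterRecord(
                dam_id=str(dam_id),
                litter_sizes=tuple(sizes),
                per_litter_carrier=tuple(carr),
                per_litter_noncarrier=tuple(nonc),
                resorbed_embryos=resorbed,
            )
        )
    return records


def read_bedgraph(path, genome_mean: float | None = None) -> DepthProfile:
    """Expand a 4-column bedGraph (0-based half-open) to per-base depth.

    Records must be sorted, non-overlapping and contiguous over one
    chromosome; a gap or overlap raises an error naming the coordinates.
    ``genome_mean`` defaults to the mean of the expanded window (supply the
    true genome-wide mean whenever it is known).
    """
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "depth"],
    )
    if df.empty:
        raise MalformedInputError(f"{path}: empty bedGraph")
    chroms = df["chrom"].unique()
    if len(chroms) != 1:
        raise MalformedInputError(f"{path}: expected one chromosome, got {list(chroms)}")
    prev_end = None
    for _, row in df.iterrows():
        s, e = int(row["start"]), int(row["end"])
        if e <= s:
            raise MalformedInputError(f"{path}: empty/inverted record {s}-{e}")
        if prev_end is not None:
            if s < prev_end:
                raise MalformedInputError(
                    f"{path}: overlapping or unsorted records at {s} (previous end {prev_end})"
                )
            if s > prev_end:
                raise MalformedInputError(
                    f"{path}: coverage gap between {prev_end} and {s}"
                )
        prev_end = e
    start = int(df["start"].iloc[0])
    depths = np.repeat(
        df["depth"].to_numpy(dtype=float),
        (df["end"] - df["start"]).to_numpy(dtype=int),
    )
    if genome_mean is None:
        genome_mean = float(depths.mean())
        log.warning(
            "%s: genome-wide mean not supplied; using window mean %.3g", path, genome_mean
        )
    return DepthProfile(
        chrom=str(chroms[0]), start=start, depths=depths, genome_mean=genome_mean
    )


def write_bedgraph(profile: DepthProfile, path) -> None:
    """Run-length-encode a depth profile back to bedGraph."""
    d = profile.depths
    change = np.flatnonzero(np.diff(d)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [d.size]])
    with open(path, "w", encoding="utf-8") as fh:
        for s, e in zip(starts, ends):
            fh.write(
                f"{profile.chrom}\t{profile.start + s}\t{profile.start + e}\t{d[s]:g}\n"
            )


def write_calls_bed(calls: list[CopyNumberCall], path) -> None:
    """BED of copy-number calls (converted back to 0-based half-open)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# copy-number calls; BED 0-based half-open; name=haploid_cn\n")
        for c in calls:
            fh.write(f"{c.chrom}\t{c.call_start - 1}\t{c.call_end}\tcn{c.haploid_cn}\n")


def read_mosaics_tsv(path) -> list[HaplotypeMosaic]:
    """Read haplotype mosaics: individual, chrom, start, end, founder, phenotype."""
    df = pd.read_csv(path, sep="\t", na_values=[MISSING], comment="#")
    _require_columns(
        df, {"individual", "chrom", "start", "end", "founder", "phenotype"}, path
    )
    mosaics = []
    for (ind, chrom), sub in df.groupby(["individual", "chrom"], sort=False):
        sub = sub.sort_values("start")
        phen = sub["phenotype"].iloc[0]
        qv = None
        if "quantitative_value" in sub.columns and not sub["quantitative_value"].isna().all():
            qv = float(sub["quantitative_value"].iloc[0])
        mosaics.append(
            HaplotypeMosaic(
                individual_id=str(ind),
                chrom=str(chrom),
                segments=tuple(
                    (float(r["start"]), float(r["end"]), str(r["founder"]))
                    for _, r in sub.iterrows()
                ),
                phenotype=str(phen),
                quantitative_value=qv,
            )
        )
    return mosaics


def write_interval_json(interval: CandidateInterval, path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "chrom": interval.chrom,
                "proximal": interval.proximal,
                "distal": interval.distal,
                "coordinate_convention": "1-based inclusive",
                "defining_individuals": list(interval.defining_individuals),
            },
            indent=2,
        )
        + "\n",
        encoding="utf-8",
    )


def packaged_cross_counts() -> list[TransmissionRecord]:
    """The packaged fixture of transmission counts from the 18 published
    F1/CC crosses segregating the WSB/EiJ high-copy chromosome-2 allele."""
    from importlib.resources import files

    path = files("drivekit.data").joinpath("f1_cross_transmission_counts.tsv")
    with path.open("rb") as fh:
        return read_counts_tsv(fh)
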