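"""Readers and writers for the pipeline's tabular formats.

Conventions, stated in every file header: SNP positions are 1-based (VCF
convention); interval columns (start/end) are 0-based half-open (BED
convention).  All tables are plain TSV so that round-trips are bit-exact for
integer fields.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from .methylation import DmrReadSet

_HEADER = (
    "# cffkit table: {kind}\n"
    "# coordinates: positions 1-based; intervals 0-based half-open\n"
)


def _write_tsv(df: pd.DataFrame, path: str | Path, kind: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_HEADER.format(kind=kind))
        df.to_csv(fh, sep="\t", index=False)


def _read_tsv(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty file, no table to parse") from exc
    if len(df) == 0:
        raise ValueError(f"{path}: table has a header but no rows")
    if len(df.columns) <= 1:
        raise ValueError(f"{path}: not a cffkit TSV (expected tab-separated columns)")
    return df


def write_binned_counts(df: pd.DataFrame, path: str | Path) -> None:
    _write_tsv(df[["chrom", "start", "end", "gc", "count"]], path, "binned_counts")


def read_binned_counts(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path)
    missing = {"chrom", "start", "end", "gc", "count"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_tagged_reads(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in ("chrom", "pos", "snp_id", "region", "allele", "tag") if c in df]
    _write_tsv(df[cols], path, "tagged_reads")


def read_tagged_reads(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path)
    missing = {"snp_id", "allele", "tag"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_pileups(df: pd.DataFrame, path: str | Path) -> None:
    _write_tsv(df, path, "snp_pileups")


def read_pileups(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path)
    missing = {"snp_id", "chrom", "r_maj", "r_min", "r_sum"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_dmr_reads(readsets: dict[str, DmrReadSet], path: str | Path) -> None:
    """Flatten DMR read sets to one long TSV of per-position calls."""
    frames = []
    for rs in readsets.values():
        merged = rs.calls.merge(rs.reads, on="read_id")
        merged.insert(0, "dmr_id", rs.dmr_id)
        merged.insert(1, "chrom", rs.chrom)
        merged["cpg_positions"] = ",".join(map(str, rs.cpg_positions))
        frames.append(merged)
    _write_tsv(pd.concat(frames, ignore_index=True), path, "dmr_reads")


def read_dmr_reads(path: str | Path) -> dict[str, DmrReadSet]:
    df = _read_tsv(path)
    out: dict[str, DmrReadSet] = {}
    for dmr_id, grp in df.groupby("dmr_id", sort=False):
        cpg = tuple(int(x) for x in str(grp["cpg_positions"].iloc[0]).split(","))
        reads = grp[["read_id", "mean_quality", "length"]].drop_duplicates(
            "read_id"
        ).reset_index(drop=True)
        calls = grp[["read_id", "pos", "context", "call"]].reset_index(drop=True)
        out[dmr_id] = DmrReadSet(
            dmr_id=str(dmr_id),
            chrom=str(grp["chrom"].iloc[0]),
            cpg_positions=cpg,
            reads=reads,
            calls=calls,
        )
    return out


def write_ground_truth(truth: dict[str, Any], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(truth, fh, sort_keys=True)


def read_ground_truth(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_report(report: dict[str, Any], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)


def read_report(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        return json.load(fh)
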