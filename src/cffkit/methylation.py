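"""Differentially methylated region (DMR) readout from bisulphite reads.

Fetal (placental) cfDNA is hypermethylated at a panel of DMRs where maternal
blood DNA is essentially unmethylated, so the methylated-read fraction at a
DMR reads out the fetal contribution.  This module implements the readout
chain: read filtering by quality and length, bisulphite conversion-rate
estimation from non-CpG cytosines, per-DMR methylation at the first two CpG
positions, and descriptive group summaries.  It deliberately exposes no
aneuploidy-call API: in practice the within-group variance of DMR methylation
is too high for a stable clinical call, and the module's role is to
characterise that behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_MIN_QUALITY = 20.0  # mean phred
DEFAULT_MIN_LENGTH = 100  # bases


@dataclass(frozen=True)
class DmrReadSet:
    """Bisulphite reads mapped to one DMR.

    ``reads`` has one row per read: ``read_id``, ``mean_quality``, ``length``.
    ``calls`` has one row per covered cytosine position per read:
    ``read_id``, ``pos`` (0-based offset within the DMR), ``context``
    (``"cpg"`` or ``"non_cpg"``) and ``call`` (``"C"`` = unconverted, i.e.
    methylated at CpG; ``"T"`` = converted).
    """

    dmr_id: str
    chrom: str
    cpg_positions: tuple[int, ...]
    reads: pd.DataFrame
    calls: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.cpg_positions) < 2:
            raise ValueError(
                f"{self.dmr_id}: a DMR needs >=2 CpG positions, got "
                f"{len(self.cpg_positions)}"
            )
        if list(self.cpg_positions) != sorted(self.cpg_positions):
            raise ValueError(f"{self.dmr_id}: cpg_positions must be sorted")

    @property
    def n_reads(self) -> int:
        return len(self.reads)


@dataclass(frozen=True)
class DmrMethylation:
    """Per-DMR methylation summary at the first two CpG positions."""

    dmr_id: str
    meth_fraction: float
    conversion_rate: float
    n_reads: int


def filter_reads(
    raw: DmrReadSet,
    min_quality: float = DEFAULT_MIN_QUALITY,
    min_length: int = DEFAULT_MIN_LENGTH,
) -> DmrReadSet:
    """Retain reads with mean quality >= Q20 and length >= 100 bp.

    Idempotent; an empty result is allowed.
    """
    keep = (raw.reads["mean_quality"] >= min_quality) & (
        raw.reads["length"] >= min_length
    )
    kept_ids = raw.reads.loc[keep, "read_id"]
    return replace(
        raw,
        reads=raw.reads.loc[keep].reset_index(drop=True),
        calls=raw.calls[raw.calls["read_id"].isin(set(kept_ids))].reset_index(
            drop=True
        ),
    )


def conversion_rate(r: DmrReadSet) -> float:
    """Bisulphite conversion rate: fraction of non-CpG cytosines read as T.

    Cytosines outside CpG context are unmethylated in mammalian DNA, so every
    non-CpG C should convert; the observed T fraction measures conversion
    efficiency.
    """
    non_cpg = r.calls[r.calls["context"] == "non_cpg"]
    if len(non_cpg) == 0:
        raise ValueError(f"{r.dmr_id}: no covered non-CpG cytosine sites")
    return float((non_cpg["call"] == "T").mean())


def dmr_methylation(r: DmrReadSet) -> DmrMethylation:
    """Methylation fraction pooled over the first two CpG positions.

    Calls at CpG1 and CpG2 are pooled (weighting by coverage) and the
    methylated fraction is the proportion of unconverted C calls.
    """
    first_two = set(r.cpg_positions[:2])
    cpg = r.calls[(r.calls["context"] == "cpg") & (r.calls["pos"].isin(first_two))]
    covered = set(cpg["pos"].unique())
    if covered != first_two:
        missing = sorted(first_two - covered)
        raise ValueError(f"{r.dmr_id}: first-two CpG positions uncovered: {missing}")
    meth = float((cpg["call"] == "C").mean())
    return DmrMethylation(
        dmr_id=r.dmr_id,
        meth_fraction=meth,
        conversion_rate=conversion_rate(r),
        n_reads=r.n_reads,
    )


def group_summary(
    levels: dict[str, list[DmrMethylation]],
    compare: tuple[str, str] = ("normal", "t21"),
) -> pd.DataFrame:
    """Per-DMR group means/SDs and a Welch-t comparison between two groups.

    ``levels`` maps group label (e.g. ``non_pregnant``, ``normal``, ``t21``)
    to per-sample :class:`DmrMethylation` values.  The comparison between the
    ``compare`` groups is descriptive: with the tiny per-group sample sizes
    typical for DMR panels the t-test is reported with its p-value but no
    clinical call is derived from it.
    """
    rows: list[dict] = []
    dmr_ids: list[str] = []
    for group_levels in levels.values():
        for m in group_levels:
            if m.dmr_id not in dmr_ids:
                dmr_ids.append(m.dmr_id)
    for dmr_id in dmr_ids:
        row: dict = {"dmr_id": dmr_id}
        by_group: dict[str, np.ndarray] = {}
        for group, group_levels in levels.items():
            vals = np.array(
                [m.meth_fraction for m in group_levels if m.dmr_id == dmr_id]
            )
            by_group[group] = vals
            row[f"{group}_mean"] = float(vals.mean()) if len(vals) else np.nan
            row[f"{group}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else np.nan
            row[f"{group}_n"] = len(vals)
        a, b = (by_group.get(g, np.array([])) for g in compare)
        if len(a) >= 1 and len(b) >= 1:
            row["difference"] = float(b.mean() - a.mean())
            if len(a) >= 2 and len(b) >= 2 and (a.std() > 0 or b.std() > 0):
                t, p = stats.ttest_ind(b, a, equal_var=False)
                row["t_stat"] = float(t)
                row["p_value"] = float(p)
            else:
                row["t_stat"] = np.nan
                row["p_value"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
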