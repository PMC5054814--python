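"""Shared result containers used across the estimation and calling modules."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

#: Chromosome labels for the three viable autosomal trisomies.
TRISOMY_CHROMS = ("chr13", "chr18", "chr21")

#: Autosome labels excluded from fetal-fraction control pools because they are
#: the trisomy targets themselves.
TARGET_CHROMS = set(TRISOMY_CHROMS)

#: Default fetal-fraction QC cutoff: below ~4% the fetal signal is too weak
#: for a reliable negative call and the sample should be flagged.
LOW_FF_CUTOFF = 0.04


@dataclass(frozen=True)
class FFEstimate:
    """A fetal-fraction estimate.

    Parameters
    ----------
    value
        Estimated fetal fraction in [0, 1].
    method
        One of ``"chrY"``, ``"dist_match"``, ``"allelic"``.
    diagnostics
        Method-specific extras (number of SNPs used, fit score, per-SNP
        values, ...).
    """

    value: float
    method: str
    diagnostics: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 1.0:
            raise ValueError(f"fetal fraction must be in [0, 1], got {self.value}")


@dataclass(frozen=True)
class AneuploidyCall:
    """Per-chromosome risk result.

    ``call`` is one of ``"high_risk"``, ``"low_risk"``, ``"no_call"``.  A
    sample whose fetal fraction is below the QC cutoff and whose statistic is
    non-significant is reported ``no_call`` with the ``low_ff`` flag: a weak
    fetal signal cannot support a confident negative.
    """

    chrom: str
    statistic: float
    call: str
    p_value: float | None = None
    qc_flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.call not in ("high_risk", "low_risk", "no_call"):
            raise ValueError(f"unknown call {self.call!r}")
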