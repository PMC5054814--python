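"""Read-count aneuploidy screening from shallow whole-genome sequencing.

The classical NIPT route: bin the genome, correct bin counts for GC bias,
express each chromosome as its share of corrected counts, and compare the
target chromosome's share against a euploid reference panel with a z-score.
A trisomic chromosome's share is inflated by a factor of about (1 + f/2),
where f is the fetal fraction, so sensitivity is gated by f — samples below
the ~4% cutoff cannot support a confident negative call.

Also provides the chromosome-Y fetal-fraction estimator for male-fetus
pregnancies: the sample's chrY share interpolated linearly between a female
background level and an adult-male reference level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .types import LOW_FF_CUTOFF, AneuploidyCall, FFEstimate

DEFAULT_Z_THRESHOLD = 3.0
DEFAULT_MIN_REFERENCE = 20
GC_STRATUM_WIDTH = 0.01  # 1% GC strata


@dataclass(frozen=True)
class ChromRepresentation:
    """Per-chromosome share of GC-corrected counts; shares sum to 1."""

    shares: pd.Series  # indexed by chromosome label
    total_reads: float

    def __post_init__(self) -> None:
        s = float(self.shares.sum())
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"chromosome shares must sum to 1, got {s}")

    def share(self, chrom: str) -> float:
        return float(self.shares.get(chrom, 0.0))


def gc_correct(binned: pd.DataFrame) -> pd.DataFrame:
    """Stratum-mean GC correction of binned counts.

    Bins are grouped into 1% GC strata; each bin's count is rescaled by
    (global mean count per bin) / (mean count of its stratum), which zeroes
    the count-GC trend while preserving the total count.  Idempotent up to
    floating-point tolerance.  Corrected counts are real-valued.
    """
    counts = binned["count"].to_numpy(float)
    if counts.sum() <= 0:
        raise ValueError("all bin counts are zero; nothing to correct")
    strata = np.floor(binned["gc"].to_numpy(float) / GC_STRATUM_WIDTH).astype(int)
    global_mean = counts.mean()
    stratum_mean = pd.Series(counts).groupby(strata).transform("mean").to_numpy()
    out = binned.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        scaled = np.where(stratum_mean > 0, counts * global_mean / stratum_mean, 0.0)
    out["count"] = scaled
    return out


def chromosome_representation(corrected: pd.DataFrame) -> ChromRepresentation:
    """Share of (corrected) counts on each chromosome."""
    per_chrom = corrected.groupby("chrom", sort=False)["count"].sum()
    total = float(per_chrom.sum())
    if total <= 0:
        raise ValueError("zero total count")
    return ChromRepresentation(shares=per_chrom / total, total_reads=total)


def zscore_call(
    sample: ChromRepresentation,
    reference: Sequence[ChromRepresentation],
    chrom: str,
    ff: FFEstimate | None = None,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
    min_reference: int = DEFAULT_MIN_REFERENCE,
    low_ff_cutoff: float = LOW_FF_CUTOFF,
) -> AneuploidyCall:
    """z-score aneuploidy call for one chromosome against a euploid panel.

    z = (sample share - reference mean) / reference SD; high risk at
    z >= ``z_threshold``.  When the fetal fraction is below ``low_ff_cutoff``
    a non-significant result becomes ``no_call`` (flag ``low_ff``): the
    fetal signal is too weak to exclude a trisomy.
    """
    if len(reference) < min_reference:
        raise ValueError(
            f"reference panel too small: {len(reference)} < {min_reference}"
        )
    ref = np.array([r.share(chrom) for r in reference], dtype=float)
    sd = ref.std(ddof=1)
    # guard against effectively-constant panels (float dust included)
    if not np.isfinite(sd) or sd <= max(abs(ref.mean()), 1e-300) * 1e-12:
        raise ValueError("degenerate reference: zero variance in shares")
    z = (sample.share(chrom) - ref.mean()) / sd

    flags: tuple[str, ...] = ()
    if ff is not None and ff.value < low_ff_cutoff:
        flags = ("low_ff",)
    if z >= z_threshold:
        call = "high_risk"
    elif flags:
        call = "no_call"
    else:
        call = "low_risk"
    return AneuploidyCall(chrom=chrom, statistic=float(z), call=call, qc_flags=flags)


def ff_from_chry(
    sample_y_share: float, female_bg: float, male_ref: float
) -> FFEstimate:
    """Fetal fraction from chromosome-Y representation (male fetus).

    Linear interpolation of the sample's chrY share between the female
    background level (mapping noise; fetal fraction 0) and the level a fully
    fetal male sample would show, clamped to [0, 1].
    """
    if female_bg < 0:
        raise ValueError("female background share must be >= 0")
    if male_ref <= female_bg:
        raise ValueError("male reference share must exceed female background")
    value = (sample_y_share - female_bg) / (male_ref - female_bg)
    return FFEstimate(
        value=float(np.clip(value, 0.0, 1.0)),
        method="chrY",
        diagnostics={
            "sample_y_share": float(sample_y_share),
            "female_bg": float(female_bg),
            "male_ref": float(male_ref),
        },
    )
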