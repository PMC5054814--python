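"""Trisomy detection from the per-SNP fetal-fraction distribution shift.

On a trisomic chromosome the fetal contribution is 3/2 of the disomic one
and the fetal allele dosages change, so per-SNP cffDNA concentration values
computed on that chromosome are drawn from a shifted distribution relative
to control autosomes.  The test compares the target chromosome's C values
against the pooled control-autosome values with a two-sided Welch t-test;
p < 0.05 flags high risk.  Chromosomes 13, 18 and 21 are all excluded from
the control pool since each is a potential trisomy target.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import TRISOMY_CHROMS, AneuploidyCall

DEFAULT_ALPHA = 0.05
MIN_TARGET_SNPS = 5
MIN_CONTROL_SNPS = 20
CONTROL_EXCLUDE = set(TRISOMY_CHROMS) | {"chrX", "chrY"}


def per_chrom_ff(per_snp: pd.DataFrame) -> dict[str, np.ndarray]:
    """Group a per-SNP concentration table (chrom, ff columns) by chromosome."""
    return {
        chrom: grp["ff"].to_numpy(float)
        for chrom, grp in per_snp.groupby("chrom", sort=False)
    }


def trisomy_shift_test(
    ff: Mapping[str, Sequence[float]] | pd.DataFrame,
    target: str,
    alpha: float = DEFAULT_ALPHA,
    min_target: int = MIN_TARGET_SNPS,
    min_control: int = MIN_CONTROL_SNPS,
) -> AneuploidyCall:
    """Welch t-test of target-chromosome C values against control autosomes.

    ``ff`` maps chromosome labels to per-SNP C values (a DataFrame with
    ``chrom``/``ff`` columns is also accepted).  Returns high_risk when the
    two-sided p-value is below ``alpha``; with too few SNPs on either side
    the result is ``no_call`` with an ``insufficient_snps`` flag.
    """
    if target not in TRISOMY_CHROMS:
        raise ValueError(f"target must be one of {TRISOMY_CHROMS}, got {target!r}")
    if isinstance(ff, pd.DataFrame):
        ff = per_chrom_ff(ff)
    target_vals = np.asarray(ff.get(target, ()), dtype=float)
    control_vals = np.concatenate(
        [np.asarray(v, float) for c, v in ff.items() if c not in CONTROL_EXCLUDE]
        or [np.array([])]
    )
    if len(target_vals) < min_target or len(control_vals) < min_control:
        return AneuploidyCall(
            chrom=target,
            statistic=float("nan"),
            call="no_call",
            qc_flags=("insufficient_snps",),
        )
    t, p = stats.ttest_ind(target_vals, control_vals, equal_var=False)
    call = "high_risk" if p < alpha else "low_risk"
    return AneuploidyCall(chrom=target, statistic=float(t), p_value=float(p), call=call)
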