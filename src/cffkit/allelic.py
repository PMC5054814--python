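"""Fetal-fraction estimation from SNP allele ratios.

At a SNP where mother and fetus differ, the minor-allele read fraction of
plasma cfDNA deviates from 0 or 1/2 by an amount set by the fetal fraction f:

* mother homozygous, fetus heterozygous: minor fraction f/2, so
  ``C = 2 * R_min / R_sum`` recovers f;
* mother heterozygous, fetus homozygous: fractions (1 +/- f)/2, so
  ``C = (R_maj - R_min) / R_sum`` recovers f.

The branch is chosen by the dividing coefficient ``a = R_min / R_maj``
(maternal-heterozygous at a >= 0.25).  Neither branch needs parental
genotypes.  Because PCR duplicates skew allele ratios, pileups are first
collapsed by random molecular tag (one template per (SNP, tag) pair).

A second, histogram-level estimator needs no per-SNP classification at all:
among high-MAF SNPs the minor-allele fraction clusters at 50% (both
heterozygous) and 50 +/- f/2 x 100% (fetus homozygous), so matching the
observed allele-fraction histogram against a family of two-peak normal
mixtures reads f off the best-scoring peak offset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .types import FFEstimate

DEFAULT_A_THRESHOLD = 0.25
DEFAULT_MIN_DEPTH = 100  # templates per SNP after dedup
DEFAULT_NOISE_RATE = 0.001  # assumed per-read miscall rate for the hom screen
DEFAULT_EXCLUDE = ("chr13", "chr18", "chr21", "chrX", "chrY")

MATERNAL_HET = "maternal_heterozygous"
MATERNAL_HOM = "maternal_homozygous"


@dataclass(frozen=True)
class SnpPileup:
    """Major/minor allele read (or template) counts at one SNP."""

    chrom: str
    pos: int
    r_maj: int
    r_min: int

    def __post_init__(self) -> None:
        if not self.r_maj >= self.r_min >= 0:
            raise ValueError(
                f"require R_maj >= R_min >= 0, got {self.r_maj}, {self.r_min}"
            )

    @property
    def r_sum(self) -> int:
        return self.r_maj + self.r_min


@dataclass(frozen=True)
class SnpClass:
    """Maternal genotype class of a SNP with its dividing coefficient."""

    label: str
    a: float


@dataclass(frozen=True)
class AfDistribution:
    """Per-SNP alt-allele fractions with the high-MAF analysis window."""

    values: np.ndarray
    window: tuple[float, float] = (0.35, 0.65)
    bin_width: float = 0.01

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if np.any((v < 0) | (v > 1)):
            raise ValueError("allele fractions must lie in [0, 1]")
        object.__setattr__(self, "values", v)


# --------------------------------------------------------------------------
# tag-based deduplication
# --------------------------------------------------------------------------


def dedup_by_tag(tagged_reads: pd.DataFrame) -> pd.DataFrame:
    """Collapse PCR duplicates: reads sharing (snp_id, tag) become one template.

    The collapsed template's allele is the majority allele among its
    duplicates; ties resolve to the allele of the first read in input order.
    Returns a per-SNP pileup table with template counts: snp_id, chrom, pos,
    n_a, n_b (counts of the lexicographically first/last allele label),
    r_maj, r_min, r_sum, alt_fraction, n_templates.

    Distinct templates that happen to share a tag at the same SNP are merged
    — the quantifiable cost of a finite tag space.
    """
    for col in ("snp_id", "allele", "tag"):
        if col not in tagged_reads.columns:
            raise ValueError(f"tagged read table lacks required column {col!r}")
    n = len(tagged_reads)
    if n == 0:
        raise ValueError("empty read table")

    snp_codes, snp_ids = pd.factorize(tagged_reads["snp_id"], sort=False)
    allele_codes, alleles = pd.factorize(tagged_reads["allele"], sort=False)
    tags = tagged_reads["tag"].to_numpy()
    if tags.dtype.kind not in "iu":
        tags = pd.factorize(tags)[0]
    n_alleles = len(alleles)

    # group reads by (snp, tag), stable in input order
    order = np.lexsort((np.arange(n), tags, snp_codes))
    s, t, a = snp_codes[order], tags[order], allele_codes[order]
    new_group = np.r_[True, (s[1:] != s[:-1]) | (t[1:] != t[:-1])]
    gid = np.cumsum(new_group) - 1
    group_snp = s[new_group]

    # majority allele per group, tie -> earliest input position
    key = gid.astype(np.int64) * n_alleles + a
    order2 = np.argsort(key, kind="stable")
    k2 = key[order2]
    pos2 = order[order2]  # original input positions
    starts = np.r_[True, k2[1:] != k2[:-1]]
    idx = np.flatnonzero(starts)
    counts = np.diff(np.r_[idx, len(k2)])
    first_pos = pos2[idx]
    grp = k2[idx] // n_alleles
    alle = (k2[idx] % n_alleles).astype(int)
    pick = np.lexsort((first_pos, -counts, grp))
    keep = np.r_[True, grp[pick][1:] != grp[pick][:-1]]
    template_allele = alle[pick][keep]  # one row per (snp, tag) group

    tpl_counts = np.bincount(
        group_snp * n_alleles + template_allele, minlength=len(snp_ids) * n_alleles
    ).reshape(len(snp_ids), n_alleles)
    return _pileup_table(tagged_reads, snp_ids, list(alleles), tpl_counts)


def tally_reads(tagged_reads: pd.DataFrame) -> pd.DataFrame:
    """Per-SNP pileup of raw read counts, ignoring molecular tags."""
    if len(tagged_reads) == 0:
        raise ValueError("empty read table")
    snp_codes, snp_ids = pd.factorize(tagged_reads["snp_id"], sort=False)
    allele_codes, alleles = pd.factorize(tagged_reads["allele"], sort=False)
    n_alleles = len(alleles)
    counts = np.bincount(
        snp_codes * n_alleles + allele_codes, minlength=len(snp_ids) * n_alleles
    ).reshape(len(snp_ids), n_alleles)
    return _pileup_table(tagged_reads, snp_ids, list(alleles), counts)


def _pileup_table(
    reads: pd.DataFrame, snp_ids: pd.Index, alleles: list, counts: np.ndarray
) -> pd.DataFrame:
    """Assemble the wide pileup table from a (snp x allele) count matrix."""
    meta_cols = [c for c in ("chrom", "pos", "region") if c in reads.columns]
    meta = (
        reads.drop_duplicates("snp_id").set_index("snp_id")[meta_cols]
        if meta_cols
        else pd.DataFrame(index=snp_ids)
    )
    # order allele columns lexicographically: first = reference-like ("A")
    col_order = np.argsort(np.asarray(alleles, dtype=object).astype(str))
    counts = counts[:, col_order]
    sorted_counts = np.sort(counts, axis=1)[:, ::-1]
    out = pd.DataFrame({"snp_id": snp_ids})
    for c in meta_cols:
        out[c] = meta.loc[snp_ids, c].to_numpy()
    out["n_a"] = counts[:, 0]
    out["n_b"] = counts[:, -1] if counts.shape[1] > 1 else 0
    out["r_maj"] = sorted_counts[:, 0]
    out["r_min"] = sorted_counts[:, 1] if counts.shape[1] > 1 else 0
    out["r_sum"] = out["r_maj"] + out["r_min"]
    with np.errstate(invalid="ignore", divide="ignore"):
        out["alt_fraction"] = np.where(
            out["r_sum"] > 0, out["n_b"] / counts.sum(axis=1), np.nan
        )
    out["n_templates"] = counts.sum(axis=1)
    return out


# --------------------------------------------------------------------------
# per-SNP estimator
# --------------------------------------------------------------------------


def classify_snp(p: SnpPileup, a_threshold: float = DEFAULT_A_THRESHOLD) -> SnpClass:
    """Classify a SNP by its dividing coefficient a = R_min / R_maj.

    ``a >= a_threshold`` (default 0.25) reads as maternal-heterozygous —
    neither allele dominates; below it the prevalent allele is taken as a
    maternal homozygote with a minor fetal allele.  The boundary value is
    assigned to the heterozygous class for determinism.
    """
    if p.r_maj == 0:
        raise ValueError("uninformative site: R_maj = 0")
    a = p.r_min / p.r_maj
    label = MATERNAL_HET if a >= a_threshold else MATERNAL_HOM
    return SnpClass(label=label, a=a)


def snp_ff(p: SnpPileup, c: SnpClass | None = None) -> float:
    """Per-SNP cffDNA concentration.

    Maternal-heterozygous: C = (R_maj - R_min) / R_sum (the allele-balance
    displacement); maternal-homozygous: C = 2 * R_min / R_sum (twice the
    minor-allele fraction).  Both equal f exactly for their intended
    genotype configurations at infinite depth.
    """
    if p.r_sum == 0:
        raise ValueError("R_sum = 0")
    if c is None:
        c = classify_snp(p)
    if c.label == MATERNAL_HET:
        return (p.r_maj - p.r_min) / p.r_sum
    return min(2 * p.r_min / p.r_sum, 1.0)


def per_snp_ff(
    pileups: pd.DataFrame,
    a_threshold: float = DEFAULT_A_THRESHOLD,
    noise_rate: float = DEFAULT_NOISE_RATE,
    informative_z: float = 3.0,
) -> pd.DataFrame:
    """Vectorised per-SNP concentration table.

    Adds columns ``a``, ``label``, ``ff`` and an ``informative`` screen:
    heterozygous sites must deviate from 50:50 by more than ``informative_z``
    binomial SDs, homozygous sites' minor count must exceed the sequencing
    error floor by the same margin.  Sites failing the screen are genotype
    configurations carrying no maternal-fetal allelic difference (both
    heterozygous, or both homozygous) whose C values cluster near zero.
    """
    df = pileups.copy()
    r_maj = df["r_maj"].to_numpy(float)
    r_min = df["r_min"].to_numpy(float)
    r_sum = df["r_sum"].to_numpy(float)
    if np.any(r_sum <= 0):
        raise ValueError("pileup with R_sum = 0")
    a = r_min / np.maximum(r_maj, 1)
    het = a >= a_threshold
    ff = np.where(
        het, (r_maj - r_min) / r_sum, np.minimum(2 * r_min / r_sum, 1.0)
    )
    # informativeness screen
    het_ok = (r_maj - r_min) > informative_z * np.sqrt(r_sum)
    floor = noise_rate * r_sum
    hom_ok = (r_min - floor) > informative_z * np.sqrt(
        np.maximum(floor * (1 - noise_rate), 1.0)
    )
    df["a"] = a
    df["label"] = np.where(het, MATERNAL_HET, MATERNAL_HOM)
    df["ff"] = ff
    df["informative"] = np.where(het, het_ok, hom_ok)
    return df


def sample_ff_allelic(
    pileups: pd.DataFrame,
    exclude_chroms: Iterable[str] = DEFAULT_EXCLUDE,
    min_depth: int = DEFAULT_MIN_DEPTH,
    a_threshold: float = DEFAULT_A_THRESHOLD,
    informative_only: bool = True,
    noise_rate: float = DEFAULT_NOISE_RATE,
) -> FFEstimate:
    """Sample-level fetal fraction: mean per-SNP C over control autosomes.

    SNPs on the trisomy-target autosomes (13/18/21) and sex chromosomes are
    excluded so a fetal aneuploidy cannot distort the estimate; sites below
    ``min_depth`` templates are dropped.  By default only sites passing the
    informativeness screen enter the mean (see :func:`per_snp_ff`);
    ``informative_only=False`` averages every retained site, which biases
    the estimate low by a factor set by the fraction of SNPs at which mother
    and fetus actually differ.
    """
    exclude = set(exclude_chroms)
    df = pileups[~pileups["chrom"].isin(exclude)]
    df = df[df["r_sum"] >= min_depth]
    if len(df) == 0:
        raise ValueError("no qualifying SNPs on control autosomes")
    df = per_snp_ff(df, a_threshold=a_threshold, noise_rate=noise_rate)
    used = df[df["informative"]] if informative_only else df
    if len(used) == 0:
        raise ValueError("no informative SNPs after screening")
    value = float(np.clip(used["ff"].mean(), 0.0, 1.0))
    return FFEstimate(
        value=value,
        method="allelic",
        diagnostics={
            "n_snps": int(len(used)),
            "n_candidates": int(len(df)),
            "per_snp": df,
        },
    )


# --------------------------------------------------------------------------
# allele-frequency distribution matching
# --------------------------------------------------------------------------


def ff_distribution_match(
    d: AfDistribution | np.ndarray,
    depth: float,
    x_range: tuple[int, int] = (1, 25),
    sd_floor: float = 0.5,
    min_snps: int = 10,
) -> FFEstimate:
    """Fetal fraction from the shape of the allele-fraction histogram.

    The observed alt-allele fractions inside the 35-65% window are binned at
    1 percentage point and compared (Pearson correlation of bin masses)
    against a candidate family: a single normal peak at 50% (f = 0) and, for
    each x in ``x_range``, an equal-weight three-peak mixture at 50% and
    50 +/- x/2 %.  Peak SD is the binomial sampling SD at the given per-SNP
    depth (in percentage points, floored at ``sd_floor``).  The best-scoring
    x is the fetal-fraction percentage.  Fractions outside the window — the
    noisy near-0%/100% peaks — never enter the histogram.
    """
    if not isinstance(d, AfDistribution):
        d = AfDistribution(values=np.asarray(d, dtype=float))
    if depth <= 0:
        raise ValueError("depth must be positive")
    lo, hi = d.window
    vals = d.values[(d.values >= lo) & (d.values <= hi)] * 100.0
    if len(vals) < min_snps:
        raise ValueError(
            f"only {len(vals)} SNPs inside the [{lo:.0%}, {hi:.0%}] window "
            f"(need >= {min_snps})"
        )
    edges = np.arange(lo * 100, hi * 100 + 1e-9, d.bin_width * 100)
    observed, _ = np.histogram(vals, bins=edges)

    sd = max(sd_floor, 100.0 * np.sqrt(0.25 / depth))

    def candidate(peaks: list[float]) -> np.ndarray:
        mass = np.zeros(len(edges) - 1)
        for mu in peaks:
            cdf = stats.norm.cdf(edges, loc=mu, scale=sd)
            mass += np.diff(cdf)
        return mass / len(peaks)

    xs = [0] + list(range(x_range[0], x_range[1] + 1))
    scores = np.full(len(xs), -np.inf)
    for i, x in enumerate(xs):
        peaks = [50.0] if x == 0 else [50.0, 50.0 - x / 2.0, 50.0 + x / 2.0]
        cand = candidate(peaks)
        if observed.std() > 0 and cand.std() > 0:
            scores[i] = np.corrcoef(observed, cand)[0, 1]
    best = int(np.argmax(scores))
    x_best = xs[best]
    return FFEstimate(
        value=x_best / 100.0,
        method="dist_match",
        diagnostics={
            "x": x_best,
            "score": float(scores[best]),
            "n_snps": int(len(vals)),
            "scores": dict(zip(xs, scores.tolist())),
            "sd": sd,
        },
    )
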