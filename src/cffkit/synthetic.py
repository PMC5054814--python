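"""Synthetic maternal+fetal cfDNA mixture generator.

Plasma of a pregnant woman carries a mixture of maternal cfDNA and a fetal
(placental) component whose proportion — the fetal fraction f, typically
10-20% — gates every noninvasive prenatal test.  This module simulates that
mixture at every level the analysis pipeline consumes, with known ground
truth:

* genome-wide binned read counts (multinomial sampling with optional
  GC-dependent bias, a (1 + f/2) count excess on a trisomic chromosome, and a
  chrY contribution of f/2 of the chrY genome share for a male fetus);
* SNP pileups over a high-MAF amplicon panel (Hardy-Weinberg maternal
  genotypes, fetal genotype = one transmitted maternal allele + one
  population allele, binomial template sampling, PCR duplication with random
  molecular tags, optional allele-skewed amplification, per-read sequencing
  error);
* bisulphite read sets over a DMR panel (maternal/fetal methylation mixture
  with incomplete conversion).

Everything is reproducible from :class:`MixtureSpec.seed`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .methylation import DmrReadSet
from .types import TRISOMY_CHROMS

# --------------------------------------------------------------------------
# genome model
# --------------------------------------------------------------------------

#: Approximate human chromosome lengths (bases), used to size the abstract
#: bin table.  Exact coordinates are irrelevant: bins are exchangeable units.
CHROM_LENGTHS: dict[str, int] = {
    "chr1": 249_000_000, "chr2": 243_000_000, "chr3": 198_000_000,
    "chr4": 191_000_000, "chr5": 181_000_000, "chr6": 171_000_000,
    "chr7": 159_000_000, "chr8": 146_000_000, "chr9": 141_000_000,
    "chr10": 136_000_000, "chr11": 135_000_000, "chr12": 134_000_000,
    "chr13": 115_000_000, "chr14": 107_000_000, "chr15": 103_000_000,
    "chr16": 90_000_000, "chr17": 81_000_000, "chr18": 78_000_000,
    "chr19": 59_000_000, "chr20": 63_000_000, "chr21": 48_000_000,
    "chr22": 51_000_000, "chrX": 155_000_000, "chrY": 59_000_000,
}

AUTOSOMES: tuple[str, ...] = tuple(f"chr{i}" for i in range(1, 23))

DEFAULT_BIN_SIZE = 50_000  # standard shallow-WGS NIPT bin width


@dataclass(frozen=True)
class MixtureSpec:
    """Ground-truth description of one simulated plasma sample."""

    fetal_fraction: float
    fetal_sex: str = "female"
    trisomy_chrom: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fetal_fraction <= 1.0:
            raise ValueError(
                f"fetal_fraction must be in [0, 1], got {self.fetal_fraction}"
            )
        if self.fetal_sex not in ("male", "female"):
            raise ValueError(f"fetal_sex must be male or female, got {self.fetal_sex}")
        if self.trisomy_chrom is not None and self.trisomy_chrom not in TRISOMY_CHROMS:
            raise ValueError(
                f"trisomy_chrom must be one of {TRISOMY_CHROMS} or None, "
                f"got {self.trisomy_chrom!r}"
            )

    def fetal_copies(self, chrom: str) -> int:
        """Fetal copy number of ``chrom`` (2, 3 for the trisomic one, sex chroms)."""
        if chrom == self.trisomy_chrom:
            return 3
        if chrom == "chrY":
            return 1 if self.fetal_sex == "male" else 0
        if chrom == "chrX":
            return 1 if self.fetal_sex == "male" else 2
        return 2

    @staticmethod
    def maternal_copies(chrom: str) -> int:
        if chrom == "chrY":
            return 0
        return 2

    def dosage_weight(self, chrom: str) -> float:
        """Relative cfDNA mass of ``chrom`` per haploid-genome unit.

        A disomic autosome in a euploid mixture has weight 1.  A trisomic
        chromosome has weight (1-f) + f*(3/2) = 1 + f/2 — the coverage excess
        the read-count method detects.
        """
        f = self.fetal_fraction
        return (1 - f) * self.maternal_copies(chrom) / 2 + f * self.fetal_copies(
            chrom
        ) / 2


@dataclass(frozen=True)
class GcBiasModel:
    """Relative sampling weight as a function of bin GC fraction.

    ``curve`` maps an array of GC fractions in [0, 1] to positive weights.
    ``None`` is the identity model (no bias).
    """

    curve: Callable[[np.ndarray], np.ndarray] | None = None

    @classmethod
    def identity(cls) -> "GcBiasModel":
        return cls(curve=None)

    @classmethod
    def linear(cls, low: float = 1.0, high: float = 2.0) -> "GcBiasModel":
        """Linear ramp: weight ``low`` at GC=0 rising to ``high`` at GC=1."""
        return cls(curve=lambda gc: low + (high - low) * np.asarray(gc, float))

    def weights(self, gc: np.ndarray) -> np.ndarray:
        gc = np.asarray(gc, dtype=float)
        if self.curve is None:
            return np.ones_like(gc)
        w = np.asarray(self.curve(gc), dtype=float)
        if np.any(w <= 0):
            raise ValueError("GC bias weights must be strictly positive")
        return w


@dataclass(frozen=True)
class PcrModel:
    """PCR amplification model for the SNP-panel simulator.

    duplication_rate
        Mean number of extra copies per template molecule (>= 0); each
        template yields ``1 + Poisson(rate)`` reads.
    amplification_bias
        Optional multiplicative boost of the duplication rate for one
        (randomly favoured) allele in a random subset of panel regions —
        the uneven amplification that corrupts raw allele ratios and that
        molecular-tag deduplication removes.
    bias_region_frac
        Fraction of regions affected when ``amplification_bias`` is set.
    tag_length
        Length of the random molecular tag; tags are drawn uniformly from
        ``4**tag_length``, so collisions (two templates merged at dedup)
        become rarer as the tag grows.
    unique_tags
        Force per-SNP tag uniqueness (collision-free ground truth).
    """

    duplication_rate: float = 1.5
    amplification_bias: float | None = None
    bias_region_frac: float = 0.25
    tag_length: int = 12
    unique_tags: bool = False

    def __post_init__(self) -> None:
        if self.duplication_rate < 0:
            raise ValueError("duplication_rate must be >= 0")
        if self.amplification_bias is not None and self.amplification_bias < 1.0:
            raise ValueError("amplification_bias must be >= 1")
        if self.tag_length < 1:
            raise ValueError("tag_length must be >= 1")

    @property
    def tag_space(self) -> int:
        return 4**self.tag_length


def default_genome_model(bin_size: int = DEFAULT_BIN_SIZE) -> pd.DataFrame:
    """Bin table (chrom, start, end, gc) covering the abstract genome.

    GC content follows a smooth deterministic profile spanning roughly
    0.30-0.60 so that GC-bias injection and correction have ~25 one-percent
    strata to work with.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    frames = []
    offset = 0
    for chrom, length in CHROM_LENGTHS.items():
        n = length // bin_size
        idx = offset + np.arange(n)
        starts = np.arange(n, dtype=np.int64) * bin_size
        gc = 0.45 + 0.10 * np.sin(idx / 97.0) + 0.05 * np.sin(idx / 13.7)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": starts + bin_size,
                    "gc": np.clip(gc, 0.30, 0.60).round(4),
                }
            )
        )
        offset += n
    return pd.concat(frames, ignore_index=True)


def simulate_binned_counts(
    spec: MixtureSpec,
    gc: GcBiasModel | None = None,
    total_reads: int = 5_000_000,
    genome_model: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Multinomial binned read counts for one plasma sample.

    Each bin's sampling weight is (dosage weight of its chromosome) x
    (GC bias weight); counts are one multinomial draw of ``total_reads``
    over bins, so the output total is exactly ``total_reads``.
    """
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    if genome_model is None:
        genome_model = default_genome_model()
    if len(genome_model) == 0:
        raise ValueError("genome model has zero bins")
    gc = gc or GcBiasModel.identity()

    out = genome_model.copy()
    dosage = out["chrom"].map(lambda c: spec.dosage_weight(c)).to_numpy(float)
    w = dosage * gc.weights(out["gc"].to_numpy())
    total_w = w.sum()
    if total_w <= 0:
        raise ValueError("all sampling weights are zero")
    rng = np.random.default_rng(spec.seed)
    out["count"] = rng.multinomial(total_reads, w / total_w)
    return out


# --------------------------------------------------------------------------
# SNP panel and pileups
# --------------------------------------------------------------------------


def snp_panel(
    n_snps: int = 220,
    n_regions: int = 36,
    maf_range: tuple[float, float] = (0.3, 0.5),
    chroms: Sequence[str] | None = None,
    seed: int = 0,
    region_offset: int = 0,
) -> pd.DataFrame:
    """Abstract high-MAF amplicon panel: ``n_regions`` short regions holding
    ``n_snps`` SNPs in total, MAF drawn uniformly from ``maf_range``.

    ``chroms`` assigns regions to chromosomes (cycled); the default spreads
    regions over all 22 autosomes.  Returns columns snp_id, region, chrom,
    pos, maf.  Allele "A" denotes the population major allele, "B" the minor.
    """
    if n_snps <= 0 or n_regions <= 0:
        raise ValueError("panel must have >=1 SNP and >=1 region")
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("MAF range must lie in (0, 0.5]")
    if chroms is None:
        chroms = AUTOSOMES
    rng = np.random.default_rng(seed)
    per_region = np.full(n_regions, n_snps // n_regions)
    per_region[: n_snps % n_regions] += 1
    rows = []
    snp_i = 0
    for r in range(n_regions):
        chrom = chroms[r % len(chroms)]
        region_id = f"region{region_offset + r:03d}"
        base = 1_000_000 + (region_offset + r) * 10_000  # disjoint 200bp spans
        positions = np.sort(rng.choice(np.arange(200), per_region[r], replace=False))
        for p in positions:
            rows.append(
                {
                    "snp_id": f"snp{region_offset * 100 + snp_i:04d}",
                    "region": region_id,
                    "chrom": chrom,
                    "pos": int(base + p) + 1,  # 1-based
                    "maf": float(rng.uniform(lo, hi)),
                }
            )
            snp_i += 1
    return pd.DataFrame(rows)


def shift_panel(
    n_target: int = 40,
    n_control: int = 180,
    target_chrom: str = "chr21",
    seed: int = 0,
) -> pd.DataFrame:
    """Panel split between a trisomy-target chromosome and control autosomes.

    Control regions avoid chr13/18/21 so the control pool of the shift test
    is untouched by any simulated trisomy.
    """
    control_chroms = [
        c for c in AUTOSOMES if c not in ("chr13", "chr18", "chr21")
    ]
    target = snp_panel(
        n_snps=n_target,
        n_regions=max(1, round(36 * n_target / (n_target + n_control))),
        chroms=[target_chrom],
        seed=seed,
    )
    control = snp_panel(
        n_snps=n_control,
        n_regions=max(1, 36 - target["region"].nunique()),
        chroms=control_chroms,
        seed=seed + 1,
        region_offset=target["region"].nunique(),
    )
    return pd.concat([target, control], ignore_index=True)


def _simulate_genotypes(
    spec: MixtureSpec, panel: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Maternal and fetal genotypes for every panel SNP.

    Maternal genotypes are Hardy-Weinberg draws from the population MAF.
    The fetus inherits one maternal allele (uniformly) plus one population
    allele; on a trisomic chromosome a third copy duplicates one of the two
    parental-origin copies, chosen uniformly.  Dosages count the "B"
    (population-minor) allele.
    """
    q = panel["maf"].to_numpy(float)
    n = len(panel)
    mat = rng.binomial(2, q)  # maternal B dosage in {0,1,2}
    transmitted = rng.random(n) < mat / 2.0  # B transmitted?
    paternal = rng.random(n) < q
    fet = transmitted.astype(int) + paternal.astype(int)
    copies = np.full(n, 2)
    if spec.trisomy_chrom is not None:
        tri = (panel["chrom"] == spec.trisomy_chrom).to_numpy()
        extra_is_b = rng.random(n) < fet / 2.0  # duplicate of a uniform copy
        fet = np.where(tri, fet + extra_is_b.astype(int), fet)
        copies = np.where(tri, 3, copies)
    out = panel.copy()
    out["mat_dosage"] = mat
    out["fet_dosage"] = fet
    out["fet_copies"] = copies
    return out


def _mixture_minor_fraction(spec: MixtureSpec, geno: pd.DataFrame) -> np.ndarray:
    """Expected B-allele fraction among cfDNA templates at each SNP."""
    f = spec.fetal_fraction
    m = geno["mat_dosage"].to_numpy(float)
    d = geno["fet_dosage"].to_numpy(float)
    c = geno["fet_copies"].to_numpy(float)
    return ((1 - f) * m / 2 + f * d / 2) / ((1 - f) + f * c / 2)


def simulate_snp_templates(
    spec: MixtureSpec,
    panel: pd.DataFrame,
    mean_templates: float,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Pre-amplification template molecules per SNP.

    Template count per SNP is Poisson(``mean_templates``); B-allele templates
    are binomial at the mixture allele fraction.  Adds columns mat_dosage,
    fet_dosage, fet_copies, p_b, n_templates, b_templates, a_templates.
    """
    if len(panel) == 0:
        raise ValueError("empty SNP panel")
    if mean_templates <= 0:
        raise ValueError("mean_templates must be positive")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    geno = _simulate_genotypes(spec, panel, rng)
    p_b = _mixture_minor_fraction(spec, geno)
    n = rng.poisson(mean_templates, len(geno))
    b = rng.binomial(n, p_b)
    geno["p_b"] = p_b
    geno["n_templates"] = n
    geno["b_templates"] = b
    geno["a_templates"] = n - b
    return geno


@dataclass(frozen=True)
class SnpSim:
    """Tagged-read simulation output: reads, pre-PCR templates, ground truth."""

    reads: pd.DataFrame  # chrom, pos, snp_id, region, allele, tag
    templates: pd.DataFrame  # per-SNP genotypes and template allele counts
    spec: MixtureSpec
    pcr: PcrModel
    error_rate: float


def _draw_tags(
    rng: np.random.Generator, counts: np.ndarray, pcr: PcrModel
) -> np.ndarray:
    """Molecular tags per template, drawn per SNP from ``4**tag_length``."""
    total = int(counts.sum())
    tags = rng.integers(0, pcr.tag_space, total, dtype=np.int64)
    if pcr.unique_tags:
        # resolve per-SNP collisions by redrawing the colliding entries
        snp_of = np.repeat(np.arange(len(counts)), counts)
        key = snp_of * np.int64(pcr.tag_space) + tags
        while True:
            _, first = np.unique(key, return_index=True)
            dup = np.ones(total, dtype=bool)
            dup[first] = False
            if not dup.any():
                break
            tags[dup] = rng.integers(0, pcr.tag_space, int(dup.sum()), dtype=np.int64)
            key = snp_of * np.int64(pcr.tag_space) + tags
    return tags


def simulate_snp_pileups(
    spec: MixtureSpec,
    panel: pd.DataFrame | None = None,
    depth: float = 5000.0,
    error_rate: float = 0.001,
    pcr: PcrModel | None = None,
) -> SnpSim:
    """Tagged sequencing reads over a SNP panel, plus ground truth.

    ``depth`` is the mean number of *reads* per SNP; the mean template count
    is ``depth / (1 + duplication_rate)`` so that amplification restores the
    requested read depth.  Each template receives a random molecular tag and
    ``1 + Poisson(rate)`` read copies, where the rate is allele-boosted in
    amplification-biased regions; each read's allele then flips with
    ``error_rate``.
    """
    if panel is None:
        panel = snp_panel()
    if len(panel) == 0:
        raise ValueError("empty SNP panel")
    if depth <= 0:
        raise ValueError("depth must be positive")
    if not 0.0 <= error_rate < 0.5:
        raise ValueError("error_rate must be in [0, 0.5)")
    pcr = pcr or PcrModel()

    rng = np.random.default_rng(spec.seed)
    mean_templates = depth / (1.0 + pcr.duplication_rate)
    templates = simulate_snp_templates(spec, panel, mean_templates, rng)

    n_tpl = templates["n_templates"].to_numpy()
    snp_idx = np.repeat(np.arange(len(templates)), n_tpl)
    # allele per template: first b_templates are B within each SNP block
    within = np.arange(len(snp_idx)) - np.repeat(
        np.concatenate(([0], np.cumsum(n_tpl)[:-1])), n_tpl
    )
    is_b = within < templates["b_templates"].to_numpy()[snp_idx]
    tags = _draw_tags(rng, n_tpl, pcr)

    # amplification: per-template duplication rate, optionally allele-skewed
    rate = np.full(len(snp_idx), pcr.duplication_rate)
    if pcr.amplification_bias is not None and pcr.duplication_rate > 0:
        regions = pd.Index(panel["region"].unique())
        biased = rng.random(len(regions)) < pcr.bias_region_frac
        favored_b = rng.random(len(regions)) < 0.5
        region_code = regions.get_indexer(templates["region"])[snp_idx]
        boost = biased[region_code] & (favored_b[region_code] == is_b)
        rate = np.where(boost, rate * pcr.amplification_bias, rate)
    copies = 1 + rng.poisson(rate)

    read_snp = np.repeat(snp_idx, copies)
    read_b = np.repeat(is_b, copies)
    read_tag = np.repeat(tags, copies)
    if error_rate > 0:
        flip = rng.random(len(read_snp)) < error_rate
        read_b = read_b ^ flip

    reads = pd.DataFrame(
        {
            "chrom": templates["chrom"].to_numpy()[read_snp],
            "pos": templates["pos"].to_numpy()[read_snp],
            "snp_id": templates["snp_id"].to_numpy()[read_snp],
            "region": templates["region"].to_numpy()[read_snp],
            "allele": np.where(read_b, "B", "A"),
            "tag": read_tag,
        }
    )
    return SnpSim(
        reads=reads, templates=templates, spec=spec, pcr=pcr, error_rate=error_rate
    )


def simulate_template_pileups(
    spec: MixtureSpec,
    panel: pd.DataFrame | None = None,
    depth: float = 5000.0,
    error_rate: float = 0.001,
) -> pd.DataFrame:
    """Template-level pileups, bypassing PCR amplification and tagging.

    Equivalent to running :func:`simulate_snp_pileups` with collision-free
    tags followed by exact deduplication (sequencing error applied per
    template instead of per read, so dedup's majority-vote error suppression
    is not modelled).  Returns a pileup table ready for the allelic module:
    snp_id, region, chrom, pos, n_a, n_b, r_maj, r_min, r_sum, alt_fraction.
    """
    if panel is None:
        panel = snp_panel()
    if not 0.0 <= error_rate < 0.5:
        raise ValueError("error_rate must be in [0, 0.5)")
    rng = np.random.default_rng(spec.seed)
    t = simulate_snp_templates(spec, panel, depth, rng)
    n = t["n_templates"].to_numpy()
    b = t["b_templates"].to_numpy()
    if error_rate > 0:
        b = rng.binomial(b, 1 - error_rate) + rng.binomial(n - b, error_rate)
    a = n - b
    out = t[["snp_id", "region", "chrom", "pos"]].copy()
    out["n_a"] = a
    out["n_b"] = b
    out["r_maj"] = np.maximum(a, b)
    out["r_min"] = np.minimum(a, b)
    out["r_sum"] = n
    with np.errstate(invalid="ignore"):
        out["alt_fraction"] = np.where(n > 0, b / np.maximum(n, 1), np.nan)
    return out


# --------------------------------------------------------------------------
# bisulphite DMR reads
# --------------------------------------------------------------------------


def default_dmr_panel() -> pd.DataFrame:
    """Synthetic 16-DMR panel: 12 DMRs on chr21 plus 4 control autosomal DMRs.

    Coordinates are synthetic placeholders (real DMR panels carry curated
    coordinates); each DMR has 8 CpG positions and 20 non-CpG cytosines.
    Columns: dmr_id, chrom, start, end, cpg_offsets, noncpg_offsets
    (offsets are 0-based within the DMR).
    """
    rows = []
    control_chroms = ["chr2", "chr5", "chr11", "chr17"]
    for i in range(16):
        chrom = "chr21" if i < 12 else control_chroms[i - 12]
        start = 5_000_000 + i * 100_000
        cpg = tuple(range(10, 10 + 8 * 12, 12))
        noncpg = tuple(range(5, 5 + 20 * 9, 9))
        rows.append(
            {
                "dmr_id": f"DMR{i + 1}",
                "chrom": chrom,
                "start": start,
                "end": start + 250,
                "cpg_offsets": cpg,
                "noncpg_offsets": tuple(p for p in noncpg if p not in cpg),
            }
        )
    return pd.DataFrame(rows)


def simulate_bisulfite_reads(
    dmr_panel: pd.DataFrame | None = None,
    spec: MixtureSpec = MixtureSpec(0.15),
    maternal_meth: float | dict[str, float] = 0.05,
    fetal_meth: float | dict[str, float] = 0.95,
    conversion_rate: float = 0.99,
    n_reads: int = 2000,
    quality_mean: float = 30.0,
    length_mean: float = 150.0,
) -> dict[str, DmrReadSet]:
    """Bisulphite read sets over a DMR panel for one mixture sample.

    Each read originates from the fetus with probability equal to the fetal
    dosage share of the DMR's chromosome (f scaled by 3/2 on a trisomic
    chromosome); CpG methylation is Bernoulli per origin; unmethylated and
    non-CpG cytosines convert to T with ``conversion_rate``.  Reads span the
    whole DMR.  Quality and length are drawn around ``quality_mean`` /
    ``length_mean`` so the Q20/100bp filter can be exercised.
    """
    if dmr_panel is None:
        dmr_panel = default_dmr_panel()
    for p in (conversion_rate,):
        if not 0.0 <= p <= 1.0:
            raise ValueError("probabilities must be in [0, 1]")
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")

    def _meth(table: float | dict[str, float], dmr_id: str) -> float:
        v = table[dmr_id] if isinstance(table, dict) else float(table)
        if not 0.0 <= v <= 1.0:
            raise ValueError("methylation probabilities must be in [0, 1]")
        return v

    rng = np.random.default_rng(spec.seed)
    f = spec.fetal_fraction
    out: dict[str, DmrReadSet] = {}
    for row in dmr_panel.itertuples(index=False):
        cpg = tuple(row.cpg_offsets)
        if len(cpg) < 2:
            raise ValueError(f"{row.dmr_id}: a DMR needs >=2 CpG positions")
        noncpg = tuple(row.noncpg_offsets)
        # fetal dosage share of this chromosome's cfDNA
        c = spec.fetal_copies(row.chrom)
        denom = (1 - f) + f * c / 2
        f_eff = (f * c / 2) / denom if denom > 0 else 0.0
        fetal = rng.random(n_reads) < f_eff
        meth_p = np.where(
            fetal, _meth(fetal_meth, row.dmr_id), _meth(maternal_meth, row.dmr_id)
        )

        methylated = rng.random((n_reads, len(cpg))) < meth_p[:, None]
        converted = rng.random((n_reads, len(cpg))) < conversion_rate
        cpg_call = np.where(methylated, "C", np.where(converted, "T", "C"))
        noncpg_call = np.where(
            rng.random((n_reads, len(noncpg))) < conversion_rate, "T", "C"
        )

        read_ids = np.array([f"{row.dmr_id}_r{i}" for i in range(n_reads)])
        reads = pd.DataFrame(
            {
                "read_id": read_ids,
                "mean_quality": np.round(rng.normal(quality_mean, 3.0, n_reads), 1),
                "length": np.maximum(
                    40, rng.normal(length_mean, 15.0, n_reads).astype(int)
                ),
            }
        )
        calls = pd.DataFrame(
            {
                "read_id": np.concatenate(
                    [np.repeat(read_ids, len(cpg)), np.repeat(read_ids, len(noncpg))]
                ),
                "pos": np.concatenate(
                    [np.tile(cpg, n_reads), np.tile(noncpg, n_reads)]
                ),
                "context": ["cpg"] * (n_reads * len(cpg))
                + ["non_cpg"] * (n_reads * len(noncpg)),
                "call": np.concatenate([cpg_call.ravel(), noncpg_call.ravel()]),
            }
        )
        out[row.dmr_id] = DmrReadSet(
            dmr_id=row.dmr_id,
            chrom=row.chrom,
            cpg_positions=cpg,
            reads=reads,
            calls=calls,
        )
    return out
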