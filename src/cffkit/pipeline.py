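"""End-to-end pipeline runner and clinical-trial confusion metrics.

``run_pipeline`` ties the stages together for one sample: simulate (or load)
the inputs, estimate the fetal fraction by every applicable method, call
aneuploidy by both the read-count z-score and the SNP-shift route, and write
a machine-readable JSON report plus a short human-readable summary.

``compute_trial_metrics`` turns per-trisomy confusion counts into the
standard screening metrics (sensitivity, specificity, PPV, NPV).  The
module also carries the outcome counts of a published 1012-sample NIPT
cohort as a worked example; predictions lost to follow-up are handled by an
explicit policy (excluded, or counted as true positives) because published
summary tables differ in which convention they adopt.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import allelic, io, shift, synthetic, wgs
from .types import LOW_FF_CUTOFF, TRISOMY_CHROMS

logger = logging.getLogger("cffkit")

#: Outcome counts of the 1012-sample whole-genome low-coverage NIPT cohort.
#: "confirmed" = karyotype- or postnatally-confirmed predicted positives;
#: "refuted" = predicted positives that failed confirmation; "unconfirmed" =
#: lost to follow-up.  One predicted-negative case was a false negative (T21).
TRIAL_OUTCOMES: dict[str, Any] = {
    "n_samples": 1012,
    "n_positive_calls": 30,
    "n_negative_calls": 982,
    "negatives_followed": 813,
    "per_trisomy": {
        "T21": {"predicted": 25, "confirmed": 23, "refuted": 1, "unconfirmed": 2,
                "false_negatives": 1},
        "T18": {"predicted": 4, "confirmed": 3, "refuted": 1, "unconfirmed": 0,
                "false_negatives": 0},
        "T13": {"predicted": 1, "confirmed": 0, "refuted": 1, "unconfirmed": 0,
                "false_negatives": 0},
    },
}


def trial_confusion(policy: str = "exclude") -> dict[str, dict[str, int]]:
    """Per-trisomy TP/FP/TN/FN from the trial outcome counts.

    ``policy`` governs predictions lost to follow-up: ``"exclude"`` drops
    them; ``"count_as_positive"`` treats unrefuted predictions as true.
    TN is the negative-call count minus that trisomy's false negatives.
    """
    if policy not in ("exclude", "count_as_positive"):
        raise ValueError(f"unknown follow-up policy {policy!r}")
    neg = TRIAL_OUTCOMES["n_negative_calls"]
    out = {}
    for name, c in TRIAL_OUTCOMES["per_trisomy"].items():
        tp = c["confirmed"] + (c["unconfirmed"] if policy == "count_as_positive" else 0)
        out[name] = {
            "TP": tp,
            "FP": c["refuted"],
            "FN": c["false_negatives"],
            "TN": neg - c["false_negatives"],
        }
    return out


def compute_trial_metrics(confusion: dict[str, dict[str, int]]) -> pd.DataFrame:
    """Screening metrics (in percent) from per-class confusion counts.

    Undefined ratios (zero denominators) are reported as NaN.
    """
    rows = []
    for name, c in confusion.items():
        tp, fp, tn, fn = (int(c[k]) for k in ("TP", "FP", "TN", "FN"))
        if min(tp, fp, tn, fn) < 0:
            raise ValueError(f"{name}: negative confusion counts")

        def ratio(num: int, den: int) -> float:
            return 100.0 * num / den if den > 0 else float("nan")

        rows.append(
            {
                "class": name,
                "sensitivity": ratio(tp, tp + fn),
                "specificity": ratio(tn, tn + fp),
                "PPV": ratio(tp, tp + fp),
                "NPV": ratio(tn, tn + fn),
            }
        )
    return pd.DataFrame(rows).set_index("class")


@dataclass(frozen=True)
class RunConfig:
    """Configuration for one simulated-sample pipeline run."""

    seed: int = 0
    fetal_fraction: float = 0.12
    fetal_sex: str = "male"
    trisomy_chrom: str | None = None
    total_reads: int = 5_000_000
    snp_depth: float = 5000.0
    n_reference: int = 30
    z_threshold: float = wgs.DEFAULT_Z_THRESHOLD
    alpha: float = shift.DEFAULT_ALPHA
    a_threshold: float = allelic.DEFAULT_A_THRESHOLD
    min_depth: int = allelic.DEFAULT_MIN_DEPTH
    low_ff_cutoff: float = LOW_FF_CUTOFF
    out_dir: str | None = None
    sample_id: str = "sample"
    extra: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        cfg = io.read_ground_truth(path) or {}
        known = {k: v for k, v in cfg.items() if k in cls.__dataclass_fields__}
        return cls(**known)


def _chry_anchors(
    genome_model: pd.DataFrame, total_reads: int, seed: int
) -> tuple[float, float]:
    """Calibrate the chrY estimator anchors from euploid simulations.

    female_bg: mean chrY share over female-fetus samples (fetal fraction 0);
    male_ref: mean chrY share over fully fetal male samples (fraction 1).
    """
    shares = {"female": [], "male": []}
    for i in range(3):
        for sex, f in (("female", 0.0), ("male", 1.0)):
            spec = synthetic.MixtureSpec(f, fetal_sex=sex, seed=seed + 7000 + i)
            counts = synthetic.simulate_binned_counts(
                spec, total_reads=total_reads, genome_model=genome_model
            )
            rep = wgs.chromosome_representation(wgs.gc_correct(counts))
            shares[sex].append(rep.share("chrY"))
    return float(np.mean(shares["female"])), float(np.mean(shares["male"]))


def run_pipeline(cfg: RunConfig) -> dict[str, Any]:
    """Simulate one sample and run every estimation and calling stage.

    Returns the sample report (also written to ``cfg.out_dir`` as JSON and
    text alongside every stage's intermediate table when an output directory
    is configured).  Deterministic given ``cfg.seed``.
    """
    logger.info("pipeline start: sample=%s seed=%d", cfg.sample_id, cfg.seed)
    spec = synthetic.MixtureSpec(
        cfg.fetal_fraction,
        fetal_sex=cfg.fetal_sex,
        trisomy_chrom=cfg.trisomy_chrom,
        seed=cfg.seed,
    )
    genome_model = synthetic.default_genome_model()
    gc_bias = synthetic.GcBiasModel.linear(1.0, 1.6)

    # --- WGS route ---------------------------------------------------------
    binned = synthetic.simulate_binned_counts(
        spec, gc=gc_bias, total_reads=cfg.total_reads, genome_model=genome_model
    )
    corrected = wgs.gc_correct(binned)
    rep = wgs.chromosome_representation(corrected)
    reference = []
    for i in range(cfg.n_reference):
        ref_spec = synthetic.MixtureSpec(
            0.10, fetal_sex="female", seed=cfg.seed + 1000 + i
        )
        ref_counts = synthetic.simulate_binned_counts(
            ref_spec, gc=gc_bias, total_reads=cfg.total_reads,
            genome_model=genome_model,
        )
        reference.append(wgs.chromosome_representation(wgs.gc_correct(ref_counts)))

    # --- fetal fraction ----------------------------------------------------
    ff_estimates: dict[str, Any] = {}
    if cfg.fetal_sex == "male":
        female_bg, male_ref = _chry_anchors(genome_model, cfg.total_reads, cfg.seed)
        ff_estimates["chrY"] = wgs.ff_from_chry(rep.share("chrY"), female_bg, male_ref)

    panel = synthetic.shift_panel(seed=cfg.seed)
    sim = synthetic.simulate_snp_pileups(spec, panel=panel, depth=cfg.snp_depth)
    pileups = allelic.dedup_by_tag(sim.reads)
    ff_estimates["allelic"] = allelic.sample_ff_allelic(
        pileups, min_depth=cfg.min_depth, a_threshold=cfg.a_threshold
    )
    try:
        ff_estimates["dist_match"] = allelic.ff_distribution_match(
            allelic.AfDistribution(pileups["alt_fraction"].dropna().to_numpy()),
            depth=float(pileups["n_templates"].median()),
        )
    except ValueError as exc:
        logger.warning("distribution matching skipped: %s", exc)

    # QC gates on the allelic estimate (sex-independent, always available)
    gating = ff_estimates["allelic"]

    # --- aneuploidy calls --------------------------------------------------
    wgs_calls = {
        chrom: wgs.zscore_call(
            rep, reference, chrom, ff=gating,
            z_threshold=cfg.z_threshold, low_ff_cutoff=cfg.low_ff_cutoff,
        )
        for chrom in TRISOMY_CHROMS
    }
    per_snp = allelic.per_snp_ff(pileups[pileups["r_sum"] >= cfg.min_depth])
    snp_calls = {
        chrom: shift.trisomy_shift_test(per_snp, chrom, alpha=cfg.alpha)
        for chrom in TRISOMY_CHROMS
    }

    report: dict[str, Any] = {
        "sample_id": cfg.sample_id,
        "seed": cfg.seed,
        "qc": {
            "ff_gating_method": gating.method,
            "ff_gating_value": gating.value,
            "low_ff": gating.value < cfg.low_ff_cutoff,
        },
        "fetal_fraction": {
            m: {"value": e.value, "method": e.method,
                "n_snps": e.diagnostics.get("n_snps")}
            for m, e in ff_estimates.items()
        },
        "wgs_calls": {
            c: {"z": k.statistic, "call": k.call, "qc_flags": list(k.qc_flags)}
            for c, k in wgs_calls.items()
        },
        "snp_shift_calls": {
            c: {"t": None if np.isnan(k.statistic) else k.statistic,
                "p_value": k.p_value, "call": k.call,
                "qc_flags": list(k.qc_flags)}
            for c, k in snp_calls.items()
        },
    }

    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        io.write_binned_counts(binned, out / "binned_counts.tsv")
        io.write_tagged_reads(sim.reads, out / "tagged_reads.tsv")
        io.write_pileups(pileups, out / "pileups.tsv")
        io.write_pileups(per_snp, out / "per_snp_ff.tsv")
        io.write_ground_truth(
            {
                "fetal_fraction": cfg.fetal_fraction,
                "fetal_sex": cfg.fetal_sex,
                "trisomy_chrom": cfg.trisomy_chrom,
                "seed": cfg.seed,
            },
            out / "ground_truth.yaml",
        )
        io.write_report(report, out / "report.json")
        (out / "report.txt").write_text(format_report(report))
    logger.info("pipeline done: sample=%s", cfg.sample_id)
    return report


def format_report(report: dict[str, Any]) -> str:
    """Human-readable rendering of a sample report."""
    lines = [
        f"sample: {report['sample_id']} (seed {report['seed']})",
        f"QC: gated by {report['qc']['ff_gating_method']} "
        f"FF={report['qc']['ff_gating_value']:.3f}"
        + ("  [LOW FF]" if report["qc"]["low_ff"] else ""),
        "fetal fraction estimates:",
    ]
    for m, e in report["fetal_fraction"].items():
        lines.append(f"  {m:>10}: {e['value']:.3f}")
    lines.append("aneuploidy calls (read-count z | SNP-shift t):")
    for chrom in report["wgs_calls"]:
        w = report["wgs_calls"][chrom]
        s = report["snp_shift_calls"][chrom]
        p = f"{s['p_value']:.2e}" if s.get("p_value") is not None else "n/a"
        t = f"{s['t']:+6.2f}" if s.get("t") is not None else "   n/a"
        lines.append(
            f"  {chrom:>6}: z={w['z']:+6.2f} {w['call']:<10} | "
            f"t={t} p={p} {s['call']}"
        )
    return "\n".join(lines) + "\n"
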