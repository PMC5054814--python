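"""Generator correctness: conservation, dosage signal, determinism, errors."""

import numpy as np
import pandas as pd
import pytest

import cffkit as ck
from cffkit.synthetic import _mixture_minor_fraction


class TestBinnedCounts:
    def test_total_reads_conserved_exactly(self, coarse_genome):
        c = ck.simulate_binned_counts(
            ck.MixtureSpec(0.13, seed=1), total_reads=123_457,
            genome_model=coarse_genome,
        )
        assert c["count"].sum() == 123_457

    def test_euploid_shares_match_genome_shares(self, coarse_genome):
        """f=0, identity GC: expected share of each autosome = its bin share."""
        reps = []
        for s in range(20):
            c = ck.simulate_binned_counts(
                ck.MixtureSpec(0.0, seed=s), total_reads=2_000_000,
                genome_model=coarse_genome,
            )
            reps.append(ck.chromosome_representation(c).shares)
        mean_shares = pd.concat(reps, axis=1).mean(axis=1)
        n_bins = coarse_genome.groupby("chrom").size()
        w = n_bins.astype(float)
        w.loc["chrY"] = 0.0  # female mother, female fetus at f=0
        expected = w / w.sum()
        for chrom in ("chr1", "chr13", "chr21", "chrX"):
            p = expected[chrom]
            se = np.sqrt(p * (1 - p) / 2_000_000) / np.sqrt(20)
            assert abs(mean_shares[chrom] - p) < 3 * se

    def test_trisomy_inflates_share_by_one_plus_half_f(self, coarse_genome):
        """Trisomic chr21 share is inflated by (1 + f/2) before normalisation."""
        f = 0.10
        spec0 = ck.MixtureSpec(f, trisomy_chrom="chr21", seed=0)
        w = coarse_genome["chrom"].map(spec0.dosage_weight)
        p21 = w[coarse_genome["chrom"] == "chr21"].sum() / w.sum()
        # analytic check of the dosage model itself
        n21 = (coarse_genome["chrom"] == "chr21").sum()
        assert spec0.dosage_weight("chr21") == pytest.approx(1 + f / 2)
        assert p21 == pytest.approx(n21 * (1 + f / 2) / w.sum())
        # Monte-Carlo mean within 3 SE of the closed form
        n_seeds, reads = 40, 2_000_000
        shares = [
            ck.chromosome_representation(
                ck.simulate_binned_counts(
                    ck.MixtureSpec(f, trisomy_chrom="chr21", seed=s),
                    total_reads=reads, genome_model=coarse_genome,
                )
            ).share("chr21")
            for s in range(n_seeds)
        ]
        se = np.sqrt(p21 * (1 - p21) / reads) / np.sqrt(n_seeds)
        assert abs(np.mean(shares) - p21) < 3 * se

    def test_trisomic_share_strictly_increases_with_f(self):
        shares = []
        for f in (0.0, 0.05, 0.1, 0.2, 0.4):
            spec = ck.MixtureSpec(f, trisomy_chrom="chr18")
            w18 = spec.dosage_weight("chr18")
            total = sum(
                spec.dosage_weight(c) * n
                for c, n in ck.synthetic.CHROM_LENGTHS.items()
            )
            shares.append(w18 * ck.synthetic.CHROM_LENGTHS["chr18"] / total)
        assert all(a < b for a, b in zip(shares, shares[1:]))

    def test_male_fetus_chry_share_scales_with_f(self, coarse_genome):
        spec = ck.MixtureSpec(0.2, fetal_sex="male", seed=3)
        c = ck.simulate_binned_counts(
            spec, total_reads=5_000_000, genome_model=coarse_genome
        )
        rep = ck.chromosome_representation(c)
        w = coarse_genome["chrom"].map(spec.dosage_weight)
        expected = w[coarse_genome["chrom"] == "chrY"].sum() / w.sum()
        se = np.sqrt(expected / 5_000_000)
        assert abs(rep.share("chrY") - expected) < 4 * se
        assert spec.dosage_weight("chrY") == pytest.approx(0.2 / 2)

    def test_seed_determinism(self, coarse_genome):
        spec = ck.MixtureSpec(0.11, trisomy_chrom="chr13", seed=42)
        a = ck.simulate_binned_counts(spec, total_reads=10**6,
                                      genome_model=coarse_genome)
        b = ck.simulate_binned_counts(spec, total_reads=10**6,
                                      genome_model=coarse_genome)
        pd.testing.assert_frame_equal(a, b)

    def test_errors(self, coarse_genome):
        with pytest.raises(ValueError):
            ck.MixtureSpec(0.1, trisomy_chrom="chr7")
        with pytest.raises(ValueError):
            ck.MixtureSpec(1.2)
        with pytest.raises(ValueError):
            ck.simulate_binned_counts(
                ck.MixtureSpec(0.1), genome_model=coarse_genome.iloc[:0]
            )
        with pytest.raises(ValueError):
            ck.simulate_binned_counts(
                ck.MixtureSpec(0.1), total_reads=0, genome_model=coarse_genome
            )


class TestSnpPileups:
    def test_balanced_heterozygote_at_zero_ff(self):
        """f=0, maternal AB: expected minor-allele template fraction is 1/2."""
        geno = pd.DataFrame(
            {"mat_dosage": [1], "fet_dosage": [1], "fet_copies": [2]}
        )
        assert _mixture_minor_fraction(ck.MixtureSpec(0.0), geno)[0] == 0.5

    def test_maternal_hom_fetal_het_fraction_is_half_f(self):
        geno = pd.DataFrame(
            {"mat_dosage": [0], "fet_dosage": [1], "fet_copies": [2]}
        )
        assert _mixture_minor_fraction(ck.MixtureSpec(0.10), geno)[0] == pytest.approx(
            0.05
        )

    def test_trisomic_dosage_rescales_fraction(self):
        """Three fetal copies weigh the fetal side by 3/2."""
        geno = pd.DataFrame(
            {"mat_dosage": [1], "fet_dosage": [3], "fet_copies": [3]}
        )
        f = 0.12
        expected = ((1 - f) / 2 + 3 * f / 2) / (1 + f / 2)
        spec = ck.MixtureSpec(f, trisomy_chrom="chr21")
        assert _mixture_minor_fraction(spec, geno)[0] == pytest.approx(expected)

    def test_seed_determinism_and_read_table_shape(self, panel):
        a = ck.simulate_snp_pileups(ck.MixtureSpec(0.1, seed=5), panel=panel,
                                    depth=500)
        b = ck.simulate_snp_pileups(ck.MixtureSpec(0.1, seed=5), panel=panel,
                                    depth=500)
        pd.testing.assert_frame_equal(a.reads, b.reads)
        assert set(a.reads.columns) >= {"chrom", "pos", "snp_id", "allele", "tag"}

    def test_dedup_oracle_restores_template_counts(self, panel):
        """error_rate=0 + unique tags: dedup recovers pre-PCR counts exactly."""
        sim = ck.simulate_snp_pileups(
            ck.MixtureSpec(0.12, seed=7), panel=panel, depth=800, error_rate=0.0,
            pcr=ck.PcrModel(duplication_rate=2.0, unique_tags=True),
        )
        pl = ck.dedup_by_tag(sim.reads).set_index("snp_id")
        t = sim.templates.set_index("snp_id")
        assert (pl.loc[t.index, "n_a"].to_numpy()
                == t["a_templates"].to_numpy()).all()
        assert (pl.loc[t.index, "n_b"].to_numpy()
                == t["b_templates"].to_numpy()).all()

    def test_mean_read_depth_matches_request(self, panel):
        sim = ck.simulate_snp_pileups(
            ck.MixtureSpec(0.1, seed=11), panel=panel, depth=2000,
            pcr=ck.PcrModel(duplication_rate=1.5),
        )
        mean_depth = len(sim.reads) / len(panel)
        assert mean_depth == pytest.approx(2000, rel=0.05)

    def test_errors(self, panel):
        with pytest.raises(ValueError):
            ck.simulate_snp_pileups(ck.MixtureSpec(0.1), panel=panel.iloc[:0])
        with pytest.raises(ValueError):
            ck.simulate_snp_pileups(ck.MixtureSpec(0.1), panel=panel,
                                    error_rate=0.6)
        with pytest.raises(ValueError):
            ck.snp_panel(maf_range=(0.0, 0.6))


class TestBisulfite:
    def test_unmethylated_maternal_only_reads_fully_converted(self):
        rs = ck.simulate_bisulfite_reads(
            spec=ck.MixtureSpec(0.0, seed=1), maternal_meth=0.0, fetal_meth=1.0,
            conversion_rate=1.0, n_reads=500,
        )
        m = ck.dmr_methylation(rs["DMR1"])
        assert m.meth_fraction == 0.0
        assert m.conversion_rate == 1.0

    def test_fully_fetal_fully_methylated(self):
        rs = ck.simulate_bisulfite_reads(
            spec=ck.MixtureSpec(1.0, seed=2), fetal_meth=1.0,
            conversion_rate=1.0, n_reads=500,
        )
        assert ck.dmr_methylation(rs["DMR2"]).meth_fraction == 1.0

    def test_mixture_methylation_matches_closed_form(self):
        """f=0.15, maternal 5% / fetal 95% methylated -> about 18.5%."""
        rs = ck.simulate_bisulfite_reads(
            spec=ck.MixtureSpec(0.15, seed=3), maternal_meth=0.05,
            fetal_meth=0.95, conversion_rate=1.0, n_reads=10_000,
        )
        m = ck.dmr_methylation(rs["DMR3"])  # control or chr21: euploid here
        expected = 0.85 * 0.05 + 0.15 * 0.95
        se = np.sqrt(expected * (1 - expected) / (2 * 10_000))
        assert abs(m.meth_fraction - expected) < 3 * se

    def test_dmr_with_too_few_cpgs_rejected(self):
        bad = ck.default_dmr_panel().copy()
        bad.loc[0, "cpg_offsets"] = (10,)
        with pytest.raises(ValueError, match=">=2 CpG"):
            ck.simulate_bisulfite_reads(dmr_panel=bad.iloc[[0]],
                                        spec=ck.MixtureSpec(0.1))
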