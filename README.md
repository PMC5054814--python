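# cffkit

Noninvasive prenatal testing (NIPT) toolkit for cell-free DNA: aneuploidy
screening, fetal-fraction estimation, and a fully controlled synthetic
maternal+fetal cfDNA mixture simulator so that every stage can be verified
against known ground truth without any patient data.

## The problem

Plasma of a pregnant woman carries a mixture of maternal cfDNA and a fetal
(placental) component; the fetal fraction *f* is typically 10–20%. A fetal
trisomy of chromosome 21, 18 or 13 inflates that chromosome's share of
sequenced reads by a factor of roughly 1 + *f*/2, which shallow whole-genome
sequencing can detect — provided counts are corrected for GC bias and *f* is
large enough (below ~4% a negative result is unreliable). Estimating *f*
therefore gates every call. `cffkit` implements:

* **Read-count calling** (`cffkit.wgs`): bins → 1%-GC-stratum mean
  correction → per-chromosome representation → z-score against a euploid
  reference panel (high risk at z ≥ 3; low-*f* negatives become no-calls).
* **Fetal fraction, three ways**:
  * *chrY representation* — linear interpolation of the sample's chrY share
    between female background and adult-male reference (male fetuses only);
  * *allelic* (`cffkit.allelic`) — per-SNP concentration from deep-sequenced
    high-MAF SNPs, no parental genotyping required. With
    a = R_min / R_maj, a SNP is maternal-heterozygous when a ≥ 0.25 and

        C = (R_maj − R_min) / R_sum   (maternal heterozygous)
        C = 2 · R_min / R_sum         (maternal homozygous, fetal minor allele)

    and the sample estimate is the mean C over informative SNPs on control
    autosomes (excluding 13/18/21 and sex chromosomes). PCR duplicates are
    first collapsed by random molecular tag — one template per (SNP, tag) —
    because uneven amplification otherwise skews allele ratios;
  * *distribution matching* — the minor-allele-fraction histogram of
    high-MAF SNPs in the 35–65% window is matched (Pearson correlation)
    against mixtures of normal peaks at 50% and 50 ± x/2 % for x = 1..25;
    the best x is the fetal-fraction percentage.
* **SNP-shift trisomy test** (`cffkit.shift`): Welch t-test of per-SNP C
  values on the target chromosome against the control-autosome pool
  (p < 0.05 → high risk).
* **DMR methylation readout** (`cffkit.methylation`): bisulphite reads over
  fetal-hypermethylated regions — Q20/100 bp filtering, conversion rate from
  non-CpG cytosines, methylation at the first two CpGs, group summaries.
  Characterisation only: no clinical call is derived from methylation.
* **Simulator** (`cffkit.synthetic`): multinomial binned counts with GC bias
  and trisomy/sex dosage, Hardy-Weinberg SNP panels with binomial template
  sampling, tagged PCR duplication with optional allele-skewed
  amplification, sequencing error, and bisulphite DMR reads — all
  reproducible from a seed, with ground truth returned alongside.

## Worked example

```python
import cffkit as ck

cfg = ck.RunConfig(seed=0, fetal_fraction=0.12, trisomy_chrom="chr21",
                   total_reads=1_000_000, n_reference=20)
report = ck.run_pipeline(cfg)
print(ck.pipeline.format_report(report))
```

```
sample: sample (seed 0)
QC: gated by allelic FF=0.120
fetal fraction estimates:
        chrY: 0.121
     allelic: 0.120
  dist_match: 0.120
aneuploidy calls (read-count z | SNP-shift t):
   chr13: z= +0.15 low_risk   | t=   n/a p=n/a no_call
   chr18: z= +1.17 low_risk   | t=   n/a p=n/a no_call
   chr21: z=+12.44 high_risk  | t= +2.13 p=3.85e-02 high_risk
```

A simulated 12%-fetal-fraction trisomy-21 sample: all three fetal-fraction
estimators recover the generating value (0.120–0.121), the read-count method
flags chr21 at z = 12.4 against a 20-sample euploid panel, and the SNP-shift
test rejects at p = 0.038. The SNP panel targets chr21, so chr13/chr18 have
no panel SNPs and the shift test reports no-call for them; the read-count
route covers all three.

The same stages are available from the shell:

```
cffkit simulate snp -f 0.12 --seed 3 --out reads.tsv
cffkit ff allelic --reads reads.tsv
cffkit metrics
```

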