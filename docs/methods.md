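# Methods

## The mixture model

A plasma sample is modelled as a two-component cfDNA mixture: maternal DNA
with weight 1 − f and fetal (placental) DNA with weight f, where f is the
fetal fraction. Dosage is expressed per haploid genome: a chromosome with
maternal copy number m and fetal copy number c contributes mass
(1 − f)·m/2 + f·c/2 per unit of genome share. Consequences used throughout:

* a fetal trisomy multiplies that chromosome's expected read share by
  1 + f/2 (before renormalisation over the genome);
* a male fetus gives chrY an expected share of f/2 times chrY's genome
  share; the mother contributes none;
* at a SNP where the mother carries dosage m ∈ {0,1,2} of an allele and the
  fetus d of c copies, the expected allele fraction among templates is
  ((1−f)·m/2 + f·d/2) / ((1−f) + f·c/2).

## Synthetic data generator

The generator emulates the tabular outputs of a sequencing pipeline, not
reads or alignments.

**Binned counts.** The genome is an abstract bin table (default 50 kb bins
over approximate human chromosome lengths, ~62k bins). Each bin's sampling
weight is its chromosome's dosage weight times an optional GC-bias weight
(`GcBiasModel`, e.g. a linear 2× ramp); counts are one multinomial draw, so
totals are conserved exactly. Bin GC follows a smooth deterministic profile
spanning ~0.30–0.60 so that 1% GC strata are well populated.

**SNP pileups.** The panel mirrors a high-MAF amplicon design: 36 regions of
~200 bp holding 220 SNPs with MAF ~ U(0.3, 0.5), independent across SNPs (no
LD; panel regions are short and disjoint). Maternal genotypes are
Hardy-Weinberg draws; the fetus inherits one maternal allele (uniformly)
plus one population allele; on a trisomic chromosome the third copy
duplicates one of the two parental-origin copies, chosen uniformly (the
simplest unbiased model — meiotic origin is not resolved). Template counts
per SNP are Poisson with mean depth/(1 + duplication_rate) so amplification
restores the requested read depth; template alleles are binomial at the
mixture fraction. Each template gets a molecular tag drawn uniformly from
4^tag_length (default 12; colliding templates at one SNP merge at dedup — a
known, quantifiable artifact; `unique_tags=True` forces collision-free
ground truth) and 1 + Poisson(rate) read copies. When amplification bias is
enabled, a random 25% of regions boost one random allele's duplication rate
by the bias factor (3.0 in the concordance study — a strong but realistic
per-amplicon skew). Reads flip allele at the sequencing error rate (default
0.1% — a typical short-read substitution rate).

`simulate_template_pileups` is a shortcut that skips tagging/amplification
and returns template-level pileups directly — equivalent to collision-free
tagging followed by exact dedup, except that sequencing error is applied per
template, so majority-vote error suppression is not modelled. The large
Monte-Carlo studies (test size/power) use it; everything that exercises the
dedup machinery uses the full tagged path.

**Bisulphite reads.** Each read originates from the fetus with probability
equal to the fetal dosage share of the DMR's chromosome (so a trisomy scales
the fetal weight by 3/2); CpG methylation is Bernoulli per origin;
unmethylated and non-CpG cytosines convert to T with the conversion rate.
The shipped 16-DMR panel (12 on chr21, 4 control) is synthetic — real panels
carry curated coordinates; only the panel's shape matters here.

**What the simulator does not model**, and hence what passing tests do not
show about real data: mappability/blacklist structure and inter-sample
technical variance in binned counts (reference panels here have pure
multinomial noise, so z-scores are optimistic), linkage disequilibrium,
structural variation under amplicons, maternal mosaicism/CNVs, and partial
read coverage of DMRs.

## Estimators and tests

**GC correction** rescales each bin by (global mean)/(its 1% GC-stratum
mean). It preserves the total count, is idempotent to float tolerance, and
zeroes the count–GC trend by construction. A single stratum is the identity.
Stratum-mean rescaling was chosen over LOESS for transparency; it is the
simplest scheme that flattens the injected bias.

**z-score calls** use the sample's chromosome share against the mean/SD of a
euploid panel (≥ 20 samples; sample SD, ddof 1), threshold z ≥ 3 — a field
convention, as is the 4% low-f QC cutoff. A low-f sample with a
non-significant statistic is reported no_call with a `low_ff` flag (a weak
fetal signal cannot support a confident negative); a significant statistic
still calls high risk.

**Per-SNP allelic estimator.** The dividing coefficient a = R_min/R_maj
classifies sites at threshold 0.25; the boundary value is assigned to the
heterozygous class so classification is deterministic. Both branch formulas
return exactly f for their intended genotype configurations at infinite
depth (closed forms (1+f)/2 − (1−f)/2 = f and 2·f/2 = f). Sites need ≥ 100
templates after dedup (below that, branch variance swamps the signal).

The sample-level estimate is the mean C over control autosomes (excluding
chr13/18/21 and sex chromosomes). By default it averages only *informative*
sites: heterozygous sites must deviate from 50:50 by more than 3 binomial
SDs, homozygous sites' minor count must exceed the error floor
(noise_rate·R_sum) by 3 SDs. Rationale: genotype configurations with no
maternal–fetal difference (both heterozygous, or both homozygous in the
same allele) produce C values clustered near zero; under Hardy-Weinberg at
MAF 0.3–0.5 they are roughly half the panel, so a literal mean over all
sites underestimates f by ~2× (the screen-off mean is unbiased at depths
where the screen's truncation is negligible, i.e. f ≳ 6/√depth). The
unscreened mean remains available (`informative_only=False`), and the shift
test below deliberately uses unscreened values. The screen makes the default
estimator insensitive below f ≈ 0.07 at 2000-template depth for the
heterozygous branch; the homozygous branch still carries the estimate there.

**Distribution matching.** Observed alt-allele fractions inside the 35–65%
window (the noisy near-0%/100% peaks never enter), histogrammed at 1
percentage point; candidates are a single normal at 50% and, for each
x = 1..25, an equal-weight three-peak mixture at 50% and 50 ± x/2 %, with
per-peak SD = 100·√(0.25/depth) percentage points, floored at 0.5. The score
is the Pearson correlation of bin masses. Equal thirds are used because the
three central genotype configurations are a priori comparably likely at
high MAF; bin width and correlation metric are the simplest choices
consistent with "correlates best". Resolution is therefore 1 percentage
point and the estimator is shape-only (invariant to duplicating every
observation).

**SNP-shift test.** Welch (unequal-variance) two-sided t-test of target-
chromosome C values against the pooled control autosomes (13/18/21 and sex
chromosomes excluded from the pool), α = 0.05 flat across targets (a
Bonferroni option is deliberately not applied by default, matching the flat
threshold the method was reported with). Two-sided because the per-SNP shift
direction depends on which allele the trisomy duplicates. Preconditions:
≥ 5 target and ≥ 20 control SNPs, otherwise no_call. Measured operating
characteristics under the default study conditions (40 target / 180 control
SNPs, 5000 templates per SNP): type-I error ≈ 0.04–0.05 at nominal 0.05, and
power ≈ 0.64 / 0.71 / 0.72 / 0.75 at f = 0.04 / 0.08 / 0.12 / 0.16 (500-seed
Monte Carlo). Power saturates near 0.75 because the per-SNP C distribution
is a genotype-configuration mixture whose spread grows with f exactly as the
trisomy shift does; more target SNPs, not more depth, is what raises it.

**chrY estimator.** Linear interpolation between a female background share
and a fully-fetal male reference share, clamped to [0, 1]; anchors are
calibrated from simulations at f = 0 and f = 1 through the same
GC-correction path as the samples.

**Methylation readout.** Reads are filtered at mean quality ≥ Q20 and
length ≥ 100 bp (boundaries inclusive). Conversion rate is the T fraction at
non-CpG cytosines. DMR methylation pools calls over the first two CpG
positions (pooling weights by coverage; a per-CpG average was the
alternative reading). Group summaries report per-DMR means, SDs and a Welch
t between groups with the explicit caveat of tiny n; the module exposes no
aneuploidy call — in mixture terms the expected level is
(1−f)·maternal + f·fetal, but within-group variance in practice makes the
readout a characterisation, not a diagnostic.

**Trial metrics.** sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
PPV = TP/(TP+FP), NPV = TN/(TN+FN), undefined ratios reported as NaN.
Predictions lost to follow-up are governed by an explicit policy flag
(`exclude` or `count_as_positive`); both are computed because published
summary tables are consistent with either convention. Metrics are always
computed from counts, never forced to match a printed table.

## Numerical and interface choices

* Coordinates: SNP positions 1-based (VCF convention); intervals 0-based
  half-open (BED convention); stated in every file header.
* Dedup ties (equal duplicate counts per tag) resolve to the allele of the
  first read in input order — deterministic under any stable input.
* Degenerate references (share SD ≤ 1e-12 of the mean) are rejected rather
  than producing astronomical z-scores.
* All randomness flows through `numpy.random.default_rng(seed)`; identical
  spec + seed gives bit-identical outputs.
* Monte-Carlo sizes in the test suite (50 seeds for allelic recovery, 500
  for test size, 100–200 for power, 5M-read binned samples) were chosen as
  the smallest runs whose binomial standard errors are well inside the
  asserted tolerances.

## Known limitations

* The z-score route's near-perfect detection at f = 0.10 reflects the
  simulator's multinomial-only noise; real reference panels have extra
  inter-sample variance and correspondingly lower z.
* The informativeness screen assumes a known sequencing error scale
  (default 0.1%) and loses heterozygous-branch sites at low f (see above).
* The distribution-matching estimator needs enough maternal-heterozygous
  SNPs in the window (≥ 10) and integer-percent resolution; samples without
  central peaks are reported as errors, not guesses.
* Cohort-scale quantities (cross-method correlations on real samples, the
  population mean fetal fraction) are properties of a clinical cohort and
  are not reproduced in simulation; only their qualitative ordering (tag
  deduplication markedly improves concordance with truth when amplification
  is allele-skewed) is asserted.
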