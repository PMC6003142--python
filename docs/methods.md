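# Methods

This note records the statistical models the package implements, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical conventions that matter for
reproducing its output.

## Variant QC

A SNP is removed when **any** of five criteria triggers: Hardy–Weinberg
p < 10⁻⁴, a duplicated-read flag, overall depth ≤ 8×, position within
10 bp of an alignment gap, or an overlapping copy number variant (≥ 2
copies). Boundary semantics are inclusive on the failing side (depth
exactly 8 fails; HWE p exactly 10⁻⁴ passes, the comparison being strictly
less-than). The duplicated-read criterion is consumed as a precomputed
boolean because the package starts downstream of read alignment; the other
four come from an annotation table, with the HWE p recomputed from
genotypes when absent. HWE defaults to the conditional exact test (the
appropriate choice for rare variants, where the 1-df chi-square is
anti-conservative); the chi-square variant is kept for larger samples. The
exact test is evaluated in controls only by default — a departure from HWE
in cases can itself be an association signal — with a pooled option.

## EM haplotype phasing

For a block of L loci (blocks here are 2–4 SNPs; the implementation
handles up to ~12 before 2^(h−1) pair enumeration becomes the limit), an
individual heterozygous at h loci is compatible with max(1, 2^(h−1))
unordered haplotype pairs. EM treats the pair as latent: the E-step
weights pair (i, j) by Pᵢ Pⱼ (doubled when i ≠ j), the M-step sets each
frequency to its expected copy count over 2N chromosomes. The
observed-data log-likelihood is asserted nondecreasing at every iteration.

Choices the estimator depends on:

- **Initialization**: the linkage-equilibrium product of allele
  frequencies plus four random Dirichlet starts (five starts total,
  seeded); the best final log-likelihood wins. The LE start alone almost
  always suffices at these block sizes; the restarts guard against the
  rare multimodal likelihood.
- **Convergence**: |Δ log-likelihood| < 10⁻⁸, at most 1000 iterations;
  non-convergence is flagged, not fatal.
- **Missing data**: individuals missing any block locus are excluded from
  that block's estimation (count logged) rather than marginalized — with
  ~1% missingness per genotype the information loss is negligible and the
  per-block totals stay interpretable as 2 × (complete individuals).
- **Pruning**: estimated frequencies below 10⁻¹⁰ are dropped.

Hard phase assignments require the best pair's posterior to exceed 0.95;
expected haplotype counts by case status default to the EM-expected copy
numbers (hence fractional totals), with an assigned-only mode that tallies
only >0.95 assignments. The expected-count mode is the default because
fractional tables are what an EM-based analysis naturally reports.

## LD and haplotype blocks

Two-locus haplotype frequencies come from the same EM. With q₁, q₂ the
minor-allele frequencies and f₁₁ the minor–minor haplotype frequency,
D = f₁₁ − q₁q₂, D′ = |D|/D_max with D_max the tightest margin-allowed
excursion in D's direction, and r² = D²/[q₁(1−q₁)q₂(1−q₂)]. The 90%
confidence interval on D′ profiles the genotype multinomial likelihood
over a 0..1 grid of D′ at step 0.001 (allele frequencies held at the EM
estimate, sign fixed at the MLE's), normalises it as a posterior and takes
the 5th/95th percentiles — the convention of the standard block-finding
software. Blocks follow the Gabriel rule: a pair is in strong LD when its
CI is (lower > 0.70, upper ≥ 0.98) and shows strong recombination when the
upper bound is < 0.90; a candidate span whose outermost pair is strong-LD
is accepted when ≥ 95% of its informative pairs are strong-LD; accepted
spans are taken greedily, longest first, non-overlapping. All three
thresholds are configurable but default to the standard values.

## Association statistics

The primary test is the uncorrected 1-df Pearson chi-square on 2×2
case/control × allele (or haplotype) copy tables. No continuity
correction: the Yates-corrected statistic does not reproduce the reference
count-table values this package is validated against, while the
uncorrected one does, to print precision. Fractional EM-expected counts
enter the formula unrounded. Adjusted odds ratios come from a logistic
model (status ~ copies + age + sex + smoking + drinking) fitted by IRLS,
complete cases only, age continuous and the rest binary; |log OR| > 15 is
flagged as separation. Multiplicity uses Bonferroni α/m. Stratified
analysis reruns the chi-square within each level of a binary stratifier
(age dichotomized at 55; never/ever and female/male in declared order) and
reports Pi = P₂/P₁ — a descriptive ratio of subgroup p-values, not a
formal interaction test.

## max(T) permutation

Case/control labels are shuffled B times with the case count fixed; each
shuffle contributes the maximum chi-square across all markers, and a
marker's family-wise empirical p is the fraction of shuffles whose maximum
reaches its observed statistic. The statistic permuted is the unadjusted
chi-square (covariates are not re-fitted), and for haplotypes the
EM-expected copy numbers are held fixed while labels permute; a
full-re-EM-per-permutation mode would be ~10⁴× slower for a negligible
change in the null distribution at these block sizes. The default counting
rule r/B can report a floor of 1/B (0.00001 at B = 10⁵); the
(r+1)/(B+1) estimator is available where a strictly positive unbiased-ish
p is preferred. Permutations come from a seeded generator; results are
bit-reproducible.

## Q–Q and FPRP

Q–Q points pair the sorted observed statistics with reference quantiles at
probability points (i − 0.5)/n. The default reference is the 1-df
chi-square (what association statistics are plotted against); the normal
reference is available. FPRP = p(1 − π) / [p(1 − π) + power·π], with power
computed by the normal approximation on the log-odds scale from the
observed table's standard error √(1/a + 1/b + 1/c + 1/d) at a target OR of
1.50 (protective targets use |ln OR|). The significance level inside the
power calculation defaults to the observed p (the convention of the
method's source); a fixed-α mode exists because published FPRP tables are
often computed at α = 0.05 and the two can differ materially for very
small p. FPRP ≤ 0.2 is labeled noteworthy.

## MDR

Factors are drinking, haplotype-carrier status, age group (≤55/>55),
smoking and sex. Carrier status defaults to EM-expected copy number ≥ 0.5,
with a hard-assignment rule available. A cell of the k-factor table is
high-risk when its case:control ratio reaches the training data's overall
ratio; empty cells are low-risk; high-risk predicts case. "100-fold
cross-validation" is implemented as 10×10-fold status-stratified CV (100
train/test evaluations) — literal 100-fold would leave ~16-sample folds at
this cohort size; passing an n_splits not divisible by 10 falls back to
literal n_splits-fold. Within each split the winner per k is the subset
with the lowest *training* balanced error (the classical MDR convention;
selecting on the held-out fold makes CVC unstable because a 160-sample
fold cannot rank near-tied models reliably), and the held-out fold
supplies the prediction error. CVC counts how often the modal subset wins;
the overall best model maximises CVC with ties broken by the lowest
average held-out error. Prediction error is balanced (mean of class-wise
error rates), robust to case/control imbalance; the permutation test
re-runs the entire search on shuffled labels and compares balanced
accuracies.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, at
the study conditions the package targets: 829 cases / 765 controls, 164
SNPs of which three blocks of 4, 4 and 2 loci are in high LD and the rest
are in linkage equilibrium (allele frequencies uniform on 0.1–0.5). Block
pools are chain-like (any locus pair shows at most three gametes), so
within-block D′ is 1 in the generating population; the two-SNP risk block
carries haplotypes at control frequencies ≈ 0.653/0.341/0.006, the rare
one (AG) being the risk haplotype. Disease follows a logistic model with
baseline log-odds −5 (rare disease, so the case-frequency enrichment
tracks the odds ratio), a per-copy haplotype effect of ln 9 — which puts
the realized case/control AG frequencies near 0.05/0.006 — and covariate
effects (age 0.05/year centred at 50, male 0.6, smoking 0.6, drinking 0.6)
sized to reproduce the order of covariate contrasts typical of such
cohorts. Sampling is retrospective: individuals are drawn from the
population model and kept until both quotas fill. The interaction preset
zeroes the main haplotype effect and gives drinkers ln(33) ≈ 3.5 per copy
with the other covariates neutral, isolating the gene–environment synergy.
Genotypes have 1% missing calls; smoking/drinking have 4% missing values.

What the generator does **not** emulate: genotyping error, population
stratification or relatedness, LD decay within blocks (block LD is
perfect), linkage between blocks, covariate correlation structure
(covariates are drawn independently), or sequence-level artefacts. Tests
passing on these cohorts therefore demonstrate correctness of the
estimators and error control under the assumed model, not robustness to
those real-data complications.

## Problem sizes and determinism

The test suite and the acceptance script run at desk scale: EM recovery
uses 100 replicate cohorts of n = 1000; family-wise error control is
checked on 200 null panels of 10 markers × 200 samples at B = 2000;
MDR recovery uses 20 replicate full-size cohorts at 100 splits; the
end-to-end pipeline runs the full 164-SNP, 829/765 design at B = 1000
permutations (B = 10⁵ is the faithful setting for final analyses and
simply takes proportionally longer). Every stochastic component takes an
explicit seed and is bit-reproducible; the pipeline manifest records
SHA-256 hashes of every output so a rerun can be verified exactly.

## Known limitations

- Haplotype blocks longer than ~12 SNPs would need partition-ligation EM.
- Only biallelic variants; no imputation, strand-flipping or liftover.
- The D′ CI is a profile posterior on a grid, adequate for block calling
  but not a frequentist interval with exact coverage.
- The FPRP power formula is a normal approximation; at very small cells it
  relies on the Haldane–Anscombe correction.
- Pi = P₂/P₁ inherits all the instability of ratios of p-values; it is
  reported because it is the field's descriptive convention, not because
  it has good sampling properties.
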