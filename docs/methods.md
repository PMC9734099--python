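# Methods

## Scope and data model

`serodiff` analyses label-free quantification (LFQ) output for a three-group
serum study: an acute-exposure group M, a survivor group S sampled years
later (with a subgroup of subjects present in both M and S), and controls C.
Inputs are MaxQuant-dialect text tables. An LFQ intensity of 0 encodes "not
quantified"; the pipeline treats 0 as missing everywhere and never imputes —
the presence filter (below) is the mechanism that keeps missingness from
dominating the statistics.

## Protein quantification

For each protein group and sample the quantification value is

    max over unique peptides p of  LFQ(p) / length(p)

Shared (non-unique) peptides are excluded to avoid cross-group variance; a
protein is missing in a sample when none of its unique peptides was
quantified there. The estimator is deliberately simple: dividing by length
removes the length bias of peptide intensities, and taking the maximum
selects the best-ionizing peptide, making the value proportional to protein
abundance times a protein-specific constant that cancels in group ratios.

QC removes protein groups flagged reverse (target-decoy hits), only
identified by site, pure contaminants — every majority accession prefixed
`CON__`; groups with a mixture of contaminant and genuine accessions are
retained, with a stricter flag-based switch available — and groups with no
unique peptide. Peptide length is taken from the sequence's residue count; a
stated `Length` column must agree or reading fails.

Isoform protein groups can be merged into an "all isoforms" row by summing
member values per sample (missing treated as 0; missing only when all
members are missing). Summation is the convention that reproduces the
published combined kininogen means from the two member groups; the rule is
inferred from those worked numbers rather than stated anywhere, and is
therefore exposed as an explicit `merge_spec` the caller controls.

## Presence filtering and sample screening

The analysis set is the proteins detected in at least 50 % (inclusive) of
the samples of at least one group. Per-sample identification counts are
screened per group with a one-sample Kolmogorov–Smirnov test against a
normal law with estimated mean/SD — note the estimated parameters make the
plain KS p-value conservative, so a Lilliefors-corrected variant is provided
— followed by a one-sided Grubbs test for a suspiciously *low* count:
G = (mean − min)/SD against the critical value
((n−1)/√n)·√(t²/(n−2+t²)) with t the upper α/n Student quantile at n−2 df.
One-sided toward the minimum because the screen targets failed runs; a
two-sided option exists.

PCA of sample intensity vectors fills missing cells with 0 (consistent with
the no-imputation policy), always centers, scales to unit variance by
default, and fixes component signs by making each component's
largest-magnitude loading positive.

## Differential testing and aggregated FDR

Contrasts are M vs S, M vs C, M vs SC and S vs C, where SC concatenates the
S and C samples (pooling at sample level, n = n_S + n_C — the convention
confirmed by the published M-vs-SC fold change). Per protein: a two-sided
two-sample t-test over observed values only (Student pooled-variance by
default, since that is the named test; Welch is a flag because common
defaults differ), requiring at least 2 observations per side and variance on
at least one side. The fold change is log2(mean_test / mean_ref).

Multiple testing uses a Benjamini–Hochberg step-up with a *fixed* total test
count m = 3 × |analysis set| (each protein faces at most three other sample
sets), i.e. q(i) = min over j ≥ i of p(j)·m/j over the pooled sorted
p-values. The three M-centric contrasts form one pooled family; S vs C is
corrected in its own family with the same total — an interpretive choice,
since the aggregation convention does not pin S vs C's family membership.
With m equal to the number of p-values the procedure reduces exactly to
textbook BH (tested against an independent implementation). Because m is at
least the number of tests, q ≥ p always holds and the correction is
conservative relative to per-contrast BH.

The paired comparison subtracts, per paired subject, the acute (M) value
from the follow-up (S) value where both are observed, and t-tests the
differences against zero (≥ 3 usable pairs, nonzero variance); plain BH runs
across the tested proteins as its own family.

## Classification

- **Single-marker LDA**: 1-D Gaussian LDA with pooled within-class variance
  and class-frequency priors, scored by leave-one-out CV; missing values
  enter as 0. In the zero-variance limit the rule degrades to
  nearest-class-mean, then to the majority class on mean ties.
  *Known behavior*: on exchangeable (null) data, LOOCV is biased below 50 %
  — removing the held-out sample shifts its own class mean away from it —
  and single replicates can reach 0 %. Apparent accuracies well above
  chance are therefore meaningful, but null accuracies scatter widely
  downward.
- **PCA-LDA** (`PCALDAClassifier`): per fit, standardize (centering always,
  unit-variance by default), PCA keeping components covering 95 % of the
  training variance (the retained fraction is a package default, not a
  claim about any particular study), LDA on the scores. All refit inside
  every CV fold. Zero-variance features are dropped per fit.
- **PLS-DA** (`PLSDAClassifier`): PLS regression on one-hot class
  indicators; the predicted class is the argmax of the fitted indicators,
  ties resolving to the alphabetically lowest label. The number of latent
  variables is selected by the oneSE rule: among 1..max_lv, the smallest
  count whose mean cross-validated accuracy is within one standard error
  (over folds) of the best mean. For two linearly separated classes,
  PLS-DA and LDA accuracies coincide up to single-sample differences.

CV schemes: leave-one-out (deterministic) and repeated stratified k-fold
(k = 10, times = 3, seeded). Held-out-group prediction fits the final model
on all samples of two groups and reports the fractions of the third group's
samples assigned to each class.

## Overrepresentation analysis

Term maps come from GMT files whose members are protein accessions; a
protein group is annotated with a term when *any* of its majority accessions
carries it. The background is the analysis set, not the whole proteome.
Before testing, a term must satisfy, in the tested set of size n_t with a
occurrences: a/n_t ≥ min_fraction (0.10; 0.05 for KEGG-style sparse
categories), a ≥ 4, and a/n_t > r × (background ratio) with r = 1 (r = 2 for
hierarchical BRITE-style categories). Eligible terms get a one-sided
("greater") Fisher exact test — one-sided because the eligibility screen
already restricts to terms above background, so the alternative of interest
is enrichment; two-sided is a flag — with BH within each category. Keyword
aggregation builds a synthetic term from all proteins carrying any term
whose name contains a given word (case-insensitive substring, so
"endopeptidase" terms also match "peptidase") and tests it alone without
eligibility thresholds.

## Synthetic studies

The generator emulates the target design: groups of 24/46/24 with 10 paired
M/S subjects. Per protein and sample,

    abundance = 2^(baseline + group_effect + subject_effect + noise)

with baseline ~ N(30, 2) in log2 (≈ 1e9 intensity units, serum-LFQ scale),
group effects ±2 log2 units on 10 % of proteins for M (5 % for S, disjoint),
subject effects N(0, 0.25) per (subject, protein) — shared between a
subject's M and S samples so the paired test gains power, but independent
across proteins so the per-protein tests stay independent (a scalar
per-subject offset would act as a batch effect correlating all tests) — and
log-normal noise with within-group CV 0.3. Each peptide's LFQ is
abundance × length × efficiency (efficiency ~ U(0.2, 1]), so the
max(LFQ/length) estimator recovers abundance × best-efficiency exactly;
detection is Bernoulli with probability logistic(slope · (log2 LFQ −
midpoint)), midpoint 31 and slope 1 by default, giving ≈ 96 % overall
detection with a monotone missing-not-at-random profile (≈ 70 % in the
lowest abundance decile). About 7 % of peptides are flagged shared, and a
small quota of reverse/contaminant/only-by-site/no-unique-peptide decoy
groups exercises the QC filters. One GO-style term map is emitted with
planted terms covering ≈ 60 % of the M-shifted proteins plus a 6 %
background rate.

What the generator does **not** emulate: peptide-level measurement noise
independent of the protein (peptides of a protein are perfectly correlated
here), LFQ normalization artifacts, match-between-runs effects, correlated
protein modules, and real annotation structure. Passing tests therefore
demonstrate correctness of the algorithms under the stated generative model,
not performance on real serum data, where detection rates are lower and
effect structure richer.

All randomness flows from one seeded generator; with a fixed seed the
emitted files are byte-identical.

## Numerical choices and problem sizes

- Missing handling: observed-only statistics in tests; missing → 0 in
  multivariate models and PCA; a zeros-as-values sensitivity mode exists for
  the contrasts.
- Degenerate inputs: proteins with < 2 observations per side (or < 3 pairs,
  or zero-variance differences) are reported untested with NaN statistics
  rather than dropped silently; zero-variance features are excluded per CV
  fold; single-class classification input raises.
- Tie-breaks: argmax class assignment resolves to the alphabetically lowest
  label; the max in quantification needs no tie-break (the value, not the
  peptide identity, is returned).
- Verification sizes: oracle equivalences run on exhaustive/random small
  instances (2×2 tables with margins ≤ 50; random peptide tables); error
  control uses 1000-protein null studies with 100 (tests) or 50 (acceptance
  script) replicates; power uses 500-protein studies with 20 replicates —
  sizes chosen so the full suite completes in minutes on one CPU while
  keeping Monte-Carlo error well inside the asserted margins.

## Known limitations

- The aggregated-BH family assignment for S vs C is a documented
  interpretation (own family, same fixed total).
- Whether published group means were computed over observed-only or all
  samples is undocumented; observed-only is assumed, consistent with the
  no-imputation policy.
- The plain KS normality screen with estimated parameters is conservative;
  use the Lilliefors variant when calibration matters.
- Printed 3-significant-digit group means limit fold-change reproduction to
  about ±0.01 in log2.
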