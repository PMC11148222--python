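# Methods

## Quantification model

Raw input is a long-format Ct table: one threshold cycle per technical
replicate per (sample, gene). Replicates are averaged arithmetically on the
cycle scale before normalisation — the standard ΔΔCt-family convention;
averaging expression values instead would bias the result because the
cycle→expression map is exponential. Normalisation is single-reference:

    ΔCt(g, s) = mean Ct(g, s) − mean Ct(TBP, s)

with TBP (TATA-box binding protein) the default housekeeping gene; any
reference symbol is accepted but multi-reference normalisation (geometric
mean of several housekeepers) is out of scope. Relative expression is
10³·2^(−ΔCt) (arbitrary units): strictly positive, halving per extra cycle.

Missing data: non-numeric Ct entries ("Undetermined", blanks) and Ct values
beyond the 40-cycle detection limit are recorded as missing at parse time,
with a warning. No Ct = 40 imputation is applied — imputing the detection
limit fabricates an expression level for a transcript that was not
detected. Samples without a usable housekeeping Ct are flagged unusable and
yield only missing ΔCt values. Downstream, missingness propagates:
screening drops missing values per gene, and a missing ΔCt makes a panel
gene abstain for that sample (excluded from that gene's accuracy
denominator) rather than vote.

## Cohort screen

Per gene, the HGG and MET relative-expression values are compared with a
two-sided Mann–Whitney U test. U is oriented as #(HGG > MET) pairs plus
half the ties, so U/(n₁n₂) is the probability a random HGG value exceeds a
random MET value — identically the ROC AUC of the same comparison, an
identity the test suite enforces to 1e-12 on random tied instances.

Two p-value modes exist because the original analysis software's choice at
n = 35/20 is unknowable:

* **exact** — the permutation distribution of U over all C(n₁+n₂, n₁)
  group assignments of the observed multiset. Implemented as an integer
  dynamic programme over tie groups (counts by 2U), equivalent to full
  enumeration including ties; validated against a brute-force
  `itertools.combinations` oracle for all n₁+n₂ ≤ 10. The two-sided p is
  the probability of |U − n₁n₂/2| at least as large as observed (the
  permutation distribution of U is symmetric about n₁n₂/2).
* **normal_approx** — z = (|U − n₁n₂/2| − ½)/σ with the tie-corrected
  variance σ² = n₁n₂/12·[(N+1) − Σ(t³−t)/(N(N−1))]; a fully tied sample
  (σ = 0) returns p = 1.
* **auto** (default) — exact when n₁·n₂ ≤ 400 (the 40-observation scale
  where the int64 DP is exact and instant), else the approximation. At the
  study's 35/20 this selects the approximation; exact and approximate p
  agree within 0.02 for tie-free groups of ≥ 8.

Effect size is the fold difference of arithmetic cohort means of relative
expression, reported as max/min ≥ 1 with a direction label (HGG_high /
MET_high / none). Significance is per-gene p < α (default 0.05) with **no
multiple-testing correction** across the 29 genes — the pipeline reproduces
a per-gene screening rule, and adjusting would change which genes become
panel candidates. Users screening larger gene sets should apply FDR control
on the reported p-values themselves.

## ROC, Youden cut-points and the panel

Per candidate gene the empirical ROC over ΔCt uses HGG as positive class.
Orientation is fixed from the screen's fold direction — a gene more
expressed in HGG predicts HGG at *low* ΔCt — not flipped post hoc to
maximise AUC; this keeps the single MET-high gene (the GRIA3 analogue)
oriented by its biology. Candidate thresholds are the midpoints between
adjacent distinct observed ΔCt values plus ±∞, so no training observation
can lie exactly on a threshold and the rule "predict HGG iff ΔCt ≤ t"
(≥ t for MET-high genes) is unambiguous and robust to measurement jitter.
Tied ΔCt values appear as diagonal ROC segments; the trapezoidal area then
equals U/(n₁n₂) exactly.

The cut-point maximises the Youden index J = sensitivity + specificity − 1.
J ties (which occur routinely with ratio-valued sens/spec) are resolved
towards higher specificity, then lower sensitivity — the most conservative
of the equally informative thresholds; the comparison uses a 1e-9 tolerance
because equal rational J values can differ in the last float bit. The
"sum of sensitivity and selectivity" phrasing sometimes seen for this index
is implemented as the −1 form, which is what published per-gene indices
reconstruct to from their sensitivity/specificity fractions.

Panel membership: screen-significant genes with AUC strictly above the gate
(default 0.8). Evaluation is a per-gene vote: each panel gene classifies
every labelled sample on its own threshold. Per-gene accuracy is
(correct HGG + correct MET)/(evaluated HGG + evaluated MET) in percent;
**total accuracy is the unweighted mean of per-gene accuracies** (matching
the published table's "total accuracy", which equals the mean of its
accuracy column), not a per-sample majority-vote accuracy — the latter is
derivable from the predictions table but is deliberately not the headline
metric. The concordance histogram counts, per sample, how many panel genes
voted its true entity; its counts sum to the number of labelled samples.
(In the source study the printed concordance counts imply 339 correct
predictions while the per-gene table sums to 338; the one-count discrepancy
is noted and not reconciled here.)

The 95% CI for total accuracy is a cohort-stratified percentile bootstrap
(default B = 2000, explicit seed): samples are resampled with replacement
within HGG and within MET (so no resample loses a cohort) and the
cut-points are **held fixed**, giving apparent-accuracy semantics that
match a published training-set table. `reselect=True` re-derives each
gene's Youden cut-point inside every resample instead, for assessing the
optimism of apparent accuracy. How the source study computed its CI is
unstated (its interval is not symmetric about its point estimate); the
stratified fixed-cut-point bootstrap is this package's explicit choice.

## Seizure and covariate associations

Within HGG, each gene's expression is compared between seizure-positive and
seizure-negative patients with the same Mann–Whitney machinery; each
stratum must have ≥ 2 samples or the screen aborts. Clinical covariates use
Pearson correlation with binary variables coded 0/1 (sex f=0/m=1, seizures
no=0/yes=1 — documented so signs are reproducible), i.e. point-biserial
correlation, with two-sided t-based p-values and pairwise-complete deletion
(the study itself has one HGG patient without seizure documentation, hence
n = 34 of 35). Zero variance leaves r undefined and flagged rather than
raising.

## Synthetic cohort generator

What it emulates: two cohorts of 35/20 samples; 29 named glutamatergic
genes; within-cohort ΔCt distributed Normal(μ_cohort, σ) per gene —
log-normal expression, consistent with the right-skewed distributions of
qPCR data; a per-sample housekeeping Ct ~ Normal(25, 1); technical
duplicates adding independent Normal(0, 0.1 cycles) to every well
(housekeeping wells included); per-replicate missingness (default 2%);
clinical covariates with the study's exact counts (sex 14f/21m and 12f/8m;
epilepsy 18/35 HGG with one record masked to emulate the undocumented
patient, 4/20 MET; ages uniform on 29–91 / 42–75 years).

Effect encoding: a between-cohort shift Δμ = log₂(fold) in mean ΔCt is
exactly the configured fold of geometric-mean expression; with equal
cohort variances (the generator keeps them equal per gene) the
arithmetic-mean fold used by the screen coincides in expectation. The nine
differential genes carry the published folds (20, 90, 2.4 MET-high, 46,
1.8, 11, 17.2, 4.7, 1.1); cohort means are placed symmetrically about the
published ΔCt cut-point where one exists, so generated cut-points land near
the published ones.

Dispersion calibration: within-cohort SD is not reported in the source
study, so σ is a calibration choice, solved in closed form from the
two-normal-model AUC, AUC = Φ(Δμ/(σ_obs√2)), for a target AUC per gene,
subtracting the technical-replicate variance 2·replicate_sd²/n_replicates
so the target refers to *observed* ΔCt. Target AUCs: 0.95/0.96/0.95 for
GRIA1/GRIA2/GRIK1 (reported as AUC > 0.9), 0.90–0.91 for GRIK4/GRM3/GLUL/
BCAT1 (reported as AUC > 0.8), and the published 0.712/0.729 for
GRIA3/SLC7A11. Null genes use σ = 1.5 cycles with fixed plausible
abundance centres. At study size (n = 35/20) the empirical AUC of a gene
calibrated to 0.73 has an SD of ≈ 0.07, so the weak-differential analogues
clear the 0.8 gate in roughly one cohort in seven — exclusion of borderline
markers at this sample size is probabilistic, not certain, and simulation
studies over many seeds should expect that rate.

What the generator does **not** model: amplification efficiency differences,
inter-plate batch effects, tumour purity, cohort-unequal variances,
gene–gene correlation, and any genuine seizure–expression association
(a shift can be planted explicitly via `seizure_shift_delta_ct` for power
studies). Passing tests on generated data therefore demonstrate the
pipeline's statistical behaviour under the stated model, not performance on
real tumour tissue.

## Numerical and design notes

* Problem sizes in the test suite: law-of-large-numbers fold recovery uses
  n = 20 000 per cohort so the Monte-Carlo error (≈1.4%) sits well inside
  the 5% assertion band; panel-recovery simulations use 20 seeds at study
  size; the no-information bound uses all-null data at n = 500 per cohort,
  screening at α = 1 and gating at 0 so the full 29-gene panel is evaluated.
* Exact-test feasibility: the DP's int64 counts are exact up to totals of
  2⁶²; larger explicit `mode="exact"` requests raise with advice to use the
  approximation.
* Degenerate inputs: empty groups, single-cohort ROC inputs, all-missing
  genes and zero-variance correlations raise or flag rather than returning
  silent defaults; an empty panel (no gene past the gate) is returned with
  a warning and cannot be bootstrapped.
* Reproducibility: every stochastic step (generator, bootstrap) takes an
  explicit seed; pipeline reruns with identical inputs and seed produce
  byte-identical TSVs, and each run writes a manifest with input digests.
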