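# Methods

## The MDR model

Given n₁ cases and n₀ controls genotyped at K biallelic loci (codes
0/1/2, minor-allele counts), a combination of k loci partitions the
sample into 3ᵏ genotype cells. Each cell is labeled high-risk when its
case:control ratio strictly exceeds T = n₁/n₀; the labeling is the MDR
model for that combination and its quality is balanced accuracy
BA = ½(n₁₁/n₁ + n₀₀/n₀). For balanced samples BA coincides with
classification accuracy. All ratio comparisons are done in exact
integer arithmetic (cases·n₀ vs controls·n₁), which makes three edge
rules fall out of one comparison:

- a ratio exactly equal to T is **low**-risk ("exceeds" is strict);
- an empty cell is low-risk, and a cell unseen at fitting time keeps
  that label at evaluation;
- a cell with cases but no controls (ratio +∞) is high-risk.

The cell-wise rule maximizes fitting-set BA over all 2^(3ᵏ) labelings,
which has one important structural consequence discussed under
*Limitations*.

All tie-breaking among equally scoring locus combinations is
lexicographic on the (sorted) locus tuple. The high/low threshold is
always recomputed from whatever subset is being fitted, never from the
full sample.

## Internal validation engines

**m-fold cross-validation** (default m = 5). Folds are stratified:
cases and controls are shuffled separately and dealt so per-fold class
counts differ by at most one. Per fold and per size k the exhaustive
search runs on the other m−1 folds; the winner's prediction accuracy
(PA) is its BA on the held-out fold using the training-derived labels.
Per k, cross-validation consistency (CVC) is the multiplicity of the
modal winning locus set, and its mean PA averages over the folds it
won (the alternative — re-evaluating the modal set in every fold — is
a documented variant we did not adopt, since only fold winners carry
"best model" status). The final model maximizes both mean PA and CVC;
when the two maximizers differ, the smaller (more parsimonious) model
wins; residual ties go to smaller k, then lexicographic order.

**Three-way split (3WS).** One stratified split into training /
testing / validation subsets with weights such as 1:1:1 or 2:2:1
(largest-remainder rounding within each class stratum, cases
apportioned before controls). Stage 1 ranks all combinations per k on
the training set and keeps the top x (ties at the cut resolved
lexicographically, keeping exactly x). Stage 2 refits each retained
combination on the testing set — fresh cell labels from testing counts,
testing-set threshold — and keeps the per-k best. Stage 3 refits the
per-k winners on the validation set; the final model maximizes
validation BA across k, ties to smaller k. The validation BA is the
reported predictive estimate. A `refit_each_stage=False` switch
carries training labels forward instead (sensitivity analysis only); a
`mode="2ws"` variant drops the validation stage and selects by testing
BA. Work accounting is explicit: the engines report fit counts, and
the training-stage counts sit at exactly m : 1 between CV-m and 3WS —
the source of the ~5× speed advantage at m = 5.

## Post-hoc pruning

The split engine lacks CV's parsimony mechanism and tends to select
models as large as the search allows. Pruning refits the selected loci
with logistic regression on genotype indicators (heterozygote and
minor-homozygote dummies per locus; common homozygote as reference) and
all inter-locus interactions: every non-empty subset of the loci is a
term, a size-s term contributing its 2ˢ indicator products. Backward
selection removes whole terms — the grouped removal preserves the
"no mode-of-inheritance assumption" semantics; a column-wise mode
exists behind `group_terms=False`. Under a p-value criterion the term
with the largest likelihood-ratio p is dropped while p > p_cut; under
AIC/BIC the single removal that most decreases the criterion is taken,
stopping when none does. Candidate scans go largest-term-first then
lexicographic, fixing all ties. No hierarchy constraint is enforced:
an interaction may outlive its main effects, since only the loci in
surviving terms matter. The pruned model is the union of those loci
and may be empty (reported as "no model", distinct from a one-locus
model). Fits use statsmodels maximum likelihood on a pivoted-QR
reduced column set; separated or non-convergent fits fall back to a
ridge-penalized GLM (α = 1e-4) whose likelihood is evaluated at the
penalized estimate, guaranteeing termination on sparse 3ᵏ designs; a
term contributing no degrees of freedom is treated as removable
(p = 1). Pruning is always fitted on the entire dataset.

## Penetrance models and the simulator

A penetrance table p_g over the 3ᵈ genotype cells of d disease loci,
with per-locus minor allele frequencies q under Hardy-Weinberg
equilibrium (cell frequencies f_g as products of (1−q)², 2q(1−q), q²),
determines prevalence K = Σ f_g p_g and the broad-sense heritability of
the binary trait h² = Σ f_g (p_g − K)² / (K(1−K)) — the
genotypic-variance ratio. Two canonical purely epistatic two-locus
models are built in: XOR (p = 0.1 where the minor-allele counts have
odd sum) and ZZ (p = 0.1 at the two opposite double-homozygote corners,
0.05 at the double heterozygote). At MAF 0.5 both have K = 0.05 and
0.025 respectively, h² ≈ 0.053 and 0.051 (0.05 to two decimals), and
exactly zero marginal single-locus effects.

Single-locus tables (dominant, recessive, additive) are solved
numerically: the target effect ratio pins the elevated-group penetrance
to the baseline, and Brent root-finding moves the baseline until the
implied h² hits its target, verified by a 1e-6 round-trip. The effect
ratio is interpreted as a penetrance **relative risk** by default, with
a group odds ratio available via `ratio_measure="odds"`. The risk
default is deliberate: the carrier-odds parameterization provably
cannot reach commonly quoted grid points — at MAF 0.5 a dominant locus
with carrier odds ratio 2.5 has a heritability supremum of ≈ 0.039, so
a target of 0.05 is infeasible, while the risk reading attains it (the
two measures agree for rare disease, and published effect-size grids of
this kind are evidently specified on the risk scale).

The simulator draws all loci independently under HWE (nuisance loci
default to the first disease locus's MAF), assigns status
Bernoulli(p_g), and rejection-samples prospectively until the case and
control quotas fill — equivalent in distribution to retrospective
sampling of genotype given status, and easier to verify. Disease loci
occupy the first columns unless placed explicitly. Datasets are
byte-deterministic given a seed. What the generator does **not**
emulate: linkage disequilibrium, missing genotypes, covariates,
genotyping error, quantitative traits, and population structure —
power estimates here speak to clean candidate-gene panels, not to the
messiness of real data.

## Power harness and permutation testing

The harness simulates replicate datasets (defaults mirror a balanced
candidate-gene design: 500 cases, 500 controls, 25 loci, 100
replicates), runs a configured engine (optionally with pruning), and
scores each replicate conservatively (selected = true loci exactly) and
liberally (selected ⊇ true loci); an empty pruned model fails both.
Standard errors are binomial, √(p̂(1−p̂)/n), maximal at 0.050 for
n = 100. Replicate seeds are counter-based
(`SeedSequence([master, replicate])`), logged per replicate so any
single dataset can be regenerated exactly. Prediction-error bias and
variance, when requested, are measured against the analytic best
attainable BA at the true loci under balanced sampling (a cell is
optimally called high when f_g p_g/K exceeds f_g(1−p_g)/(1−K)), rather
than against a finite holdout. Permutation tests shuffle phenotype
labels across the whole sample, re-run the full pipeline B times, and
report p = (1 + #{permuted ≥ observed})/(B + 1).

The test suite and the acceptance script run the full 100-replicate,
25-locus study for the headline two-locus comparisons (about a minute
of CPU) and scale down to 30–50 replicates and 8–12 loci for
directional properties (size inflation, pruning benefit, h²
monotonicity), where only orderings — not levels — are asserted.

## Numerical and design notes

- The vectorized search tabulates whole chunks of combinations with a
  single `bincount` over offset cell indices (4096 combinations per
  chunk bounds memory); the brute-force oracle in the test suite is an
  independent hash-map implementation.
- BA values are IEEE doubles derived from identical integer counts, so
  "exact tie" is well-defined and reproducible.
- Genotype codes outside {0,1,2} are rejected outright; the strict
  file parser reports the offending line and never imputes.
- `x` (top models carried per size) defaults to the number of loci;
  split proportions default to 1:1:1, with 2:2:1 the recommended
  cheaper alternative.

## Limitations

Because the refit labeling is BA-optimal per partition, refining a
combination by adding a locus can never lower its fitting-set BA: in
the validation refit, any superset of a true model scores at least as
high as the true model, and strictly higher exactly when some sub-cell
crosses the threshold. 3WS conservative power under per-stage
refitting therefore equals the probability of an exact validation-BA
tie (resolved by parsimony), which rises with signal strength — on
strong, sparse tables like ZZ it approaches 1. Published estimates of
3WS conservative power obtained with other implementations can sit
substantially lower; variants that carry labels forward instead of
refitting (both available here) change the comparison but score even
higher in our measurements. The pruning step, not the raw split,
should be regarded as the false-positive control. Other limits: the
search is single-threaded and k > 4 is API-permitted but not exercised
at scale; covariate adjustment and repeated/averaged splits are out of
scope (the seed loop in the power harness is the only replication
mechanism).
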