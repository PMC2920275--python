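# mdrsplit

Multifactor Dimensionality Reduction (MDR) for detecting epistatic
(gene–gene interaction) effects in case-control genotype data, with two
interchangeable internal-validation engines — classical m-fold
cross-validation and a single three-way train/test/validation split
(3WS) with top-x carry-forward — plus post-hoc pruning by
backward-selection logistic regression, a penetrance-function
case-control simulator, and a power-evaluation harness.

## Who this is for

Statistical geneticists and epidemiologists screening candidate-gene
case-control panels (tens of SNPs, hundreds of subjects) for interacting
loci whose joint effect on disease risk is invisible to single-locus
tests. The three-way split gives MDR's exhaustive search a ~5× cheaper
internal validation than 5-fold cross-validation; pruning restores the
parsimony that the split alone lacks.

## The method

For a combination of k loci (genotypes coded 0/1/2 as minor-allele
counts), the sample falls into 3^k genotype cells. A cell is labeled
**high-risk** when its case:control ratio exceeds the threshold
T = n₁/n₀ (1.0 for balanced data), otherwise **low-risk**. This binary
labeling is the MDR model; its quality is the balanced accuracy

&nbsp;&nbsp;&nbsp;&nbsp;BA = ½ (n₁₁/n₁ + n₀₀/n₀),

the mean of sensitivity and specificity. The best model of each size k
is the combination maximizing BA, found by exhaustive search.

*Cross-validation engine*: the sample is split into m stratified folds;
each fold's winner is refit on m−1 folds and scored on the held-out
fold (prediction accuracy, PA). Per size k, cross-validation
consistency (CVC) counts how often the modal locus set wins. The final
model maximizes both mean PA and CVC, with ties resolved toward the
more parsimonious model.

*Three-way-split engine*: one stratified split into training / testing
/ validation subsets. The exhaustive search runs only on the training
set; the top x combinations per k are refit on the testing set; the
per-k winners are refit on the validation set, and the final model
maximizes validation BA across k. A 2WS variant stops at the testing
stage.

*Pruning*: the selected loci are expanded into genotype indicator
variables with all interactions; backward selection under AIC, BIC, or
a likelihood-ratio p-value threshold drops terms, and the pruned model
is the loci surviving in any term.

*Simulator*: multi-locus penetrance tables (built-in XOR and ZZ
epistatic models, or tables solved to hit a target heritability and
effect ratio) generate balanced case-control samples under
Hardy-Weinberg equilibrium, with prevalence
K = Σ f_g p_g and heritability h² = Σ f_g (p_g − K)² / (K(1−K)).

## Worked example

```bash
mdrsplit simulate --model xor --maf 0.5 --n-cases 500 --n-controls 500 \
    --loci 25 --seed 7 --out xor.txt
mdrsplit mdr-3ws xor.txt --proportions 1:1:1 --x 25 --kmax 3 --prune bic --seed 1
```

prints (abridged):

```json
{
  "method": "3ws",
  "per_k": [
    {"k": 1, "loci": ["L6"], "validation_ba": 0.5210843373493976},
    {"k": 2, "loci": ["L1", "L2"], "validation_ba": 0.7771084337349398},
    {"k": 3, "loci": ["L1", "L2", "L6"], "validation_ba": 0.7771084337349398}
  ],
  "selected": {"k": 2, "loci": ["L1", "L2"],
               "prediction_estimate": 0.7771084337349398},
  "n_fits": {"training": 2625, "testing": 75, "validation": 3},
  "pruned": {"criterion": "bic", "loci": ["L1", "L2"]}
}
```

The simulated disease loci are L1 and L2 (an XOR interaction with no
marginal effects). The testing stage carried a k = 3 model containing
the true pair plus the false positive L6; on the validation refit it
exactly tied the true pair's BA (0.7771) and the parsimony tie-break
kept the two-locus model, whose validation BA is the reported
predictive estimate. BIC pruning confirms the pair. The training stage
evaluated all 25 + 300 + 2300 = 2625 combinations once; 5-fold
cross-validation would have needed five such passes.

The same analyses are available as library calls (`run_cv`, `run_3ws`,
`prune_model`, `power_experiment`, `permutation_test`); see the module
docstrings.

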