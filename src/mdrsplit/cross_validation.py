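"""m-fold stratified cross-validation for MDR.

For each fold the exhaustive search runs on the remaining m-1 intervals
and the winning model's prediction accuracy (PA) is its balanced
accuracy on the held-out interval, using the training-derived cell
labels.  Cross-validation consistency (CVC) of a locus set is the
number of folds in which it was the fold winner.  The final model
maximizes both mean PA and CVC; when the two maximizers disagree the
more parsimonious (smaller) model wins.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .dataset import GenotypeDataset
from .mdr import balanced_accuracy, count_combinations, fit_risk_model, rank_models_for_k


@dataclass(frozen=True)
class CVConfig:
    """Settings for :func:`run_cv`.

    m is the fold count (5 is the field's default; 10 is common),
    k_range the interaction sizes searched, seed drives the stratified
    fold assignment.
    """

    m: int = 5
    k_range: tuple[int, ...] = (1, 2, 3)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("fold count m must be >= 2")
        if not self.k_range:
            raise ValueError("k_range must be non-empty")


@dataclass(frozen=True)
class FoldRecord:
    """Winner of one (k, fold) search."""

    k: int
    fold: int
    loci: tuple[int, ...]
    training_ba: float
    prediction_accuracy: float


@dataclass(frozen=True)
class CVCandidate:
    """Per-k modal model with its consistency and mean prediction accuracy.

    ``mean_pa`` averages PA over the folds in which this locus set was
    the fold winner.
    """

    k: int
    loci: tuple[int, ...]
    cvc: int
    mean_pa: float


@dataclass(frozen=True)
class CVResult:
    m: int
    fold_records: tuple[FoldRecord, ...]
    candidates: tuple[CVCandidate, ...]  # one per k, ascending k
    selected: CVCandidate
    n_training_fits: int

    @property
    def prediction_estimate(self) -> float:
        """Mean PA of the selected model — the reported predictive capability."""
        return self.selected.mean_pa


class StratificationError(ValueError):
    """A class stratum is too small for the requested number of folds."""


def stratified_folds(data: GenotypeDataset, m: int, seed: int) -> list[np.ndarray]:
    """Partition indices into m folds with near-equal cases and controls.

    Cases and controls are shuffled separately and dealt out so per-fold
    class counts differ by at most one.  Deterministic given the seed.
    """
    if data.n_cases < m or data.n_controls < m:
        raise StratificationError(
            f"need at least m={m} cases and controls (have {data.n_cases}/{data.n_controls})"
        )
    rng = np.random.default_rng(seed)
    folds: list[list[np.ndarray]] = [[] for _ in range(m)]
    for label in (1, 0):
        stratum = np.flatnonzero(data.phenotype == label)
        rng.shuffle(stratum)
        for i, part in enumerate(np.array_split(stratum, m)):
            folds[i].append(part)
    return [np.sort(np.concatenate(parts)) for parts in folds]


def run_cv(data: GenotypeDataset, config: CVConfig) -> CVResult:
    """Run MDR with m-fold cross-validation over the configured sizes."""
    data.require_both_classes()
    folds = stratified_folds(data, config.m, config.seed)
    all_idx = np.arange(data.n)
    records: list[FoldRecord] = []
    n_fits = 0
    for fold_id, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(all_idx, test_idx, assume_unique=True)
        train = data.subset(train_idx)
        test = data.subset(test_idx)
        for k in config.k_range:
            ((loci, train_ba),) = rank_models_for_k(train, k, 1)
            n_fits += count_combinations(data.n_loci, k)
            model = fit_risk_model(train, loci)
            pa = balanced_accuracy(model, test).balanced_accuracy
            records.append(
                FoldRecord(k=k, fold=fold_id, loci=loci, training_ba=train_ba,
                           prediction_accuracy=pa)
            )

    candidates = []
    for k in config.k_range:
        k_records = [r for r in records if r.k == k]
        counts = Counter(r.loci for r in k_records)
        mean_pa = {
            loci: float(np.mean([r.prediction_accuracy for r in k_records if r.loci == loci]))
            for loci in counts
        }
        # modal model; ties by higher mean PA, then lexicographic loci
        best = min(counts, key=lambda L: (-counts[L], -mean_pa[L], L))
        candidates.append(CVCandidate(k=k, loci=best, cvc=counts[best], mean_pa=mean_pa[best]))

    selected = select_final_cv(candidates)
    return CVResult(
        m=config.m,
        fold_records=tuple(records),
        candidates=tuple(sorted(candidates, key=lambda c: c.k)),
        selected=selected,
        n_training_fits=n_fits,
    )


def select_final_cv(candidates) -> CVCandidate:
    """Final-model choice among per-k modal models.

    If one candidate attains both the maximum mean PA and the maximum
    CVC it is selected.  Otherwise the parsimony rule applies: of the
    PA maximizer and the CVC maximizer, the smaller model is chosen.
    Residual ties go to smaller k, then lexicographic loci.
    """
    cands = list(candidates)
    if not cands:
        raise ValueError("no candidate models supplied")
    max_pa = max(c.mean_pa for c in cands)
    max_cvc = max(c.cvc for c in cands)
    both = [c for c in cands if c.mean_pa == max_pa and c.cvc == max_cvc]
    if both:
        return min(both, key=lambda c: (c.k, c.loci))
    pa_best = min((c for c in cands if c.mean_pa == max_pa), key=lambda c: (c.k, c.loci))
    cvc_best = min((c for c in cands if c.cvc == max_cvc), key=lambda c: (c.k, c.loci))
    return min((pa_best, cvc_best), key=lambda c: (c.k, c.loci))
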