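"""Three-way-split (3WS) internal validation for MDR, plus the 2WS variant.

The sample is split once into training / testing / validation subsets,
stratified by case-control status.  The exhaustive search runs only in
the training set; the top x locus combinations per size k carry forward
to the testing set, where each is refit (fresh cell labels from testing
counts) and the per-k best is retained; the per-k winners are refit
once more on the validation set, and the final model maximizes
validation balanced accuracy across k.  This costs one exhaustive pass
instead of the m passes of m-fold cross-validation.

In 2WS mode there is no validation set: the final model maximizes the
testing-stage BA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import GenotypeDataset
from .mdr import balanced_accuracy, count_combinations, fit_risk_model, rank_models_for_k


@dataclass(frozen=True)
class ThreeWaySplitConfig:
    """Settings for :func:`run_3ws`.

    proportions are positive weights for (training, testing,
    validation), e.g. ``(1, 1, 1)`` or ``(2, 2, 1)``; x is the number of
    top training models carried to the testing stage per k.  In mode
    ``"2ws"`` the validation weight is ignored and selection ends at
    the testing stage.  ``refit_each_stage=False`` carries the
    training-derived cell labels forward instead of refitting, for
    sensitivity analysis only.
    """

    proportions: tuple[float, ...] = (1.0, 1.0, 1.0)
    x: int = 25
    k_range: tuple[int, ...] = (1, 2, 3)
    seed: int = 0
    mode: str = "3ws"
    refit_each_stage: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("3ws", "2ws"):
            raise ValueError("mode must be '3ws' or '2ws'")
        n_parts = 3 if self.mode == "3ws" else 2
        if len(self.proportions) < n_parts:
            raise ValueError(f"mode {self.mode} needs {n_parts} proportion weights")
        if any(w <= 0 for w in self.proportions[:n_parts]):
            raise ValueError("proportion weights must be positive")
        if self.x < 1:
            raise ValueError("x must be >= 1")
        if not self.k_range:
            raise ValueError("k_range must be non-empty")


@dataclass(frozen=True)
class StageRecord:
    """Per-k trace through the three stages."""

    k: int
    training_top: tuple[tuple[tuple[int, ...], float], ...]  # (loci, training BA)
    testing_winner: tuple[int, ...]
    testing_ba: float
    validation_ba: float | None  # None in 2WS mode


@dataclass(frozen=True)
class ThreeWaySplitResult:
    mode: str
    records: tuple[StageRecord, ...]
    selected_loci: tuple[int, ...]
    selected_k: int
    prediction_estimate: float  # validation BA (3WS) or testing BA (2WS)
    n_training_fits: int
    n_testing_fits: int
    n_validation_fits: int


def _largest_remainder(total: int, weights) -> list[int]:
    """Apportion ``total`` into integer parts proportional to ``weights``."""
    w = np.asarray(weights, dtype=float)
    quotas = total * w / w.sum()
    base = np.floor(quotas).astype(int)
    rem = total - base.sum()
    # distribute leftovers by largest fractional remainder, earlier subset on ties
    order = np.argsort(-(quotas - base), kind="stable")
    base[order[:rem]] += 1
    return base.tolist()


def split_three(data: GenotypeDataset, proportions, seed: int) -> list[GenotypeDataset]:
    """Stratified split of the sample into one subset per weight.

    Within each class stratum (cases first, then controls) subset sizes
    follow largest-remainder rounding of the weights; assignment is a
    seeded shuffle, so the subsets are disjoint, exhaustive, and
    deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    parts: list[list[np.ndarray]] = [[] for _ in proportions]
    for label in (1, 0):
        stratum = np.flatnonzero(data.phenotype == label)
        rng.shuffle(stratum)
        sizes = _largest_remainder(stratum.size, proportions)
        stop = np.cumsum(sizes)
        start = stop - sizes
        for i, (a, b) in enumerate(zip(start, stop)):
            parts[i].append(stratum[a:b])
    subsets = [data.subset(np.sort(np.concatenate(p))) for p in parts]
    for s in subsets:
        if s.n_cases == 0 or s.n_controls == 0:
            raise ValueError("split infeasible: a subset has no cases or no controls")
    return subsets


def run_3ws(data: GenotypeDataset, config: ThreeWaySplitConfig) -> ThreeWaySplitResult:
    """Run MDR with a single three-way (or two-way) split."""
    data.require_both_classes()
    n_parts = 3 if config.mode == "3ws" else 2
    subsets = split_three(data, config.proportions[:n_parts], config.seed)
    train, test = subsets[0], subsets[1]
    valid = subsets[2] if config.mode == "3ws" else None

    records: list[StageRecord] = []
    n_train_fits = n_test_fits = n_valid_fits = 0
    for k in config.k_range:
        top = rank_models_for_k(train, k, config.x)
        n_train_fits += count_combinations(data.n_loci, k)
        retained = [loci for loci, _ in top]
        if config.refit_each_stage:
            ((test_loci, test_ba),) = rank_models_for_k(test, k, 1, candidates=retained)
            n_test_fits += len(retained)
        else:
            scored = []
            for loci in retained:
                model = fit_risk_model(train, loci)
                scored.append((loci, balanced_accuracy(model, test).balanced_accuracy))
            n_test_fits += len(retained)
            test_loci, test_ba = min(scored, key=lambda t: (-t[1], t[0]))

        if valid is not None:
            if config.refit_each_stage:
                ((_, valid_ba),) = rank_models_for_k(valid, k, 1, candidates=[test_loci])
            else:
                model = fit_risk_model(train, test_loci)
                valid_ba = balanced_accuracy(model, valid).balanced_accuracy
            n_valid_fits += 1
        else:
            valid_ba = None
        records.append(
            StageRecord(k=k, training_top=tuple(top), testing_winner=test_loci,
                        testing_ba=test_ba, validation_ba=valid_ba)
        )

    selected = select_final_3ws(records, mode=config.mode)
    return ThreeWaySplitResult(
        mode=config.mode,
        records=tuple(records),
        selected_loci=selected.testing_winner,
        selected_k=selected.k,
        prediction_estimate=(
            selected.validation_ba if config.mode == "3ws" else selected.testing_ba
        ),
        n_training_fits=n_train_fits,
        n_testing_fits=n_test_fits,
        n_validation_fits=n_valid_fits,
    )


def select_final_3ws(records, mode: str = "3ws") -> StageRecord:
    """Final model: argmax of validation BA (3WS) or testing BA (2WS).

    Exact ties go to the smaller k, then the lexicographically smaller
    locus tuple.
    """
    recs = list(records)
    if not recs:
        raise ValueError("no stage records supplied")
    if mode == "3ws":
        key = lambda r: (-r.validation_ba, r.k, r.testing_winner)
    else:
        key = lambda r: (-r.testing_ba, r.k, r.testing_winner)
    return min(recs, key=key)
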