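"""Power-study harness and permutation testing.

Power is estimated over replicate simulated datasets under two
definitions: conservative (the selected loci are exactly the true
disease loci) and liberal (the selected loci contain all true loci,
false positives allowed).  Conservative success implies liberal
success, so conservative power never exceeds liberal power.  Standard
errors are binomial, sqrt(p(1-p)/n).

Permutation testing re-runs the full analysis on datasets whose
phenotype labels have been shuffled, giving an empirical p-value for
the observed final-model accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cross_validation import CVConfig, run_cv
from .dataset import GenotypeDataset
from .pruning import PruningConfig, prune_model
from .simulation import PenetranceModel, bayes_balanced_accuracy, simulate_dataset
from .three_way_split import ThreeWaySplitConfig, run_3ws


@dataclass(frozen=True)
class PowerSummary:
    """Aggregated results of a replicate power experiment."""

    n_datasets: int
    conservative_power: float
    liberal_power: float
    se_conservative: float
    se_liberal: float
    mean_selected_size: float
    se_selected_size: float
    mean_prediction_estimate: float
    prediction_bias: float | None
    prediction_variance: float | None
    replicates: pd.DataFrame


@dataclass(frozen=True)
class PermutationResult:
    observed_statistic: float
    n_permutations: int
    p_value: float


def binomial_se(p_hat: float, n: int) -> float:
    """Standard error of an estimated proportion: sqrt(p(1-p)/n)."""
    return float(np.sqrt(p_hat * (1.0 - p_hat) / n))


def classify_result(selected, truth) -> dict:
    """Score one selected locus set against the truth.

    conservative_correct: exact equality; liberal_correct: the truth is
    contained in the selection.  An empty selection fails both.
    """
    selected = frozenset(selected)
    truth = frozenset(truth)
    liberal = bool(truth) and truth <= selected
    return {
        "conservative_correct": selected == truth,
        "liberal_correct": liberal,
    }


def _run_method(data: GenotypeDataset, method: str, config, pruning: PruningConfig | None,
                seed: int):
    """One analysis pass; returns (selected loci, prediction estimate)."""
    if method == "cv":
        cfg = CVConfig(m=config.m, k_range=config.k_range, seed=seed)
        res = run_cv(data, cfg)
        loci, estimate = set(res.selected.loci), res.prediction_estimate
    elif method in ("3ws", "2ws"):
        cfg = ThreeWaySplitConfig(
            proportions=config.proportions, x=config.x, k_range=config.k_range,
            seed=seed, mode=method, refit_each_stage=config.refit_each_stage,
        )
        res = run_3ws(data, cfg)
        loci, estimate = set(res.selected_loci), res.prediction_estimate
    else:
        raise ValueError("method must be 'cv', '3ws' or '2ws'")
    if pruning is not None:
        loci = set(prune_model(data, sorted(loci), pruning))
    return loci, estimate, res


def replicate_seeds(master_seed: int, n: int) -> list[tuple[int, int]]:
    """Deterministic (simulation, analysis) seed pair per replicate.

    Counter-based: replicate i draws from SeedSequence([master, i]), so
    any single replicate can be re-run exactly from the logged pair.
    """
    pairs = []
    for i in range(n):
        state = np.random.SeedSequence([int(master_seed), i]).generate_state(2)
        pairs.append((int(state[0] % 2**31), int(state[1] % 2**31)))
    return pairs


def power_experiment(
    model: PenetranceModel,
    method: str,
    config,
    n_datasets: int = 100,
    seed: int = 0,
    truth: tuple[int, ...] | None = None,
    n_cases: int = 500,
    n_controls: int = 500,
    total_loci: int = 25,
    pruning: PruningConfig | None = None,
    compute_bias: bool = False,
) -> PowerSummary:
    """Estimate conservative/liberal power over simulated replicates.

    Each replicate simulates a fresh dataset from ``model``, runs the
    configured validation engine (optionally followed by pruning), and
    scores the selected loci against the true disease loci (by default
    the first d columns).  ``compute_bias`` additionally reports the
    bias and variance of the prediction estimate against the model's
    analytic best attainable balanced accuracy.
    """
    if n_datasets < 1:
        raise ValueError("n_datasets must be >= 1")
    truth = tuple(range(model.n_loci)) if truth is None else tuple(truth)
    rows = []
    for rep, (sim_seed, ana_seed) in enumerate(replicate_seeds(seed, n_datasets)):
        data = simulate_dataset(model, n_cases, n_controls, total_loci, seed=sim_seed,
                                disease_positions=truth)
        loci, estimate, _ = _run_method(data, method, config, pruning, seed=ana_seed)
        score = classify_result(loci, truth)
        rows.append({
            "replicate": rep,
            "sim_seed": sim_seed,
            "analysis_seed": ana_seed,
            "selected_loci": ",".join(str(i) for i in sorted(loci)),
            "selected_size": len(loci),
            "prediction_estimate": estimate,
            **score,
        })
    df = pd.DataFrame(rows)
    cons = float(df["conservative_correct"].mean())
    lib = float(df["liberal_correct"].mean())
    sizes = df["selected_size"].to_numpy(dtype=float)
    bias = variance = None
    if compute_bias:
        reference = bayes_balanced_accuracy(model)
        errs = df["prediction_estimate"].to_numpy() - reference
        bias = float(errs.mean())
        variance = float(df["prediction_estimate"].var(ddof=1)) if n_datasets > 1 else 0.0
    return PowerSummary(
        n_datasets=n_datasets,
        conservative_power=cons,
        liberal_power=lib,
        se_conservative=binomial_se(cons, n_datasets),
        se_liberal=binomial_se(lib, n_datasets),
        mean_selected_size=float(sizes.mean()),
        se_selected_size=float(sizes.std(ddof=1) / np.sqrt(n_datasets)) if n_datasets > 1 else 0.0,
        mean_prediction_estimate=float(df["prediction_estimate"].mean()),
        prediction_bias=bias,
        prediction_variance=variance,
        replicates=df,
    )


def permutation_test(
    data: GenotypeDataset,
    method: str,
    config,
    n_permutations: int = 99,
    seed: int = 0,
    pruning: PruningConfig | None = None,
) -> PermutationResult:
    """Permutation p-value for the final model's accuracy estimate.

    Phenotype labels are shuffled across the whole sample B times; the
    full pipeline reruns on each shuffled dataset and
    p = (1 + #{permuted >= observed}) / (B + 1).
    """
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    rng = np.random.default_rng(seed)
    _, observed, _ = _run_method(data, method, config, pruning,
                                 seed=int(rng.integers(2**31)))
    exceed = 0
    for _ in range(n_permutations):
        perm = GenotypeDataset(
            phenotype=rng.permutation(data.phenotype),
            genotypes=data.genotypes,
            locus_names=data.locus_names,
        )
        _, stat, _ = _run_method(perm, method, config, pruning,
                                 seed=int(rng.integers(2**31)))
        if stat >= observed:
            exceed += 1
    return PermutationResult(
        observed_statistic=observed,
        n_permutations=n_permutations,
        p_value=(1 + exceed) / (n_permutations + 1),
    )
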