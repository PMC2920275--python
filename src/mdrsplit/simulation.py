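"""Penetrance-model algebra and case-control genotype simulation.

A penetrance model assigns every multi-locus genotype combination a
disease probability; together with minor-allele frequencies under
Hardy-Weinberg equilibrium (HWE) it fully specifies a disease model.
Population prevalence, broad-sense heritability of the binary trait,
and odds ratios all follow algebraically from the table.  The
simulator draws independent HWE genotypes, assigns disease status by
the penetrance of the cell at the disease loci, and rejection-samples
prospectively until the case and control quotas are filled — a
balanced candidate-gene case-control design.

Two canonical purely epistatic two-locus models are built in: XOR
(risk 0.1 wherever the two minor-allele counts have odd sum) and ZZ
(risk 0.1 at the two opposite double-homozygote corners and 0.05 at
the double heterozygote).  Neither has any marginal single-locus
effect at MAF 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .dataset import GenotypeDataset

_MODES = ("dominant", "recessive", "additive")


@dataclass(frozen=True)
class PenetranceModel:
    """Penetrance table over the 3^d genotype cells of d disease loci.

    ``table`` is flat in base-3 cell order (first locus most
    significant; code = minor-allele count, so index 0 is the
    all-common-homozygote cell).  ``mafs`` gives the minor allele
    frequency of each disease locus.
    """

    mafs: tuple[float, ...]
    table: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        table = np.asarray(self.table, dtype=float).ravel()
        d = len(self.mafs)
        if table.size != 3**d:
            raise ValueError(f"table must have 3^{d} entries, got {table.size}")
        if (table < 0).any() or (table > 1).any():
            raise ValueError("penetrances must lie in [0, 1]")
        if any(not 0 < q <= 0.5 for q in self.mafs):
            raise ValueError("minor allele frequencies must lie in (0, 0.5]")
        object.__setattr__(self, "table", table)
        object.__setattr__(self, "mafs", tuple(float(q) for q in self.mafs))

    @property
    def n_loci(self) -> int:
        return len(self.mafs)


@dataclass(frozen=True)
class EffectSizeSpec:
    """Target effect size for the single-locus penetrance solver.

    ratio_measure selects how ``odds_ratio`` is interpreted: ``"risk"``
    (default) compares the penetrances directly (the relative risk);
    ``"odds"`` compares group odds p/(1-p).  The two coincide for rare
    disease, but common (h2, ratio, MAF) grid points are attainable
    only under the risk interpretation — e.g. a dominant locus at MAF
    0.5 cannot reach h2 = 0.05 with a carrier odds ratio of 2.5 (the
    supremum is about 0.039), but can with a risk ratio of 2.5 — which
    is why risk is the default.
    """

    maf: float
    h2: float
    odds_ratio: float
    genetic_mode: str = "dominant"
    ratio_measure: str = "risk"

    def __post_init__(self) -> None:
        if not 0 < self.h2 < 1:
            raise ValueError("heritability must lie in (0, 1)")
        if self.odds_ratio <= 1:
            raise ValueError("odds ratio must exceed 1 (no-effect models are degenerate)")
        if self.genetic_mode not in _MODES:
            raise ValueError(f"genetic_mode must be one of {_MODES}")
        if self.ratio_measure not in ("odds", "risk"):
            raise ValueError("ratio_measure must be 'odds' or 'risk'")


def penetrance_xor() -> PenetranceModel:
    """Two-locus XOR model: risk 0.1 when the minor-allele counts differ in parity."""
    table = np.zeros((3, 3))
    for a in range(3):
        for b in range(3):
            if (a + b) % 2 == 1:
                table[a, b] = 0.1
    return PenetranceModel(mafs=(0.5, 0.5), table=table, name="XOR")


def penetrance_zz() -> PenetranceModel:
    """Two-locus ZZ model: risk 0.1 at the opposite homozygote corners,
    0.05 at the double heterozygote, 0 elsewhere."""
    table = np.zeros((3, 3))
    table[0, 2] = 0.1
    table[2, 0] = 0.1
    table[1, 1] = 0.05
    return PenetranceModel(mafs=(0.5, 0.5), table=table, name="ZZ")


def genotype_frequencies(maf: float) -> np.ndarray:
    """HWE genotype frequencies (common hom, het, minor hom) at one locus."""
    q = maf
    return np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])


def cell_frequencies(model: PenetranceModel) -> np.ndarray:
    """HWE frequency of each multi-locus cell, matching table order."""
    freqs = np.ones(1)
    for q in model.mafs:
        freqs = np.kron(freqs, genotype_frequencies(q))
    return freqs


def prevalence(model: PenetranceModel) -> float:
    """Population prevalence K = sum_g f_g p_g under HWE."""
    return float(cell_frequencies(model) @ model.table)


def heritability(model: PenetranceModel) -> float:
    """Broad-sense heritability of the binary trait.

    h2 = sum_g f_g (p_g - K)^2 / (K (1 - K)) — the genotypic variance of
    penetrance over the phenotypic (Bernoulli) variance.
    """
    K = prevalence(model)
    if not 0 < K < 1:
        raise ValueError("heritability undefined for degenerate prevalence")
    f = cell_frequencies(model)
    var_g = float(f @ (model.table - K) ** 2)
    return var_g / (K * (1 - K))


def _single_locus_table(mode: str, baseline: float, elevated: float) -> np.ndarray:
    if mode == "dominant":
        return np.array([baseline, elevated, elevated])
    if mode == "recessive":
        return np.array([baseline, baseline, elevated])
    raise ValueError(mode)


def _odds(p: float) -> float:
    return p / (1 - p)


def solve_single_locus_penetrance(spec: EffectSizeSpec) -> PenetranceModel:
    """Solve a one-locus penetrance table matching a target (h2, OR, MAF).

    The effect ratio fixes the elevated-group penetrance as a function
    of the baseline (dominant: carriers vs non-carriers; recessive:
    minor homozygotes vs others; additive: per-minor-allele ratio,
    linear in allele count on the log-odds or log-risk scale per
    ``spec.ratio_measure``), leaving the baseline as the one free
    parameter, found by root-finding so the implied heritability hits
    the target.  The result is verified by recomputing h2.
    """
    or_, target = spec.odds_ratio, spec.h2

    def table_for(baseline: float) -> np.ndarray:
        if spec.genetic_mode == "additive":
            if spec.ratio_measure == "odds":
                eta = np.log(_odds(baseline)) + np.log(or_) * np.arange(3)
                return 1.0 / (1.0 + np.exp(-eta))
            table = baseline * or_ ** np.arange(3)
            if table[-1] >= 1:
                return np.array([np.nan] * 3)
            return table
        if spec.ratio_measure == "odds":
            elevated_odds = or_ * _odds(baseline)
            elevated = elevated_odds / (1 + elevated_odds)
        else:
            elevated = or_ * baseline
            if elevated >= 1:
                return np.array([np.nan] * 3)
        return _single_locus_table(spec.genetic_mode, baseline, elevated)

    def h2_gap(baseline: float) -> float:
        table = table_for(baseline)
        if not np.isfinite(table).all():
            return np.nan
        model = PenetranceModel(mafs=(spec.maf,), table=table)
        return heritability(model) - target

    lo, hi = 1e-9, 1.0 - 1e-9
    grid = np.geomspace(lo, 0.999, 400)
    vals = [h2_gap(float(b)) for b in grid]
    bracket = None
    for (b1, v1), (b2, v2) in zip(zip(grid, vals), zip(grid[1:], vals[1:])):
        if np.isfinite(v1) and np.isfinite(v2) and v1 * v2 <= 0:
            bracket = (float(b1), float(b2))
            break
    if bracket is None:
        raise ValueError(
            f"no penetrance table attains h2={target} at OR={or_}, MAF={spec.maf} "
            f"({spec.genetic_mode} mode)"
        )
    baseline = brentq(h2_gap, *bracket, xtol=1e-14)
    model = PenetranceModel(mafs=(spec.maf,), table=table_for(baseline),
                            name=spec.genetic_mode)
    if abs(heritability(model) - target) > 1e-6:
        raise ValueError("penetrance solver failed round-trip heritability check")
    return model


def simulate_dataset(
    model: PenetranceModel,
    n_cases: int = 500,
    n_controls: int = 500,
    total_loci: int = 25,
    seed: int | np.random.SeedSequence = 0,
    nuisance_maf: float | None = None,
    disease_positions: tuple[int, ...] | None = None,
) -> GenotypeDataset:
    """Simulate a balanced (or arbitrary-quota) case-control dataset.

    All loci are independent HWE draws; disease status is Bernoulli in
    the penetrance of the disease-locus cell; prospective draws are
    rejected once a class quota is full.  Nuisance loci default to the
    first disease locus's MAF.  Disease loci occupy the first columns
    unless ``disease_positions`` says otherwise.  Deterministic given
    the seed.
    """
    d = model.n_loci
    if total_loci < d:
        raise ValueError("total_loci must be at least the number of disease loci")
    K = prevalence(model)
    if not 0 < K < 1:
        raise ValueError("prevalence is degenerate; one class quota is unreachable")
    positions = tuple(range(d)) if disease_positions is None else tuple(disease_positions)
    if len(set(positions)) != d or any(not 0 <= p < total_loci for p in positions):
        raise ValueError("disease_positions must be d distinct column indices")

    q_nuis = model.mafs[0] if nuisance_maf is None else float(nuisance_maf)
    mafs = np.full(total_loci, q_nuis)
    mafs[list(positions)] = model.mafs
    cum = np.cumsum(np.stack([genotype_frequencies(q) for q in mafs]), axis=1)  # (L, 3)

    rng = np.random.default_rng(seed)
    weights = 3 ** np.arange(d - 1, -1, -1)
    case_rows: list[np.ndarray] = []
    ctrl_rows: list[np.ndarray] = []
    need_cases, need_controls = n_cases, n_controls
    # expected draws per case is 1/K; batch accordingly
    batch = max(1024, int(1.2 * max(n_cases / K, n_controls / (1 - K))))
    while need_cases > 0 or need_controls > 0:
        u = rng.random((batch, total_loci))
        geno = (u > cum[None, :, 0]).astype(np.int8) + (u > cum[None, :, 1])
        cell = (geno[:, list(positions)].astype(np.int64) * weights).sum(axis=1)
        sick = rng.random(batch) < model.table[cell]
        if need_cases > 0:
            take = geno[sick][:need_cases]
            case_rows.append(take)
            need_cases -= take.shape[0]
        if need_controls > 0:
            take = geno[~sick][:need_controls]
            ctrl_rows.append(take)
            need_controls -= take.shape[0]
        batch = max(1024, int(1.2 * max(need_cases / K, need_controls / (1 - K), 0) + 64))

    genotypes = np.vstack([np.vstack(case_rows), np.vstack(ctrl_rows)])
    phenotype = np.concatenate([np.ones(n_cases, dtype=np.int8),
                                np.zeros(n_controls, dtype=np.int8)])
    return GenotypeDataset(phenotype=phenotype, genotypes=genotypes)


def bayes_balanced_accuracy(model: PenetranceModel) -> float:
    """Best attainable balanced accuracy at the true disease loci.

    Under balanced case-control sampling a cell's case share is
    f_g p_g / K and its control share f_g (1 - p_g) / (1 - K); the
    optimal rule calls a cell high-risk when the former exceeds the
    latter.  Serves as the truth reference for prediction-error bias.
    """
    K = prevalence(model)
    f = cell_frequencies(model)
    case_share = f * model.table / K
    ctrl_share = f * (1 - model.table) / (1 - K)
    high = case_share > ctrl_share
    return float(0.5 * (case_share[high].sum() + ctrl_share[~high].sum()))
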