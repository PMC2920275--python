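"""Penetrance algebra and the case-control simulator."""

import itertools

import numpy as np
import pytest

from mdrsplit import (
    EffectSizeSpec,
    PenetranceModel,
    heritability,
    penetrance_xor,
    penetrance_zz,
    prevalence,
    simulate_dataset,
    solve_single_locus_penetrance,
)
from mdrsplit.simulation import bayes_balanced_accuracy, cell_frequencies


class TestCanonicalTables:
    def test_xor_cells(self):
        t = penetrance_xor().table.reshape(3, 3)
        assert t[0, 1] == 0.1  # AA,Bb carries 10% risk
        assert t[0, 0] == 0.0  # AA,BB carries none
        assert t[1, 0] == t[1, 2] == t[2, 1] == 0.1
        assert t.sum() == pytest.approx(0.4)

    def test_zz_cells(self):
        t = penetrance_zz().table.reshape(3, 3)
        assert t[0, 2] == t[2, 0] == 0.1
        assert t[1, 1] == 0.05
        assert t.sum() == pytest.approx(0.25)

    def test_no_marginal_effects_at_maf_half(self):
        """Both canonical epistatic models hide completely from
        single-locus scans: every marginal genotype has the same
        penetrance."""
        for model in (penetrance_xor(), penetrance_zz()):
            t = model.table.reshape(3, 3)
            f = np.array([0.25, 0.5, 0.25])
            row_marg = t @ f
            col_marg = t.T @ f
            assert np.allclose(row_marg, row_marg[0])
            assert np.allclose(col_marg, col_marg[0])


class TestPrevalenceHeritability:
    def test_xor_prevalence(self):
        assert prevalence(penetrance_xor()) == pytest.approx(0.05)

    def test_zz_prevalence(self):
        assert prevalence(penetrance_zz()) == pytest.approx(0.025)

    def test_zero_table(self):
        model = PenetranceModel(mafs=(0.3,), table=[0, 0, 0])
        assert prevalence(model) == 0.0

    def test_xor_heritability(self):
        assert heritability(penetrance_xor()) == pytest.approx(0.0025 / (0.05 * 0.95))
        assert round(heritability(penetrance_xor()), 2) == 0.05

    def test_zz_heritability(self):
        assert heritability(penetrance_zz()) == pytest.approx(0.00125 / (0.025 * 0.975))
        assert round(heritability(penetrance_zz()), 2) == 0.05

    def test_constant_table_zero_h2(self):
        model = PenetranceModel(mafs=(0.5, 0.5), table=np.full(9, 0.3))
        assert heritability(model) == pytest.approx(0.0)

    @pytest.mark.parametrize("d", [1, 2, 3])
    def test_agrees_with_cellwise_enumeration(self, d):
        """Prevalence/heritability match an independent loop over all
        3^d cells with explicit HWE frequency products."""
        rng = np.random.default_rng(d)
        mafs = tuple(rng.uniform(0.1, 0.5, size=d))
        table = rng.uniform(0, 0.4, size=3**d)
        model = PenetranceModel(mafs=mafs, table=table)
        K = 0.0
        for i, cell in enumerate(itertools.product(range(3), repeat=d)):
            f = 1.0
            for q, g in zip(mafs, cell):
                f *= [(1 - q) ** 2, 2 * q * (1 - q), q**2][g]
            K += f * table[i]
        assert prevalence(model) == pytest.approx(K)
        var = 0.0
        for i, cell in enumerate(itertools.product(range(3), repeat=d)):
            f = 1.0
            for q, g in zip(mafs, cell):
                f *= [(1 - q) ** 2, 2 * q * (1 - q), q**2][g]
            var += f * (table[i] - K) ** 2
        assert heritability(model) == pytest.approx(var / (K * (1 - K)))


class TestSolver:
    @pytest.mark.parametrize("mode,measure", [
        ("dominant", "risk"),
        ("recessive", "risk"),
        ("additive", "risk"),
        ("dominant", "odds"),
    ])
    def test_round_trip(self, mode, measure):
        h2 = 0.05 if measure == "risk" else 0.01
        spec = EffectSizeSpec(maf=0.5, h2=h2, odds_ratio=2.5,
                              genetic_mode=mode, ratio_measure=measure)
        model = solve_single_locus_penetrance(spec)
        assert heritability(model) == pytest.approx(h2, abs=1e-6)
        t = model.table
        if mode == "dominant":
            assert t[1] == pytest.approx(t[2])
            assert t[1] > t[0]
            if measure == "risk":
                assert t[1] / t[0] == pytest.approx(2.5)
        elif mode == "recessive":
            assert t[0] == pytest.approx(t[1])
            assert t[2] > t[0]

    def test_recessive_low_maf(self):
        spec = EffectSizeSpec(maf=0.25, h2=0.01, odds_ratio=1.5,
                              genetic_mode="recessive")
        model = solve_single_locus_penetrance(spec)
        assert heritability(model) == pytest.approx(0.01, abs=1e-6)
        assert model.table[2] / model.table[0] == pytest.approx(1.5)

    def test_no_effect_rejected(self):
        with pytest.raises(ValueError):
            EffectSizeSpec(maf=0.5, h2=0.05, odds_ratio=1.0)

    def test_infeasible_target(self):
        # a dominant carrier odds ratio of 2.5 cannot produce h2=0.05 at
        # MAF 0.5 (supremum ~0.039)
        spec = EffectSizeSpec(maf=0.5, h2=0.05, odds_ratio=2.5,
                              genetic_mode="dominant", ratio_measure="odds")
        with pytest.raises(ValueError, match="no penetrance table"):
            solve_single_locus_penetrance(spec)


class TestSimulateDataset:
    def test_quota_and_coding(self):
        data = simulate_dataset(penetrance_xor(), 500, 500, 25, seed=3)
        assert data.n_cases == 500
        assert data.n_controls == 500
        assert data.n_loci == 25
        assert set(np.unique(data.genotypes)) <= {0, 1, 2}

    def test_hwe_frequencies_at_nuisance_loci(self):
        data = simulate_dataset(penetrance_xor(), 500, 500, 25, seed=4)
        # nuisance columns keep HWE (0.25, 0.5, 0.25) within binomial noise
        counts = np.bincount(data.genotypes[:, 10], minlength=3) / data.n
        assert counts == pytest.approx([0.25, 0.5, 0.25], abs=0.06)

    def test_cases_only_in_risk_cells(self):
        data = simulate_dataset(penetrance_xor(), 400, 400, 4, seed=6)
        cases = data.genotypes[data.phenotype == 1]
        parity = (cases[:, 0] + cases[:, 1]) % 2
        assert (parity == 1).all()  # zero-penetrance cells produce no cases

    def test_seed_determinism(self):
        a = simulate_dataset(penetrance_zz(), 100, 100, 10, seed=42)
        b = simulate_dataset(penetrance_zz(), 100, 100, 10, seed=42)
        assert np.array_equal(a.genotypes, b.genotypes)
        assert np.array_equal(a.phenotype, b.phenotype)

    def test_disease_positions(self):
        data = simulate_dataset(penetrance_xor(), 300, 300, 6, seed=7,
                                disease_positions=(1, 4))
        cases = data.genotypes[data.phenotype == 1]
        assert (((cases[:, 1] + cases[:, 4]) % 2) == 1).all()

    def test_degenerate_prevalence_rejected(self):
        dead = PenetranceModel(mafs=(0.5,), table=[0, 0, 0])
        with pytest.raises(ValueError):
            simulate_dataset(dead, 10, 10, 2, seed=0)

    def test_cell_composition_converges(self):
        """Empirical case:control make-up per disease cell approaches
        p(1-K) : (1-p)K under balanced sampling (large-n check)."""
        model = penetrance_xor()
        n = 100_000
        data = simulate_dataset(model, n, n, 2, seed=9)
        K = prevalence(model)
        f = cell_frequencies(model)
        cell = data.genotypes[:, 0] * 3 + data.genotypes[:, 1]
        for c in range(9):
            p = model.table[c]
            exp_cases = f[c] * p / K
            obs_cases = np.mean(cell[data.phenotype == 1] == c)
            se = np.sqrt(exp_cases * (1 - exp_cases) / n)
            assert abs(obs_cases - exp_cases) < max(3 * se, 1e-9)

    def test_nuisance_independence(self):
        """No nuisance locus should associate with the phenotype: the
        case/control genotype distributions agree within noise."""
        from scipy.stats import chi2_contingency

        data = simulate_dataset(penetrance_xor(), 2000, 2000, 5, seed=10)
        pvals = []
        for j in range(2, 5):
            tab = np.array([
                np.bincount(data.genotypes[data.phenotype == 1, j], minlength=3),
                np.bincount(data.genotypes[data.phenotype == 0, j], minlength=3),
            ])
            pvals.append(chi2_contingency(tab).pvalue)
        assert min(pvals) > 1e-4


def test_bayes_ba_is_attainable_ceiling():
    """The analytic best balanced accuracy at the true pair matches a
    fitted MDR model's performance on a huge sample, and exceeds it on
    independent data."""
    from mdrsplit import balanced_accuracy, fit_risk_model

    model = penetrance_zz()
    ceiling = bayes_balanced_accuracy(model)
    data = simulate_dataset(model, 50_000, 50_000, 2, seed=13)
    fitted = fit_risk_model(data, (0, 1))
    ba = balanced_accuracy(fitted, data).balanced_accuracy
    assert ba == pytest.approx(ceiling, abs=0.01)
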