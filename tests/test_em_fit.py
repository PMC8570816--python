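import math

import numpy as np
import pytest

from mhcfdr.beta_core import BetaParams, mom_estimate
from mhcfdr.em_fit import (
    BetaMixture,
    FitConfig,
    MixtureComponent,
    e_step,
    fit_mixture,
    initialize,
    mm_step,
    relative_change,
)
from mhcfdr.score_io import ScoreRecord, ScoreTable
from mhcfdr.synth_eval import SyntheticSpec, generate_synthetic


def _table_from_scores(scores, bound=4.0):
    recs = [
        ScoreRecord(
            peptide="AAAAAAAAA",
            allele="X",
            ic50_nm=float(10 ** (s * bound)),
            scaled_score=float(s),
        )
        for s in scores
    ]
    return ScoreTable(records=recs, allele="X", scale_upper_bound=bound)


def _mixture(a1, b1, w1, a2, b2, w2):
    return BetaMixture(
        MixtureComponent(BetaParams(a1, b1), w1),
        MixtureComponent(BetaParams(a2, b2), w2),
    )


class TestInitialize:
    def test_halving_weights_and_hand_moments(self):
        table = _table_from_scores([0.1, 0.2, 0.8, 0.9])
        mix = initialize(table)
        assert mix.true_component.weight == 0.5
        assert mix.false_component.weight == 0.5
        # lower half {0.1, 0.2}: mu=0.15, var=0.0025 -> Beta(7.5, 42.5)
        assert mix.true_component.params.alpha == pytest.approx(7.5, rel=1e-9)
        assert mix.true_component.params.beta == pytest.approx(42.5, rel=1e-9)
        # upper half {0.8, 0.9}: mirrored shapes
        assert mix.false_component.params.alpha == pytest.approx(42.5, rel=1e-9)
        assert mix.false_component.params.beta == pytest.approx(7.5, rel=1e-9)

    def test_odd_n_lower_half_gets_extra_record(self):
        scores = [0.1, 0.15, 0.2, 0.8, 0.9]
        table = _table_from_scores(scores)
        mix = initialize(table)
        # lower half is {0.1, 0.15, 0.2} -> mean 0.15
        assert mix.true_component.params.mean == pytest.approx(0.15, abs=1e-9)

    def test_too_few_records(self):
        with pytest.raises(ValueError, match="at least 4"):
            initialize(_table_from_scores([0.2, 0.8]))


class TestEStep:
    def test_identical_components_give_uniform_rows(self):
        mix = _mixture(2, 5, 0.5, 2, 5, 0.5)
        resp = e_step(np.array([0.1, 0.4, 0.9]), mix)
        assert np.allclose(resp, 0.5)

    def test_uniform_components_return_weights(self):
        mix = _mixture(1, 1, 0.3, 1, 1, 0.7)
        resp = e_step(np.array([0.2, 0.5, 0.8]), mix)
        assert np.allclose(resp[:, 0], 0.3)
        assert np.allclose(resp[:, 1], 0.7)

    def test_linear_density_hand_value(self):
        # x=0.25: Beta(2,1) density 2x=0.5, Beta(1,2) density 2(1-x)=1.5
        mix = _mixture(2, 1, 0.5, 1, 2, 0.5)
        resp = e_step(np.array([0.25]), mix)
        assert resp[0, 0] == pytest.approx(0.25, abs=1e-12)
        assert resp[0, 1] == pytest.approx(0.75, abs=1e-12)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(3)
        xs = rng.uniform(0.01, 0.99, 500)
        mix = _mixture(1.5, 8, 0.2, 6, 2.5, 0.8)
        resp = e_step(xs, mix)
        assert np.allclose(resp.sum(axis=1), 1.0, atol=1e-12)


class TestMMStep:
    def test_hard_assignment_recovers_full_sample_moments(self):
        rng = np.random.default_rng(4)
        xs = rng.beta(2, 8, 400)
        W = np.column_stack([np.ones_like(xs), np.zeros_like(xs)])
        mix, _ = mm_step(xs, W, FitConfig(), previous=_mixture(1, 1, 0.5, 1, 1, 0.5))
        assert mix.true_component.weight == pytest.approx(1.0)
        expected = mom_estimate(xs.mean(), xs.var())
        assert mix.true_component.params.alpha == pytest.approx(expected.alpha)
        assert mix.true_component.params.beta == pytest.approx(expected.beta)

    def test_uniform_responsibilities_equalize_components(self):
        rng = np.random.default_rng(5)
        xs = rng.beta(3, 3, 300)
        W = np.full((300, 2), 0.5)
        mix, _ = mm_step(xs, W, FitConfig())
        assert mix.true_component.params.alpha == pytest.approx(
            mix.false_component.params.alpha
        )
        assert mix.true_component.weight == pytest.approx(0.5)

    def test_oracle_responsibilities_match_partition_mom(self):
        """With true-label responsibilities, each component's parameters equal
        direct MoM on its labeled partition."""
        rng = np.random.default_rng(6)
        lo = rng.beta(2, 8, 100)
        hi = rng.beta(8, 2, 100)
        xs = np.concatenate([lo, hi])
        W = np.zeros((200, 2))
        W[:100, 0] = 1.0
        W[100:, 1] = 1.0
        mix, _ = mm_step(xs, W, FitConfig())
        e_lo = mom_estimate(lo.mean(), lo.var())
        e_hi = mom_estimate(hi.mean(), hi.var())
        assert mix.true_component.params.alpha == pytest.approx(e_lo.alpha)
        assert mix.false_component.params.beta == pytest.approx(e_hi.beta)
        # and they sit within MoM sampling error of the generating shapes
        assert mix.true_component.params.alpha == pytest.approx(2.0, rel=0.35)
        assert mix.false_component.params.alpha == pytest.approx(8.0, rel=0.35)

    def test_weights_always_renormalized(self):
        rng = np.random.default_rng(7)
        xs = rng.uniform(0.05, 0.95, 100)
        W = np.column_stack([np.full(100, 0.3), np.full(100, 0.7)])
        mix, _ = mm_step(xs, W, FitConfig())
        assert mix.true_component.weight + mix.false_component.weight == pytest.approx(
            1.0, abs=1e-12
        )


class TestRelativeChange:
    def test_identical_mixtures_zero(self):
        m = _mixture(2, 3, 0.4, 5, 1, 0.6)
        assert relative_change(m, m) == 0.0

    def test_single_alpha_change(self):
        old = _mixture(1, 3, 0.5, 5, 1, 0.5)
        new = _mixture(2, 3, 0.5, 5, 1, 0.5)
        assert relative_change(old, new) == pytest.approx(0.5)

    def test_weight_change_uses_max_denominator(self):
        old = _mixture(2, 3, 0.5, 5, 1, 0.5)
        new = _mixture(2, 3, 0.4, 5, 1, 0.6)
        # |0.4-0.5|/0.5 = 0.2; |0.6-0.5|/0.6 = 0.1667 -> max is 0.2
        assert relative_change(old, new) == pytest.approx(0.2)


class TestFitMixture:
    def test_determinism(self):
        spec = SyntheticSpec(n_true=300, n_false=900, seed=11)
        table = generate_synthetic(spec)
        f1 = fit_mixture(table, FitConfig())
        f2 = fit_mixture(table, FitConfig())
        assert f1.to_dict() == f2.to_dict()

    def test_parameter_recovery_two_seeds(self):
        """Loose recovery check; the full 10-seed evaluation lives in the
        acceptance suite."""
        for seed in (0, 1):
            spec = SyntheticSpec(
                n_true=1250, n_false=3750, decoy_exclusion_scaled=None, seed=seed
            )
            fit = fit_mixture(generate_synthetic(spec))
            assert fit.converged
            assert fit.mixture.false_component.weight == pytest.approx(0.75, abs=0.05)
            assert fit.mixture.true_component.params.mean == pytest.approx(
                BetaParams(1.5, 8.0).mean, abs=0.05
            )

    def test_loglik_non_decreasing_at_convergence(self):
        spec = SyntheticSpec(
            n_true=500, n_false=1500, decoy_exclusion_scaled=None, seed=13
        )
        fit = fit_mixture(generate_synthetic(spec))
        tail = np.array(fit.loglik_trace[-10:])
        assert np.all(np.diff(tail) >= -1e-6 * np.abs(tail[:-1]))

    def test_all_false_collapses_to_single_component(self):
        spec = SyntheticSpec(
            n_true=0, n_false=2000, decoy_exclusion_scaled=None, seed=14
        )
        fit = fit_mixture(generate_synthetic(spec))
        assert fit.single_component == "all_false"
        assert fit.true_constraint_applied
        assert fit.mixture.true_component.weight < 0.02
        # false component hugs the generating Beta(6, 2.5)
        assert fit.mixture.false_component.params.alpha == pytest.approx(6.0, rel=0.2)

    def test_all_true_collapses_to_single_component(self):
        spec = SyntheticSpec(n_true=1000, n_false=0, seed=15)
        fit = fit_mixture(generate_synthetic(spec))
        assert fit.single_component == "all_true"
        assert fit.mixture.true_component.weight == pytest.approx(1.0)

    def test_refit_of_own_simulation_is_fixed_point(self):
        from mhcfdr.synth_eval import simulate_from_fit

        spec = SyntheticSpec(
            n_true=1250, n_false=3750, decoy_exclusion_scaled=None, seed=16
        )
        fit = fit_mixture(generate_synthetic(spec))
        sims = simulate_from_fit(fit, 5000, seed=17)
        refit = fit_mixture(_table_from_scores(sims, bound=4.7))
        m0, m1 = fit.mixture, refit.mixture
        assert m1.false_component.weight == pytest.approx(
            m0.false_component.weight, abs=0.03
        )
        for p0, p1 in (
            (m0.true_component.params, m1.true_component.params),
            (m0.false_component.params, m1.false_component.params),
        ):
            assert p1.alpha == pytest.approx(p0.alpha, rel=0.2)
            assert p1.beta == pytest.approx(p0.beta, rel=0.2)

    def test_unscaled_table_rejected(self):
        table = ScoreTable(
            records=[
                ScoreRecord(peptide="AAAAAAAAA", allele="X", ic50_nm=100.0)
            ]
            * 5,
            allele="X",
        )
        with pytest.raises(ValueError):
            fit_mixture(table)
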