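"""Regularized EM mixtures: initialization, ascent, recovery, BIC selection."""

import numpy as np
import pytest

from powermix import (
    FitConfig,
    GmmFit,
    MixtureComponent,
    bic,
    em_fit,
    kmeanspp_seed,
    mixture_density,
    responsibilities,
    sweep_and_select,
)
from powermix.exceptions import DomainError
from powermix.mixture import SelectionSweep
from powermix.synth import generate_power_mixture


def _fit_from(weights, means, variances):
    comps = tuple(
        MixtureComponent(w, m, v) for w, m, v in zip(weights, means, variances)
    )
    return GmmFit(
        components=comps, loglik=0.0, bic=0.0, converged=True,
        n_iterations=1, seed=0, n=1,
    )


class TestKmeansPlusPlus:
    def test_k_equals_one_returns_a_data_point(self, rng):
        x = np.array([0.2, 0.4, 0.9])
        assert kmeanspp_seed(x, 1, rng)[0] in x

    def test_k_equals_n_exhausts_distinct_values(self, rng):
        x = np.array([0.1, 0.3, 0.6, 0.9])
        centers = kmeanspp_seed(x, 4, rng)
        assert sorted(centers) == sorted(x)

    def test_two_clusters_split_almost_surely(self):
        # squared-distance sampling puts all mass on the opposite cluster
        x = np.array([0.0, 0.0, 0.0, 10.0, 10.0, 10.0])
        hit = 0
        for seed in range(1000):
            c = kmeanspp_seed(x, 2, np.random.default_rng(seed))
            hit += {0.0, 10.0} == set(c)
        assert hit >= 990

    def test_k_larger_than_n_rejected(self, rng):
        with pytest.raises(DomainError):
            kmeanspp_seed(np.array([1.0, 2.0]), 3, rng)


class TestEmFit:
    def test_single_component_closed_form(self, rng):
        x = rng.normal(0.4, 0.2, 137)
        fit = em_fit(x, FitConfig(k=1, restarts=1, seed=0))
        assert fit.means[0] == pytest.approx(x.mean(), abs=1e-12)
        assert fit.variances[0] == pytest.approx(x.var() + 0.001, abs=1e-12)
        assert fit.weights[0] == 1.0

    def test_two_component_parameter_recovery(self):
        rng = np.random.default_rng(3)
        x = np.concatenate(
            [rng.normal(0.1, 0.02, 200), rng.normal(0.8, 0.05, 200)]
        )
        fit = em_fit(x, FitConfig(k=2, seed=1))
        assert fit.means == pytest.approx([0.1, 0.8], abs=0.02)
        assert fit.weights == pytest.approx([0.5, 0.5], abs=0.05)

    def test_loglik_trace_is_monotone(self):
        for seed in range(8):
            rng = np.random.default_rng(seed)
            x = np.concatenate(
                [rng.normal(0.2, 0.05, 100), rng.normal(0.6, 0.15, 100)]
            )
            fit = em_fit(x, FitConfig(k=3, restarts=5, seed=seed))
            trace = fit.loglik_trace
            assert all(b >= a - 1e-8 for a, b in zip(trace, trace[1:]))

    def test_variances_never_below_regularization_floor(self):
        # collapse-prone: one isolated point far from a tight cluster
        x = np.concatenate([np.full(10, 0.1), [5.0]])
        fit = em_fit(x, FitConfig(k=4, restarts=10, seed=2))
        assert fit.variances.min() >= 0.001

    def test_unregularized_collapse_is_flagged_or_diverges(self):
        x = np.concatenate([np.linspace(0.0, 1.0, 8), [50.0]])
        fit = em_fit(
            x, FitConfig(k=8, regularization=0.0, restarts=20, seed=0, max_iter=200)
        )
        assert fit.degenerate or fit.loglik > 1e3 or not np.isfinite(fit.loglik)

    def test_identical_data_with_k2_flagged_degenerate(self):
        fit = em_fit(np.full(30, 0.5), FitConfig(k=2, restarts=3, seed=0))
        assert fit.degenerate
        assert fit.variances == pytest.approx([0.001, 0.001])

    def test_weights_sum_to_one_and_sorted_by_mean(self):
        rng = np.random.default_rng(11)
        x = rng.uniform(0, 1, 300)
        fit = em_fit(x, FitConfig(k=4, restarts=10, seed=7))
        assert fit.weights.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.all(np.diff(fit.means) >= 0)

    def test_identical_seed_identical_fit(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=150)
        f1 = em_fit(x, FitConfig(k=3, restarts=5, seed=9))
        f2 = em_fit(x, FitConfig(k=3, restarts=5, seed=9))
        assert f1.components == f2.components

    def test_too_few_observations_rejected(self):
        with pytest.raises(DomainError):
            em_fit(np.array([1.0, 2.0]), FitConfig(k=3))


class TestBic:
    def test_formula_arithmetic(self):
        fit = _fit_from([0.5, 0.5], [0.0, 1.0], [1.0, 1.0])
        fit = GmmFit(
            components=fit.components, loglik=-100.0, bic=0.0, converged=True,
            n_iterations=1, seed=0, n=730,
        )
        assert bic(fit, 730) == pytest.approx(232.97, abs=0.01)

    def test_prefers_one_component_on_unimodal_data(self):
        x = np.random.default_rng(21).normal(0.0, 1.0, 500)
        f1 = em_fit(x, FitConfig(k=1, restarts=5, seed=0))
        f2 = em_fit(x, FitConfig(k=2, restarts=5, seed=0))
        assert f1.bic < f2.bic
        # the extra component still never decreases the likelihood
        assert f2.loglik >= f1.loglik - 1e-6


class TestSweepAndSelect:
    def test_recovers_four_components(self, bench_mixture_spec):
        w, m, s = bench_mixture_spec
        x, _ = generate_power_mixture(w, m, s, 730, np.random.default_rng(0))
        sweep = sweep_and_select(x, 6, FitConfig(seed=0))
        assert sweep.winner_k == 4

    def test_unimodal_winner_is_one(self):
        x = np.random.default_rng(13).normal(0.5, 0.1, 500)
        sweep = sweep_and_select(x, 5, FitConfig(seed=13))
        assert sweep.winner_k == 1

    def test_strong_evidence_threshold_is_ten(self):
        def fit_with_bic(b):
            return GmmFit(
                components=(MixtureComponent(1.0, 0.0, 1.0),), loglik=0.0,
                bic=b, converged=True, n_iterations=1, seed=0, n=10,
            )

        strong = SelectionSweep(
            fits={1: fit_with_bic(100.0), 2: fit_with_bic(110.0)},
            winner_k=1, delta_bic_runner_up=10.0,
        )
        weak = SelectionSweep(
            fits={1: fit_with_bic(100.0), 2: fit_with_bic(109.9)},
            winner_k=1, delta_bic_runner_up=9.9,
        )
        assert strong.strong_evidence and not weak.strong_evidence

    def test_winner_minimizes_bic_and_loglik_nondecreasing_in_k(self, bench_mixture_spec):
        w, m, s = bench_mixture_spec
        x, _ = generate_power_mixture(w, m, s, 400, np.random.default_rng(2))
        sweep = sweep_and_select(x, 5, FitConfig(restarts=20, seed=2))
        bics = sweep.bic_curve()
        assert sweep.winner_k == min(bics, key=bics.get)
        logliks = [sweep.fits[k].loglik for k in sorted(sweep.fits)]
        assert all(b >= a - 1e-6 for a, b in zip(logliks, logliks[1:]))


class TestResponsibilitiesAndDensity:
    def test_rows_sum_to_one(self, rng):
        x = rng.uniform(0, 1, 200)
        fit = em_fit(x, FitConfig(k=3, restarts=5, seed=1))
        resp = responsibilities(fit, x)
        assert resp.shape == (200, 3)
        assert np.allclose(resp.sum(axis=1), 1.0, atol=1e-12)

    def test_point_at_mean_of_separated_component(self):
        fit = _fit_from([0.5, 0.5], [0.0, 10.0], [0.01, 0.01])
        resp = responsibilities(fit, [0.0, 10.0])
        assert resp[0, 0] > 0.99
        assert resp[1, 1] > 0.99

    def test_identical_components_share_responsibility(self):
        fit = _fit_from([0.25] * 4, [0.5] * 4, [0.2] * 4)
        resp = responsibilities(fit, [0.1, 0.9])
        assert np.allclose(resp, 0.25)

    def test_standard_normal_density_value(self):
        fit = _fit_from([1.0], [0.0], [1.0])
        assert mixture_density(fit, [0.0])[0] == pytest.approx(0.3989, abs=1e-4)

    def test_density_nonnegative_and_normalized(self):
        fit = _fit_from([0.3, 0.7], [0.2, 0.8], [0.01, 0.04])
        grid = np.linspace(-2, 3, 4001)
        dens = mixture_density(fit, grid)
        assert np.all(dens >= 0)
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-3)


class TestSerializationAndOracle:
    def test_json_round_trip(self, rng):
        x = rng.normal(size=120)
        fit = em_fit(x, FitConfig(k=2, restarts=5, seed=4))
        assert GmmFit.from_json(fit.to_json()) == fit

    def test_matches_sklearn_reference_likelihood(self):
        # independent implementation of the same regularized model
        sklearn = pytest.importorskip("sklearn.mixture")
        rng = np.random.default_rng(8)
        x = np.concatenate([rng.normal(0.15, 0.05, 150), rng.normal(0.7, 0.1, 150)])
        ours = em_fit(x, FitConfig(k=2, restarts=10, seed=0))
        ref = sklearn.GaussianMixture(
            n_components=2, covariance_type="diag", reg_covar=0.001,
            n_init=10, random_state=0, tol=1e-8, max_iter=500,
        ).fit(x.reshape(-1, 1))
        ref_loglik = ref.score(x.reshape(-1, 1)) * x.size
        # our multi-restart EM must do at least as well as the reference
        # (it may land in a marginally better optimum, never a worse one)
        assert ours.loglik >= ref_loglik - 0.05
        assert ours.loglik == pytest.approx(ref_loglik, abs=0.5)
        assert np.sort(ref.means_.ravel()) == pytest.approx(ours.means, abs=0.01)
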