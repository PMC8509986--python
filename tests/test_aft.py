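"""Stage-1 AFT machinery: censoring KM, IPCW-WLS, residual distribution."""

import numpy as np
import pytest
from lifelines import KaplanMeierFitter

from censmed import (
    MediationDataset,
    censoring_km,
    encode_dummies,
    fit_aft,
    fit_aft_wls,
    residual_distribution,
)
from censmed.aft import product_limit


def _dataset(times, event, exposure=None, weights=None):
    n = len(times)
    return MediationDataset(
        outcome=np.zeros(n),
        mediator_time=np.asarray(times, dtype=float),
        event=np.asarray(event),
        exposure=np.array(exposure if exposure is not None else ["a", "b"] * (n // 2) + ["a"] * (n % 2), dtype=object),
        weights=weights,
    )


class TestCensoringKM:
    def test_no_censoring_gives_unit_survival(self):
        ds = _dataset([1, 2, 3, 4], [1, 1, 1, 1])
        G = censoring_km(ds)
        assert G.times.size == 0
        np.testing.assert_allclose(G.left_limit([1, 2, 3, 4]), 1.0)

    def test_hand_computed_product_limit(self):
        # censoring at t=2 with risk set {2, 3}: G drops 1 -> 1/2
        ds = _dataset([1.0, 2.0, 3.0], [1, 0, 1])
        G = censoring_km(ds)
        np.testing.assert_allclose(G.left_limit([1.0, 2.0]), [1.0, 1.0])
        np.testing.assert_allclose(G.left_limit(3.0), 0.5)
        np.testing.assert_allclose(G(2.0), 0.5)

    def test_event_at_largest_time_keeps_positive_weight(self):
        # largest observation is an event: left limit must stay positive
        ds = _dataset([1.0, 2.0, 3.0, 4.0], [1, 0, 0, 1])
        G = censoring_km(ds)
        assert G.left_limit(4.0) > 0

    def test_matches_lifelines_on_untied_data(self):
        rng = np.random.default_rng(42)
        t = rng.exponential(1.0, size=200)
        c = rng.uniform(0, 2.5, size=200)
        m = np.minimum(t, c)
        delta = (t <= c).astype(int)
        ds = _dataset(m, delta, exposure=rng.choice(["a", "b"], 200))
        G = censoring_km(ds)
        kmf = KaplanMeierFitter().fit(m, event_observed=1 - delta)
        grid = np.quantile(m, [0.1, 0.3, 0.5, 0.7, 0.9])
        ours = np.asarray(G(grid))
        theirs = kmf.survival_function_at_times(grid).to_numpy()
        np.testing.assert_allclose(ours, theirs, atol=1e-10)

    def test_weighted_km_matches_lifelines_weights(self):
        rng = np.random.default_rng(3)
        m = rng.uniform(0.1, 3.0, size=100)
        delta = rng.integers(0, 2, size=100)
        w = rng.uniform(0.5, 2.0, size=100)
        km = product_limit(m, delta, weights=w)
        kmf = KaplanMeierFitter().fit(m, event_observed=delta, weights=w)
        grid = np.quantile(m, [0.2, 0.5, 0.8])
        np.testing.assert_allclose(
            np.asarray(km(grid)),
            kmf.survival_function_at_times(grid).to_numpy(),
            atol=1e-10,
        )

    def test_approximates_uniform_censoring_survival(self, cont_scenario):
        from censmed import simulate_population

        ds = simulate_population(cont_scenario, 60_000, seed=11)
        G = censoring_km(ds)
        # true censoring law: log c ~ U(L, U) -> S(t) = 1 - (log t - L)/(U - L)
        # grid kept within the region where subjects remain at risk (the KM
        # variance blows up beyond the bulk of the mediator distribution)
        L, U = cont_scenario.censoring_log_lower, cont_scenario.censoring_log_upper
        grid = np.exp(np.linspace(L + 0.5, cont_scenario.a0 + 2.0, 7))
        truth = 1.0 - (np.log(grid) - L) / (U - L)
        np.testing.assert_allclose(np.asarray(G(grid)), truth, atol=0.02)


class TestAFTWLS:
    def test_reduces_to_ols_without_censoring(self, toy_dataset):
        ds = MediationDataset(
            outcome=toy_dataset.outcome,
            mediator_time=toy_dataset.mediator_time,
            event=np.ones(6, dtype=int),
            exposure=toy_dataset.exposure,
        )
        design = encode_dummies(ds, "low")
        theta = fit_aft_wls(ds, design, censoring_km(ds))
        ols, *_ = np.linalg.lstsq(design.matrix, ds.log_mediator, rcond=None)
        np.testing.assert_allclose(theta, ols, atol=1e-12)

    def test_toy_fit_matches_bruteforce_normal_equations(self, toy_dataset):
        design = encode_dummies(toy_dataset, "low")
        G = censoring_km(toy_dataset)
        theta = fit_aft_wls(toy_dataset, design, G)
        # independent brute-force accumulation of the weighted normal equations
        dim = design.matrix.shape[1]
        M = np.zeros((dim, dim))
        v = np.zeros(dim)
        for i in range(toy_dataset.n):
            if toy_dataset.event[i] == 0:
                continue
            g = float(G.left_limit(toy_dataset.mediator_time[i]))
            A_i = design.matrix[i]
            M += np.outer(A_i, A_i) / g
            v += A_i * np.log(toy_dataset.mediator_time[i]) / g
        np.testing.assert_allclose(theta, np.linalg.solve(M, v), atol=1e-12)

    def test_invariant_to_weight_rescaling(self, binary_data):
        design = encode_dummies(binary_data, 0, order=(0, 1, 2))
        theta1 = fit_aft_wls(binary_data, design, censoring_km(binary_data))
        scaled = MediationDataset(
            outcome=binary_data.outcome,
            mediator_time=binary_data.mediator_time,
            event=binary_data.event,
            exposure=binary_data.exposure,
            weights=binary_data.weights * 3.7,
            family="binary",
        )
        theta2 = fit_aft_wls(scaled, design, censoring_km(scaled))
        np.testing.assert_allclose(theta1, theta2, atol=1e-10)

    def test_singular_design_raises_named_error(self):
        # non-reference category present only in censored rows
        ds = _dataset([1, 2, 3, 4], [1, 1, 1, 0], exposure=["a", "a", "a", "b"])
        design = encode_dummies(ds, "a")
        with pytest.raises(np.linalg.LinAlgError, match="x\\[b\\]"):
            fit_aft_wls(ds, design, censoring_km(ds))


class TestResidualDistribution:
    def test_uncensored_gives_empirical_distribution(self):
        ds = _dataset([1.0, 2.0, 7.0, 4.0], [1, 1, 1, 1])
        design = encode_dummies(ds, "a")
        eta = residual_distribution(ds, design, np.zeros(2))
        np.testing.assert_allclose(eta.masses, 0.25)
        np.testing.assert_allclose(eta.support, np.log([1.0, 2.0, 4.0, 7.0]))
        assert eta.tau == pytest.approx(np.log(7.0))

    def test_hand_computed_km_jumps(self):
        # residuals (-1, 0, 2) with delta (1, 0, 1): jumps 1/3 at -1, 2/3 at 2
        ds = _dataset(np.exp([-1.0, 0.0, 2.0]), [1, 0, 1])
        design = encode_dummies(ds, "a")
        eta = residual_distribution(ds, design, np.zeros(2))
        np.testing.assert_allclose(eta.support, [-1.0, 2.0])
        np.testing.assert_allclose(eta.masses, [1.0 / 3.0, 2.0 / 3.0])

    def test_renormalized_when_largest_residual_censored(self):
        ds = _dataset(np.exp([-1.0, 0.0, 2.0, 3.0]), [1, 1, 1, 0])
        design = encode_dummies(ds, "a")
        eta = residual_distribution(ds, design, np.zeros(2))
        assert eta.support[-1] == pytest.approx(2.0)
        assert eta.masses.sum() == pytest.approx(1.0, abs=1e-12)

    def test_large_sample_masses_approximate_standard_normal(self, cont_scenario):
        from scipy.stats import norm

        from censmed import simulate_population

        ds = simulate_population(cont_scenario, 30_000, seed=13)
        design = encode_dummies(ds, 0, order=(0, 1, 2))
        fit = fit_aft(ds, design)
        eta = fit.residual_dist
        # Kolmogorov-Smirnov distance of eta_hat to the generating N(0, 1)
        cdf_hat = np.cumsum(eta.masses)
        ks = np.max(np.abs(cdf_hat - norm.cdf(eta.support)))
        assert ks < 0.02

    def test_masses_sum_to_one_on_fitted_data(self, binary_data):
        design = encode_dummies(binary_data, 0, order=(0, 1, 2))
        fit = fit_aft(binary_data, design)
        assert fit.residual_dist.masses.sum() == pytest.approx(1.0, abs=1e-10)
        assert fit.tau == pytest.approx(fit.residual_dist.support[-1])
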