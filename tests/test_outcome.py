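"""Stage-2 pseudo-likelihood: weights, evaluation, and maximization."""

import numpy as np
import pytest
from scipy.special import expit
from scipy.stats import norm

from censmed import (
    MediationDataset,
    conditional_outcome_mean,
    encode_dummies,
    fit_aft,
    fit_outcome,
    pseudo_log_likelihood,
    sampling_weights,
)


def _naive_pl(phi, ds, design, aft, sigma=None, conditional=True):
    """Plain-loop reference implementation of the log-pseudo-likelihood."""
    k = design.k
    eta = aft.residual_dist
    A = design.matrix
    b0, b = phi[0], phi[1]
    c = phi[2 : 1 + k]
    gamma = phi[1 + k :]

    def pr(y, log_t, i):
        lp = b0 + b * log_t + c @ design.indicators[i] + gamma @ ds.covariates[i]
        if ds.family == "binary":
            p = expit(lp)
            return p if y == 1 else 1.0 - p
        return norm.pdf(y, loc=lp, scale=sigma)

    total = 0.0
    for i in range(ds.n):
        mu = A[i] @ aft.theta
        if ds.event[i] == 1:
            total += ds.weights[i] * np.log(pr(ds.outcome[i], np.log(ds.mediator_time[i]), i))
            continue
        e_i = np.log(ds.mediator_time[i]) - mu
        num, P = 0.0, 0.0
        for e_s, p_s in zip(eta.support, eta.masses):
            if e_s > e_i:
                num += pr(ds.outcome[i], e_s + mu, i) * p_s
                P += p_s
        if P == 0.0:  # beyond all support: nearest-point convention at tau
            total += ds.weights[i] * np.log(pr(ds.outcome[i], eta.tau + mu, i))
            continue
        val = num / P if conditional else num
        total += ds.weights[i] * np.log(val)
    return total / ds.n


def _simulated(family, n, seed, censoring=0.35):
    from censmed import SimulationScenario, calibrate_censoring, simulate_population

    kwargs = dict(maf=0.3, a0=6.0, a=0.4, b=0.4, c=0.5, censoring=censoring)
    if family == "binary":
        sc = SimulationScenario(
            family="binary", b0=-3.7, n=None, n_case=n, n_control=n, **kwargs
        )
    else:
        sc = SimulationScenario(family="continuous", b0=1.0, n=n, **kwargs)
    calibrate_censoring(sc, mc_draws=50_000, seed=seed)
    return simulate_population(sc, n, seed=seed + 1)


class TestSamplingWeights:
    def test_inverse_prevalence_rule(self):
        ds = MediationDataset(
            outcome=np.repeat([1.0, 0.0], 500),
            mediator_time=np.ones(1000),
            event=np.ones(1000, dtype=int),
            exposure=np.tile(["a", "b"], 500),
            family="binary",
        )
        sw = sampling_weights(ds, prevalence=0.10)
        assert sw.weights[0] == pytest.approx(0.2)
        assert sw.weights[-1] == pytest.approx(1.8)
        assert sw.weights.mean() == pytest.approx(1.0)

    def test_representative_sample_gets_unit_weights(self):
        y = np.array([1.0] * 10 + [0.0] * 90)
        ds = MediationDataset(
            outcome=y,
            mediator_time=np.ones(100),
            event=np.ones(100, dtype=int),
            exposure=np.tile(["a", "b"], 50),
            family="binary",
        )
        sw = sampling_weights(ds, prevalence=0.10)
        np.testing.assert_allclose(sw.weights, 1.0)

    def test_invalid_inputs_rejected(self):
        ds = MediationDataset(
            outcome=np.ones(4),
            mediator_time=np.ones(4),
            event=np.ones(4, dtype=int),
            exposure=np.array(["a", "b", "a", "b"]),
            family="binary",
        )
        with pytest.raises(ValueError, match="prevalence"):
            sampling_weights(ds, 1.5)
        with pytest.raises(ValueError, match="cases and controls"):
            sampling_weights(ds, 0.1)


class TestConditionalOutcomeMean:
    def test_binary_linear_predictor(self):
        phi = np.array([-5.0, 0.4, 0.0, 0.0])
        val = conditional_outcome_mean(phi, 6.0, [0.0, 0.0], family="binary")
        assert val == pytest.approx(expit(-2.6))
        assert val == pytest.approx(0.0691, abs=5e-5)

    def test_blocked_mediator_path(self):
        phi = np.array([1.0, 0.0, 0.3, 0.7])
        v1 = conditional_outcome_mean(phi, 2.0, [1.0, 0.0])
        v2 = conditional_outcome_mean(phi, 9.0, [1.0, 0.0])
        assert v1 == v2

    def test_zero_model(self):
        phi = np.zeros(3)
        assert conditional_outcome_mean(phi, 5.0, [0.0]) == 0.0

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            conditional_outcome_mean(np.zeros(3), 1.0, [0.0, 1.0])


class TestPseudoLikelihood:
    def test_uncensored_equals_exact_loglik_continuous(self):
        ds = _simulated("continuous", 60, seed=21)
        ds = MediationDataset(
            outcome=ds.outcome, mediator_time=ds.mediator_time,
            event=np.ones(ds.n, dtype=int), exposure=ds.exposure,
        )
        design = encode_dummies(ds, 0, order=(0, 1, 2))
        aft = fit_aft(ds, design)
        phi = np.array([1.0, 0.4, 0.5, 1.0])
        got = pseudo_log_likelihood(phi, ds, design, aft, sigma=1.1)
        lp = phi[0] + phi[1] * ds.log_mediator + design.indicators @ phi[2:4]
        expected = norm.logpdf(ds.outcome, loc=lp, scale=1.1).mean()
        assert got == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("family", ["continuous", "binary"])
    @pytest.mark.parametrize("conditional", [True, False])
    def test_matches_bruteforce_loop(self, family, conditional):
        ds = _simulated(family, 70, seed=31)
        design = encode_dummies(ds, 0, order=(0, 1, 2))
        aft = fit_aft(ds, design)
        phi = np.array([1.0 if family == "continuous" else -3.7, 0.4, 0.5, 1.0])
        sigma = 1.0 if family == "continuous" else None
        got = pseudo_log_likelihood(
            phi, ds, design, aft, sigma=sigma, conditional=conditional
        )
        expected = _naive_pl(phi, ds, design, aft, sigma=sigma, conditional=conditional)
        assert got == pytest.approx(expected, rel=1e-10)

    def test_invariant_to_subject_permutation(self):
        ds = _simulated("binary", 50, seed=41)
        design = encode_dummies(ds, 0, order=(0, 1, 2))
        aft = fit_aft(ds, design)
        phi = np.array([-3.7, 0.4, 0.5, 1.0])
        base = pseudo_log_likelihood(phi, ds, design, aft)
        rng = np.random.default_rng(1)
        perm = rng.permutation(ds.n)
        ds_p = ds.subset(perm)
        design_p = encode_dummies(ds_p, 0, order=(0, 1, 2))
        aft_p = fit_aft(ds_p, design_p)
        # same theta (WLS is permutation invariant) -> same PL value
        got = pseudo_log_likelihood(phi, ds_p, design_p, aft_p)
        assert got == pytest.approx(base, rel=1e-10)

    def test_dominated_by_generating_parameters(self):
        ds = _simulated("continuous", 4000, seed=51)
        design = encode_dummies(ds, 0, order=(0, 1, 2))
        aft = fit_aft(ds, design)
        truth = np.array([1.0, 0.4, 0.5, 1.0])
        at_truth = pseudo_log_likelihood(truth, ds, design, aft, sigma=1.0)
        for shift in ([0.5, 0, 0, 0], [0, 0.2, 0, 0], [0, 0, -0.4, 0.4]):
            perturbed = pseudo_log_likelihood(
                truth + np.asarray(shift), ds, design, aft, sigma=1.0
            )
            assert perturbed < at_truth


class TestFitOutcome:
    def test_uncensored_continuous_matches_wls(self):
        ds = _simulated("continuous", 300, seed=61)
        ds = MediationDataset(
            outcome=ds.outcome, mediator_time=ds.mediator_time,
            event=np.ones(ds.n, dtype=int), exposure=ds.exposure,
        )
        design = encode_dummies(ds, 0, order=(0, 1, 2))
        aft = fit_aft(ds, design)
        fit = fit_outcome(ds, design, aft)
        M = np.column_stack([np.ones(ds.n), ds.log_mediator, design.indicators])
        beta, *_ = np.linalg.lstsq(M, ds.outcome, rcond=None)
        np.testing.assert_allclose(fit.phi, beta, atol=1e-4)
        assert fit.converged

    def test_uncensored_binary_matches_logit_mle(self):
        import statsmodels.api as sm

        ds = _simulated("binary", 400, seed=71)
        ds = MediationDataset(
            outcome=ds.outcome, mediator_time=ds.mediator_time,
            event=np.ones(ds.n, dtype=int), exposure=ds.exposure,
            family="binary",
        )
        design = encode_dummies(ds, 0, order=(0, 1, 2))
        aft = fit_aft(ds, design)
        fit = fit_outcome(ds, design, aft)
        M = np.column_stack([np.ones(ds.n), ds.log_mediator, design.indicators])
        ref = sm.Logit(ds.outcome, M).fit(disp=0).params
        np.testing.assert_allclose(fit.phi, ref, atol=2e-3)

    def test_censored_fit_recovers_generating_values_roughly(self, binary_data):
        design = encode_dummies(binary_data, 0, order=(0, 1, 2))
        aft = fit_aft(binary_data, design)
        fit = fit_outcome(binary_data, design, aft)
        # single replicate at n=500: generous 3-sigma-ish bands
        assert fit.phi[1] == pytest.approx(0.4, abs=0.4)
        assert fit.converged
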