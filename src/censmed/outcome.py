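"""Stage 2: pseudo-likelihood estimation of the outcome model.

The outcome is linear in the log-scale mediator for a continuous ``y`` and
logistic for a binary ``y``:

    continuous:  y_i = b0 + b * log t_i + sum_j c_j x_ji + gamma^T z_i + eps
    binary:      logit Pr(y_i = 1) = b0 + b * log t_i + sum_j c_j x_ji + gamma^T z_i

When the mediator is censored its contribution integrates the outcome
probability over the stage-1 residual distribution eta_hat beyond the
censoring residual.  With phi = (b0, b, c_1..c_{k-1}, gamma) the weighted
log-pseudo-likelihood is

    PL(phi) = (1/n) sum_i w_i [ delta_i log Pr_phi(y_i | log m_i, A_i)
              + (1 - delta_i) log sum_{e_s > e_i} Pr_phi(y_i | e_s + A_i^T theta_hat, A_i) p_s / P_i ]

where e_i = log m_i - A_i^T theta_hat, the support points e_s and masses p_s
come from eta_hat (truncated at tau), and P_i = sum_{e_s > e_i} p_s
renormalizes the tail to a conditional distribution (the literal,
unnormalized tail sum is available with ``conditional=False``).  A censored
subject whose residual exceeds every support point contributes through the
nearest support point tau.  The maximizer phi_hat is found by Nelder-Mead;
for the continuous family log(sigma) is co-estimated by appending it to the
search vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

from .aft import AFTFit
from .data import DummyDesign, MediationDataset

__all__ = [
    "SamplingWeights",
    "OutcomeFit",
    "sampling_weights",
    "conditional_outcome_mean",
    "PseudoLikelihood",
    "pseudo_log_likelihood",
    "fit_outcome",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class SamplingWeights:
    """Inverse-prevalence case-control sampling weights."""

    weights: np.ndarray
    prevalence: float


def sampling_weights(dataset: MediationDataset, prevalence: float) -> SamplingWeights:
    """Weights restoring population representativeness of a case-control draw.

    Cases receive ``pi / p_case`` and controls ``(1 - pi) / (1 - p_case)``
    where ``pi`` is the population disease prevalence and ``p_case`` the
    sample case fraction; the weighted sample then mirrors a population in
    which cases occur at rate ``pi``.
    """
    if dataset.family != "binary":
        raise ValueError("sampling weights require a binary outcome")
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must lie in (0, 1)")
    p_case = float(dataset.outcome.mean())
    if p_case in (0.0, 1.0):
        raise ValueError("both cases and controls must be present")
    w = np.where(
        dataset.outcome == 1.0,
        prevalence / p_case,
        (1.0 - prevalence) / (1.0 - p_case),
    )
    return SamplingWeights(weights=w, prevalence=prevalence)


def _unpack(phi: np.ndarray, k: int, p: int):
    phi = np.asarray(phi, dtype=float)
    if phi.shape[0] != 2 + (k - 1) + p:
        raise ValueError(
            f"phi has length {phi.shape[0]}, expected {2 + (k - 1) + p}"
        )
    return phi[0], phi[1], phi[2 : 1 + k], phi[1 + k :]


def conditional_outcome_mean(
    phi: np.ndarray,
    log_mediator,
    dummy_row: np.ndarray,
    z: np.ndarray | None = None,
    family: str = "continuous",
):
    """E[y | log t, x, z]: the linear predictor, inverse-logit for binary."""
    dummy_row = np.atleast_1d(np.asarray(dummy_row, dtype=float))
    z = np.empty(0) if z is None else np.atleast_1d(np.asarray(z, dtype=float))
    b0, b, c, gamma = _unpack(phi, dummy_row.size + 1, z.size)
    lp = b0 + b * np.asarray(log_mediator, dtype=float) + c @ dummy_row + gamma @ z
    return expit(lp) if family == "binary" else lp


class PseudoLikelihood:
    """Evaluator for PL(phi) with the data-dependent pieces precomputed.

    Censored subjects with identical design rows share the support-point sums
    (binary family), which makes the evaluation O(q) per distinct exposure
    pattern instead of O(n_censored * q).
    """

    def __init__(
        self,
        dataset: MediationDataset,
        design: DummyDesign,
        aft: AFTFit,
        conditional: bool = True,
    ):
        self.family = dataset.family
        self.conditional = conditional
        self.n = dataset.n
        self.k = design.k
        self.p = design.covariates.shape[1]
        eta = aft.residual_dist
        self.support = eta.support
        self.masses = eta.masses
        q = self.support.size

        A = design.matrix
        mu = A @ aft.theta  # A_i^T theta_hat
        X = design.indicators
        Z = design.covariates
        y, w, logm = dataset.outcome, dataset.weights, dataset.log_mediator
        ev = dataset.event == 1

        resid = logm - mu
        idx = np.searchsorted(self.support, resid, side="right")
        tail = np.concatenate([np.cumsum(self.masses[::-1])[::-1], [0.0]])
        P = tail[idx]  # mass of support strictly beyond e_i

        cen = ~ev & (P > 0)
        # censored beyond all support: nearest-point convention at tau
        beyond = ~ev & (P == 0)

        # event-like block: true events at log m, beyond-tau subjects at
        # tau + mu (their mediator value pinned to the largest residual)
        self.e_logt = np.concatenate([logm[ev], eta.tau + mu[beyond]])
        self.e_y = np.concatenate([y[ev], y[beyond]])
        self.e_w = np.concatenate([w[ev], w[beyond]])
        self.e_off = np.concatenate([X[ev], X[beyond]]), np.concatenate(
            [Z[ev], Z[beyond]]
        )

        # censored block
        self.c_y = y[cen]
        self.c_w = w[cen]
        self.c_idx = idx[cen]
        self.c_logP = np.log(P[cen]) if cen.any() else np.zeros(0)
        self.c_mu = mu[cen]
        self.c_X = X[cen]
        self.c_Z = Z[cen]
        if cen.any():
            rows = np.column_stack([mu[cen], X[cen], Z[cen]])
            uniq, inv = np.unique(rows, axis=0, return_inverse=True)
            self.c_group = inv
            self.g_mu = uniq[:, 0]
            self.g_X = uniq[:, 1 : self.k]
            self.g_Z = uniq[:, self.k :]
            # support mask weights for the continuous family
            self.c_pmat = np.where(
                np.arange(q)[None, :] >= self.c_idx[:, None],
                self.masses[None, :],
                0.0,
            )
        else:
            self.c_group = np.zeros(0, dtype=int)
            self.c_pmat = np.zeros((0, q))
        # scratch buffer reused across evaluations (continuous family)
        self._buf = np.empty_like(self.c_pmat)

    # -- linear-predictor helpers ------------------------------------------

    def _offsets(self, c, gamma, X, Z):
        out = X @ c
        if gamma.size:
            out = out + Z @ gamma
        return out

    # -- evaluation --------------------------------------------------------

    def __call__(self, phi: np.ndarray, sigma: float | None = None) -> float:
        b0, b, c, gamma = _unpack(phi, self.k, self.p)
        if self.family == "continuous":
            if sigma is None or sigma <= 0:
                raise ValueError("continuous family requires sigma > 0")
            total = self._continuous(b0, b, c, gamma, sigma)
        else:
            total = self._binary(b0, b, c, gamma)
        return total / self.n

    def _binary(self, b0, b, c, gamma) -> float:
        Xe, Ze = self.e_off
        lp = b0 + b * self.e_logt + self._offsets(c, gamma, Xe, Ze)
        sgn = 2.0 * self.e_y - 1.0
        # log expit(sgn * lp), numerically stable
        ll_e = -np.logaddexp(0.0, -sgn * lp)
        total = float(self.e_w @ ll_e)

        if self.c_y.size:
            const = b0 + b * self.g_mu + self._offsets(c, gamma, self.g_X, self.g_Z)
            pi = expit(b * self.support[None, :] + const[:, None])
            # tail sums T(g, s0) = sum_{s >= s0} pi p_s for y=1 (resp. 1-pi)
            pw = pi * self.masses[None, :]
            cum1 = np.concatenate(
                [np.cumsum(pw[:, ::-1], axis=1)[:, ::-1], np.zeros((pw.shape[0], 1))],
                axis=1,
            )
            tail_all = np.concatenate(
                [np.cumsum(self.masses[::-1])[::-1], [0.0]]
            )
            t1 = cum1[self.c_group, self.c_idx]
            t_all = tail_all[self.c_idx]
            t = np.where(self.c_y == 1.0, t1, t_all - t1)
            if np.any(t <= 0):
                return -np.inf
            ll_c = np.log(t)
            if self.conditional:
                ll_c = ll_c - self.c_logP
            total += float(self.c_w @ ll_c)
        return total

    def _continuous(self, b0, b, c, gamma, sigma) -> float:
        s2 = sigma * sigma
        norm_const = -0.5 * (_LOG_2PI + np.log(s2))
        Xe, Ze = self.e_off
        r = self.e_y - (b0 + b * self.e_logt + self._offsets(c, gamma, Xe, Ze))
        total = float(self.e_w @ (norm_const - r * r / (2.0 * s2)))

        if self.c_y.size:
            rc = self.c_y - (
                b0 + b * self.c_mu + self._offsets(c, gamma, self.c_X, self.c_Z)
            )
            # in-place pipeline over one preallocated (n_cens, q) buffer:
            # buf = p_s * exp(-(r_i - b e_s)^2 / (2 sigma^2))
            buf = self._buf
            np.subtract(rc[:, None], (b * self.support)[None, :], out=buf)
            np.multiply(buf, buf, out=buf)
            buf *= -1.0 / (2.0 * s2)
            np.exp(buf, out=buf)
            buf *= self.c_pmat
            t = buf.sum(axis=1)
            if np.any(t <= 0.0):
                # rescue underflowing rows with a shifted (log-sum-exp) pass
                bad = np.flatnonzero(t <= 0.0)
                d = rc[bad, None] - b * self.support[None, :]
                expo = -(d * d) / (2.0 * s2)
                masked = np.where(self.c_pmat[bad] > 0, expo, -np.inf)
                mx = masked.max(axis=1)
                shifted = np.einsum(
                    "ij,ij->i", self.c_pmat[bad], np.exp(expo - mx[:, None])
                )
                ll_c = np.empty(t.shape)
                pos = t > 0.0
                ll_c[pos] = np.log(t[pos])
                ll_c[bad] = mx + np.log(shifted)
            else:
                ll_c = np.log(t)
            ll_c = ll_c + norm_const
            if self.conditional:
                ll_c = ll_c - self.c_logP
            total += float(self.c_w @ ll_c)
        return total


def pseudo_log_likelihood(
    phi: np.ndarray,
    dataset: MediationDataset,
    design: DummyDesign,
    aft: AFTFit,
    sigma: float | None = None,
    conditional: bool = True,
) -> float:
    """PL(phi): the weighted mean log-pseudo-likelihood (one-shot wrapper)."""
    return PseudoLikelihood(dataset, design, aft, conditional=conditional)(
        phi, sigma=sigma
    )


@dataclass
class OutcomeFit:
    """Stage-2 fit phi_hat with optimizer diagnostics."""

    phi: np.ndarray
    coef_names: list[str]
    family: str
    sigma: float | None
    log_pseudo_likelihood: float
    converged: bool
    n_iter: int

    @property
    def b(self) -> float:
        """Mediator (log-scale) coefficient."""
        return float(self.phi[1])

    def coef(self, name: str) -> float:
        return float(self.phi[self.coef_names.index(name)])

    def summary(self) -> dict:
        out = {name: float(v) for name, v in zip(self.coef_names, self.phi)}
        if self.sigma is not None:
            out["sigma"] = float(self.sigma)
        return out


def _complete_case_init(dataset: MediationDataset, design: DummyDesign):
    """Weighted regression of y on (log m, X, z) over the uncensored rows."""
    import statsmodels.api as sm

    ev = dataset.event == 1
    M = np.column_stack(
        [
            np.ones(int(ev.sum())),
            dataset.log_mediator[ev],
            design.indicators[ev],
            design.covariates[ev],
        ]
    )
    y = dataset.outcome[ev]
    w = dataset.weights[ev]
    dim = M.shape[1]
    try:
        if dataset.family == "continuous":
            res = sm.WLS(y, M, weights=w).fit()
            resid = y - M @ res.params
            sigma = float(np.sqrt(np.average(resid**2, weights=w)))
            return np.asarray(res.params), max(sigma, 1e-3)
        res = sm.GLM(y, M, family=sm.families.Binomial(), var_weights=w).fit()
        beta = np.asarray(res.params)
        if not np.all(np.isfinite(beta)):
            raise ValueError("non-finite init")
        return beta, None
    except Exception:
        return np.zeros(dim), 1.0 if dataset.family == "continuous" else None


def fit_outcome(
    dataset: MediationDataset,
    design: DummyDesign,
    aft: AFTFit,
    conditional: bool = True,
    init: np.ndarray | None = None,
    sigma_init: float | None = None,
    xatol: float = 1e-6,
    fatol: float = 1e-6,
    maxiter: int | None = None,
) -> OutcomeFit:
    """Maximize PL(phi) by Nelder-Mead.

    Default starting values come from the complete-case weighted regression;
    the continuous family appends log(sigma) to the search vector.
    """
    pl = PseudoLikelihood(dataset, design, aft, conditional=conditional)
    continuous = dataset.family == "continuous"
    if init is None:
        init, s0 = _complete_case_init(dataset, design)
        if sigma_init is None:
            sigma_init = s0
    elif continuous and sigma_init is None:
        sigma_init = 1.0
    init = np.asarray(init, dtype=float)

    if continuous:
        x0 = np.concatenate([init, [np.log(sigma_init)]])

        def nll(x):
            val = pl(x[:-1], sigma=float(np.exp(x[-1])))
            return -val if np.isfinite(val) else np.inf

    else:
        x0 = init

        def nll(x):
            val = pl(x)
            return -val if np.isfinite(val) else np.inf

    if not np.isfinite(nll(x0)):
        raise ValueError("pseudo-likelihood not finite at the starting values")
    dim = x0.size
    res = minimize(
        nll,
        x0,
        method="Nelder-Mead",
        options={
            "xatol": xatol,
            "fatol": fatol,
            "maxiter": maxiter if maxiter is not None else 2000 * dim,
            "maxfev": maxiter if maxiter is not None else 2000 * dim,
        },
    )
    x = res.x
    phi = x[:-1] if continuous else x
    sigma = float(np.exp(x[-1])) if continuous else None
    names = ["b0", "b"] + [f"c[{c}]" for c in design.categories[1:]]
    names += [f"z{j + 1}" for j in range(design.covariates.shape[1])]
    return OutcomeFit(
        phi=np.asarray(phi),
        coef_names=names,
        family=dataset.family,
        sigma=sigma,
        log_pseudo_likelihood=float(-res.fun),
        converged=bool(res.success),
        n_iter=int(res.nit),
    )
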