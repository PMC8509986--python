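"""Stage 1: semiparametric AFT fit of the censored mediator.

The mediator follows an accelerated failure time model
``log t_i = A_i^T theta + eps_i`` with i.i.d. errors of unspecified
distribution.  Coefficients are estimated by inverse-probability-of-censoring
weighted least squares with the closed form

    theta_hat = [sum_i delta_i w_i A_i A_i^T / G(m_i-)]^{-1}
                [sum_i delta_i w_i A_i log(m_i) / G(m_i-)]

where ``G`` is the Kaplan-Meier survival estimate of the censoring process
and ``w_i`` are optional sampling weights (case-control designs).  The error
distribution ``eta_hat`` is the Kaplan-Meier estimate on the residuals
``e_i = log m_i - A_i^T theta_hat``, truncated at the largest event residual
``tau`` and renormalized to a proper distribution.

The product-limit routine is implemented here because the pipeline needs
sampling-weighted risk sets, an explicit events-before-censorings tie rule,
and left-limit evaluation ``G(t-)``; it is cross-validated against lifelines
in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data import DummyDesign, MediationDataset

__all__ = [
    "StepSurvival",
    "ResidualDistribution",
    "AFTFit",
    "product_limit",
    "censoring_km",
    "fit_aft_wls",
    "residual_distribution",
    "fit_aft",
]

# IPCW guard: weights are capped at G >= G_MIN
G_MIN = 1e-8


@dataclass
class StepSurvival:
    """Right-continuous Kaplan-Meier survival step function.

    ``times`` are the drop points (distinct times with positive event mass)
    and ``surv`` the survival values immediately after each drop.
    """

    times: np.ndarray
    surv: np.ndarray

    def _eval(self, t, side: str):
        t = np.asarray(t, dtype=float)
        if self.times.size == 0:
            out = np.ones_like(t)
            return out if out.ndim else 1.0
        idx = np.searchsorted(self.times, t, side=side)
        out = np.where(idx == 0, 1.0, self.surv[np.maximum(idx - 1, 0)])
        return out if out.ndim else float(out)

    def __call__(self, t) -> np.ndarray:
        """S(t), right-continuous."""
        return self._eval(t, "right")

    def left_limit(self, t) -> np.ndarray:
        """S(t-): survival just before ``t``."""
        return self._eval(t, "left")

    @property
    def jumps(self) -> np.ndarray:
        """Probability mass dropped at each time: S(t-) - S(t)."""
        before = np.concatenate([[1.0], self.surv[:-1]])
        return before - self.surv


def product_limit(
    times: np.ndarray,
    events: np.ndarray,
    weights: np.ndarray | None = None,
    competing_precede: bool = False,
) -> StepSurvival:
    """Weighted Kaplan-Meier product-limit estimate.

    ``events`` flags the terminal event of interest; the complement is
    treated as independent censoring of that process.  With
    ``competing_precede=True``, tied competing observations leave the risk
    set *before* events at the same time — used for the censoring-process KM,
    where the convention is that true mediator events precede censorings at
    ties.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=float)
    if weights is None:
        weights = np.ones_like(times)
    else:
        weights = np.asarray(weights, dtype=float)
    uniq, inv = np.unique(times, return_inverse=True)
    d = np.bincount(inv, weights=weights * events, minlength=uniq.size)
    c = np.bincount(inv, weights=weights * (1.0 - events), minlength=uniq.size)
    total = d + c
    at_risk = total[::-1].cumsum()[::-1]
    if competing_precede:
        at_risk = at_risk - c
    frac = np.ones_like(d)
    pos = at_risk > 0
    frac[pos] = 1.0 - d[pos] / at_risk[pos]
    surv = np.cumprod(frac)
    drop = d > 0
    return StepSurvival(times=uniq[drop], surv=surv[drop])


@dataclass
class ResidualDistribution:
    """Discrete AFT error distribution eta_hat on the event residuals.

    ``support`` holds the distinct event residuals in increasing order and
    ``masses`` the Kaplan-Meier jumps renormalized to sum to one over the
    support truncated at ``tau = support[-1]`` (mass that the KM leaves
    beyond the largest event residual is redistributed proportionally).
    """

    support: np.ndarray
    masses: np.ndarray

    def __post_init__(self) -> None:
        if self.support.size == 0:
            raise ValueError("residual distribution needs at least one event residual")
        if not np.all(np.diff(self.support) > 0):
            raise ValueError("support must be strictly increasing")
        if abs(self.masses.sum() - 1.0) > 1e-10:
            raise ValueError("masses must sum to 1")

    @property
    def tau(self) -> float:
        """Largest observed event residual (upper truncation point)."""
        return float(self.support[-1])

    def tail_mass(self, e) -> np.ndarray:
        """P(support > e) under eta_hat."""
        idx = np.searchsorted(self.support, e, side="right")
        rev = np.concatenate([np.cumsum(self.masses[::-1])[::-1], [0.0]])
        return rev[idx]


@dataclass
class AFTFit:
    """Stage-1 fit: coefficients, residuals, and the residual distribution."""

    theta: np.ndarray
    coef_names: list[str]
    residuals: np.ndarray
    event: np.ndarray
    censoring_survival: StepSurvival
    residual_dist: ResidualDistribution

    @property
    def tau(self) -> float:
        return self.residual_dist.tau

    @property
    def intercept(self) -> float:
        """a_0."""
        return float(self.theta[0])

    def coef(self, name: str) -> float:
        return float(self.theta[self.coef_names.index(name)])

    def summary(self) -> dict:
        return {name: float(v) for name, v in zip(self.coef_names, self.theta)}


def censoring_km(dataset: MediationDataset, use_weights: bool = True) -> StepSurvival:
    """Kaplan-Meier estimate G of the censoring survival function.

    Censoring is the event (indicator ``1 - delta``); mediator events are
    the competing observations and precede tied censorings.  With no
    censored rows the estimate is identically one and the downstream WLS
    reduces to ordinary least squares.
    """
    w = dataset.weights if use_weights else None
    return product_limit(
        dataset.mediator_time, 1 - dataset.event, weights=w, competing_precede=True
    )


def _ipcw(dataset: MediationDataset, G: StepSurvival) -> np.ndarray:
    """delta_i * w_i / G(m_i-), with the small-G guard."""
    g = np.asarray(G.left_limit(dataset.mediator_time), dtype=float)
    if np.any(g[dataset.event == 1] < G_MIN):
        warnings.warn(
            "censoring survival below %.0e at some event times; capping" % G_MIN,
            RuntimeWarning,
            stacklevel=3,
        )
    g = np.maximum(g, G_MIN)
    return dataset.event * dataset.weights / g


def fit_aft_wls(
    dataset: MediationDataset, design: DummyDesign, G: StepSurvival
) -> np.ndarray:
    """Closed-form IPCW weighted least squares estimate of theta."""
    A = design.matrix
    omega = _ipcw(dataset, G)
    Aw = A * omega[:, None]
    M = Aw.T @ A
    v = Aw.T @ dataset.log_mediator
    if np.linalg.matrix_rank(M) < M.shape[0]:
        active = A[omega > 0]
        bad = [
            name
            for j, name in enumerate(design.coef_names)
            if j > 0 and np.ptp(active[:, j]) == 0
        ]
        detail = f" (degenerate columns among events: {bad})" if bad else ""
        raise np.linalg.LinAlgError(
            "singular AFT normal equations" + detail
        )
    return np.linalg.solve(M, v)


def residual_distribution(
    dataset: MediationDataset,
    design: DummyDesign,
    theta: np.ndarray,
    use_weights: bool = True,
) -> ResidualDistribution:
    """Kaplan-Meier distribution of the AFT residuals, truncated at tau."""
    resid = dataset.log_mediator - design.matrix @ theta
    w = dataset.weights if use_weights else None
    km = product_limit(resid, dataset.event, weights=w)
    masses = km.jumps
    total = masses.sum()  # < 1 when the largest residual is censored
    return ResidualDistribution(support=km.times, masses=masses / total)


def fit_aft(
    dataset: MediationDataset, design: DummyDesign, use_weights: bool = True
) -> AFTFit:
    """Full stage 1: censoring KM, IPCW-WLS coefficients, residual KM."""
    G = censoring_km(dataset, use_weights=use_weights)
    theta = fit_aft_wls(dataset, design, G)
    eta = residual_distribution(dataset, design, theta, use_weights=use_weights)
    return AFTFit(
        theta=theta,
        coef_names=design.coef_names,
        residuals=dataset.log_mediator - design.matrix @ theta,
        event=dataset.event,
        censoring_survival=G,
        residual_dist=eta,
    )
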