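"""BCa bootstrap confidence intervals for the overall mediation effects.

The bias-corrected and accelerated interval adjusts the bootstrap percentile
interval by a median-bias term ``z0`` and an acceleration term ``a_hat``
(jackknife skewness).  Resampling is of whole subjects with replacement,
stratified by case/control status in binary case-control mode so the design
margins are preserved; both stages and the effect measures are re-estimated
inside every replicate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .data import MediationDataset
from .pipeline import fit_mediation

__all__ = [
    "BootstrapResult",
    "bca_interval",
    "bootstrap_effects",
    "significance_call",
]

_QUANTITIES = ("IE", "DE", "TE", "PM")


def _jackknife_acceleration(jackknife) -> float:
    """a_hat from the standard jackknife skewness formula (0 if unavailable)."""
    if jackknife is None or np.asarray(jackknife).size < 2:
        return 0.0
    u = np.asarray(jackknife, dtype=float)
    u = u[np.isfinite(u)]
    if u.size < 2:
        return 0.0
    d = u.mean() - u
    denom = (d @ d) ** 1.5
    return float((d**3).sum() / (6.0 * denom)) if denom > 0 else 0.0


def bca_interval(
    point: float,
    replicates: np.ndarray,
    jackknife: np.ndarray | None = None,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """BCa interval at level ``1 - alpha`` from bootstrap replicates.

    ``z0`` uses the fraction of replicates below the point estimate (ties
    counted half, proportion clamped to [1/(B+1), B/(B+1)]); ``a_hat`` is the
    jackknife skewness, zero when no jackknife estimates are supplied.
    """
    if not 0.0 < alpha < 0.5:
        raise ValueError("alpha must lie in (0, 0.5)")
    reps = np.asarray(replicates, dtype=float)
    reps = reps[np.isfinite(reps)]
    if reps.size == 0:
        raise ValueError("no finite bootstrap replicates")
    B = reps.size
    if np.ptp(reps) == 0.0:
        return float(reps[0]), float(reps[0])
    prop = (np.sum(reps < point) + 0.5 * np.sum(reps == point)) / B
    if prop <= 0.0 or prop >= 1.0:
        warnings.warn(
            "all bootstrap replicates on one side of the point estimate; "
            "clamping the bias-correction proportion",
            RuntimeWarning,
            stacklevel=2,
        )
        prop = np.clip(prop, 1.0 / (B + 1), B / (B + 1.0))
    z0 = norm.ppf(prop)
    a_hat = _jackknife_acceleration(jackknife)
    out = []
    for za in (norm.ppf(alpha / 2.0), norm.ppf(1.0 - alpha / 2.0)):
        adj = z0 + (z0 + za) / (1.0 - a_hat * (z0 + za))
        out.append(float(np.quantile(reps, norm.cdf(adj), method="linear")))
    return out[0], out[1]


def significance_call(interval: tuple[float, float], null_value: float = 0.0) -> bool:
    """True iff the (closed) interval excludes the null value."""
    lo, hi = interval
    if not lo <= hi:
        raise ValueError("interval lower bound exceeds upper bound")
    return bool(null_value < lo or null_value > hi)


@dataclass
class BootstrapResult:
    """Point estimates, replicate draws, and BCa intervals per quantity."""

    point: dict
    replicates: dict
    intervals: dict
    z0: dict = field(default_factory=dict)
    acceleration: dict = field(default_factory=dict)
    B: int = 0
    seed: int | None = None
    n_failed: int = 0

    def significant(self, quantity: str = "IE", null_value: float = 0.0) -> bool:
        return significance_call(self.intervals[quantity], null_value)

    def summary(self) -> dict:
        return {
            q: {
                "estimate": self.point[q],
                "lower": self.intervals[q][0],
                "upper": self.intervals[q][1],
                "z0": self.z0.get(q),
                "acceleration": self.acceleration.get(q),
            }
            for q in self.point
        }


def _effect_vector(fit) -> dict:
    eff = fit.effects
    return {
        "IE": eff.ie,
        "DE": eff.de,
        "TE": eff.te,
        "PM": eff.pm if eff.pm is not None else np.nan,
    }


def bootstrap_effects(
    dataset: MediationDataset,
    reference: object,
    B: int = 200,
    seed: int | None = None,
    alpha: float = 0.05,
    stratify: bool | None = None,
    acceleration: str = "jackknife",
    max_failure_fraction: float = 0.10,
    warm_start: bool = True,
    **fit_kwargs,
) -> BootstrapResult:
    """Full-pipeline BCa bootstrap of IE, DE, TE and PM.

    ``stratify=None`` auto-selects stratified resampling for a binary
    outcome (preserving the case/control split); ``acceleration`` is
    ``"jackknife"`` (leave-one-out refits, O(n)) or ``"none"`` for the
    faster bias-corrected-only variant with ``a_hat = 0``.  With
    ``warm_start`` the stage-2 optimizer in each resample starts from the
    full-data estimate instead of the complete-case regression.
    """
    if B < 2:
        raise ValueError("B must be at least 2")
    if B < 50:
        warnings.warn("B < 50 is too small for interval construction", RuntimeWarning)
    elif B < 999:
        warnings.warn(
            "B < 999; intervals are application-grade, not simulation-grade",
            RuntimeWarning,
            stacklevel=2,
        )
    if acceleration not in ("jackknife", "none"):
        raise ValueError("acceleration must be 'jackknife' or 'none'")
    rng = np.random.default_rng(seed)
    if stratify is None:
        stratify = dataset.family == "binary"
    n = dataset.n
    if stratify:
        strata = [np.flatnonzero(dataset.outcome == v) for v in (0.0, 1.0)]
        strata = [s for s in strata if s.size]
    else:
        strata = [np.arange(n)]

    point_fit = fit_mediation(dataset, reference, **fit_kwargs)
    point = _effect_vector(point_fit)
    if warm_start and "init" not in fit_kwargs:
        fit_kwargs = dict(
            fit_kwargs,
            init=point_fit.outcome.phi,
            sigma_init=point_fit.outcome.sigma,
        )

    reps = {q: [] for q in _QUANTITIES}
    n_failed = 0
    for _ in range(B):
        idx = np.concatenate(
            [rng.choice(s, size=s.size, replace=True) for s in strata]
        )
        try:
            fit = fit_mediation(dataset.subset(idx), reference, **fit_kwargs)
        except Exception:
            n_failed += 1
            continue
        vec = _effect_vector(fit)
        for q in _QUANTITIES:
            reps[q].append(vec[q])
    if n_failed > max_failure_fraction * B:
        raise RuntimeError(
            f"{n_failed}/{B} bootstrap replicates failed to fit; "
            "data too fragile for interval construction"
        )

    jack = {q: None for q in _QUANTITIES}
    if acceleration == "jackknife":
        jvals = {q: [] for q in _QUANTITIES}
        for i in range(n):
            idx = np.delete(np.arange(n), i)
            try:
                fit = fit_mediation(dataset.subset(idx), reference, **fit_kwargs)
            except Exception:
                continue
            vec = _effect_vector(fit)
            for q in _QUANTITIES:
                jvals[q].append(vec[q])
        jack = {q: np.asarray(v) for q, v in jvals.items()}

    intervals, z0s, accels = {}, {}, {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for q in _QUANTITIES:
            arr = np.asarray(reps[q], dtype=float)
            if np.isnan(point[q]) or not np.isfinite(arr).any():
                intervals[q] = (np.nan, np.nan)
                z0s[q] = np.nan
                accels[q] = np.nan
                continue
            intervals[q] = bca_interval(point[q], arr, jack[q], alpha=alpha)
            finite = arr[np.isfinite(arr)]
            prop = (
                np.sum(finite < point[q]) + 0.5 * np.sum(finite == point[q])
            ) / finite.size
            z0s[q] = float(norm.ppf(np.clip(prop, 1 / (B + 1), B / (B + 1))))
            accels[q] = _jackknife_acceleration(jack[q])
    return BootstrapResult(
        point=point,
        replicates={q: np.asarray(v) for q, v in reps.items()},
        intervals=intervals,
        z0=z0s,
        acceleration=accels,
        B=B,
        seed=seed,
        n_failed=n_failed,
    )
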