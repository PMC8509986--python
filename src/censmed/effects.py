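"""Counterfactual mediation effects and their frequency-weighted overall forms.

For each non-reference exposure category ``d_j`` the natural indirect and
direct effects versus the reference are computed by averaging the outcome
mean over the mediator error distribution ``eta`` (the stage-1 residual
distribution for estimates, the standard normal for theoretical values):

    IE_j = sum_s p_s g(b0 + b(e_s + a0 + a_j + gt'z) + c_j + g'z)
         - sum_s p_s g(b0 + b(e_s + a0       + gt'z) + c_j + g'z)
    DE_j = sum_s p_s g(b0 + b(e_s + a0 + gt'z) + c_j + g'z)
         - sum_s p_s g(b0 + b(e_s + a0 + gt'z)       + g'z)

with ``g`` the identity (continuous outcome) or the inverse logit (binary
outcome).  In the continuous family the sums cancel algebraically, leaving
``IE_j = b a_j`` and ``DE_j = c_j`` regardless of ``eta``.

The overall effects weight the per-category effects by the exposure-category
frequencies ``f_j`` (by default renormalized to sum to one over the
non-reference categories):  ``IE = sum_j f_j IE_j``, ``DE = sum_j f_j DE_j``,
``TE = IE + DE`` and ``PM = IE / TE``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .aft import AFTFit
from .data import CategoryFrequencies, DummyDesign, MediationDataset
from .outcome import OutcomeFit

__all__ = [
    "EffectEstimates",
    "ie_category",
    "de_category",
    "overall_effects",
    "estimate_effects",
    "theoretical_effects",
]

_TE_EPS = 1e-10


@dataclass
class EffectEstimates:
    """Per-category and overall mediation effects.

    ``pm`` is ``None`` when the total effect is numerically zero.
    """

    categories: tuple
    ie_by_category: np.ndarray
    de_by_category: np.ndarray
    frequency_weights: np.ndarray
    ie: float
    de: float
    te: float
    pm: float | None
    z_star: np.ndarray = field(default_factory=lambda: np.empty(0))

    def summary(self) -> dict:
        out = {"IE": self.ie, "DE": self.de, "TE": self.te, "PM": self.pm}
        for c, ie_j, de_j in zip(
            self.categories, self.ie_by_category, self.de_by_category
        ):
            out[f"IE[{c} vs ref]"] = float(ie_j)
            out[f"DE[{c} vs ref]"] = float(de_j)
        return out


def _mixture_mean(eta_support, eta_masses, alpha, b, family):
    """sum_s p_s g(alpha + b e_s)."""
    vals = alpha + b * eta_support
    if family == "binary":
        vals = expit(vals)
    return float(eta_masses @ vals)


def _split_params(theta, phi, k, p):
    a0 = float(theta[0])
    a = np.asarray(theta[1:k], dtype=float)
    gamma_t = np.asarray(theta[k:], dtype=float)
    b0 = float(phi[0])
    b = float(phi[1])
    c = np.asarray(phi[2 : 1 + k], dtype=float)
    gamma = np.asarray(phi[1 + k :], dtype=float)
    assert gamma_t.size == p and gamma.size == p
    return a0, a, gamma_t, b0, b, c, gamma


def _category_effects(
    theta, phi, eta_support, eta_masses, k, family, z_star
):
    """(IE_j, DE_j) for j = 1..k-1 over a discrete error distribution."""
    p = np.asarray(z_star).size
    a0, a, gamma_t, b0, b, c, gamma = _split_params(theta, phi, k, p)
    zt = float(gamma_t @ z_star) if p else 0.0
    zo = float(gamma @ z_star) if p else 0.0
    if family == "continuous":
        # exact cancellation of the error distribution
        return b * a, c.copy()
    ie = np.empty(k - 1)
    de = np.empty(k - 1)
    base = _mixture_mean(eta_support, eta_masses, b0 + b * (a0 + zt) + zo, b, family)
    for j in range(k - 1):
        shifted = _mixture_mean(
            eta_support, eta_masses, b0 + b * (a0 + a[j] + zt) + c[j] + zo, b, family
        )
        natural = _mixture_mean(
            eta_support, eta_masses, b0 + b * (a0 + zt) + c[j] + zo, b, family
        )
        ie[j] = shifted - natural
        de[j] = natural - base
    return ie, de


def ie_category(
    j: int,
    aft: AFTFit,
    outcome: OutcomeFit,
    design: DummyDesign,
    z_star: np.ndarray | None = None,
) -> float:
    """Natural indirect effect of category j (1-based) versus the reference."""
    z_star = _default_profile(design, z_star)
    ie, _ = _category_effects(
        aft.theta,
        outcome.phi,
        aft.residual_dist.support,
        aft.residual_dist.masses,
        design.k,
        outcome.family,
        z_star,
    )
    return float(ie[j - 1])


def de_category(
    j: int,
    aft: AFTFit,
    outcome: OutcomeFit,
    design: DummyDesign,
    z_star: np.ndarray | None = None,
) -> float:
    """Natural direct effect of category j (1-based) versus the reference."""
    z_star = _default_profile(design, z_star)
    _, de = _category_effects(
        aft.theta,
        outcome.phi,
        aft.residual_dist.support,
        aft.residual_dist.masses,
        design.k,
        outcome.family,
        z_star,
    )
    return float(de[j - 1])


def overall_effects(
    ie_by_category: np.ndarray,
    de_by_category: np.ndarray,
    freqs: CategoryFrequencies,
    normalize: bool = True,
    z_star: np.ndarray | None = None,
) -> EffectEstimates:
    """Frequency-weighted overall IE, DE, TE and PM."""
    f = freqs.weights(normalize=normalize)
    ie_by_category = np.asarray(ie_by_category, dtype=float)
    de_by_category = np.asarray(de_by_category, dtype=float)
    if f.shape != ie_by_category.shape or f.shape != de_by_category.shape:
        raise ValueError("one weight per non-reference category required")
    ie = float(f @ ie_by_category)
    de = float(f @ de_by_category)
    te = ie + de
    pm = ie / te if abs(te) > _TE_EPS else None
    return EffectEstimates(
        categories=freqs.categories[1:],
        ie_by_category=ie_by_category,
        de_by_category=de_by_category,
        frequency_weights=f,
        ie=ie,
        de=de,
        te=te,
        pm=pm,
        z_star=np.empty(0) if z_star is None else np.asarray(z_star, dtype=float),
    )


def _default_profile(design: DummyDesign, z_star, dataset: MediationDataset | None = None):
    if z_star is not None:
        return np.atleast_1d(np.asarray(z_star, dtype=float))
    p = design.covariates.shape[1]
    if p == 0:
        return np.empty(0)
    if dataset is not None:
        return np.average(dataset.covariates, axis=0, weights=dataset.weights)
    return np.average(design.covariates, axis=0)


def estimate_effects(
    dataset: MediationDataset,
    design: DummyDesign,
    aft: AFTFit,
    outcome: OutcomeFit,
    freqs: CategoryFrequencies,
    z_star: np.ndarray | None = None,
    normalize: bool = True,
) -> EffectEstimates:
    """Overall effects from fitted stage-1/stage-2 models.

    Effects are conditional on the covariate profile ``z_star`` (default:
    the sampling-weighted covariate mean).
    """
    z_star = _default_profile(design, z_star, dataset)
    ie, de = _category_effects(
        aft.theta,
        outcome.phi,
        aft.residual_dist.support,
        aft.residual_dist.masses,
        design.k,
        outcome.family,
        z_star,
    )
    out = overall_effects(ie, de, freqs, normalize=normalize, z_star=z_star)
    return out


def theoretical_effects(
    a0: float,
    a: np.ndarray,
    b0: float,
    b: float,
    c: np.ndarray,
    freqs: CategoryFrequencies,
    family: str,
    gamma: np.ndarray | None = None,
    gamma_t: np.ndarray | None = None,
    z_star: np.ndarray | None = None,
    normalize: bool = True,
    n_nodes: int = 40,
) -> EffectEstimates:
    """Theoretical effects under known generating parameters and N(0,1) errors.

    The continuous family is closed form (``IE_j = b a_j``, ``DE_j = c_j``);
    the binary family integrates the logistic outcome probability over the
    standard-normal mediator error by Gauss-Hermite quadrature.
    """
    a = np.atleast_1d(np.asarray(a, dtype=float))
    c = np.atleast_1d(np.asarray(c, dtype=float))
    k = a.size + 1
    z_star = np.empty(0) if z_star is None else np.atleast_1d(np.asarray(z_star))
    gamma = np.zeros(z_star.size) if gamma is None else np.atleast_1d(gamma)
    gamma_t = np.zeros(z_star.size) if gamma_t is None else np.atleast_1d(gamma_t)
    theta = np.concatenate([[a0], a, gamma_t])
    phi = np.concatenate([[b0, b], c, gamma])
    # Gauss-Hermite nodes for the N(0,1) error: int f(e) dPhi(e)
    nodes, wts = np.polynomial.hermite.hermgauss(n_nodes)
    support = np.sqrt(2.0) * nodes
    masses = wts / np.sqrt(np.pi)
    order = np.argsort(support)
    ie, de = _category_effects(
        theta, phi, support[order], masses[order], k, family, z_star
    )
    return overall_effects(ie, de, freqs, normalize=normalize, z_star=z_star)
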