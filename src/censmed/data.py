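"""Subject-level data container, dummy coding, and category frequencies.

A mediation dataset holds, per subject, an outcome ``y`` (continuous or
binary), an observed mediator time ``m = min(t, c)`` with event indicator
``delta = 1{t <= c}`` (``delta = 0`` means the mediator is right-censored),
a categorical exposure (e.g. an additive-coded SNP genotype), optional
covariates and optional sampling weights.

The categorical exposure with ``k`` levels is represented by ``k - 1``
indicator (dummy) variables against a reference level; overall mediation
effects combine per-category effects using the population frequencies of the
non-reference levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MediationDataset",
    "DummyDesign",
    "CategoryFrequencies",
    "encode_dummies",
    "hwe_frequencies",
    "category_frequencies",
]

GENOTYPE_LABELS = ("rr", "Rr", "RR")


@dataclass
class MediationDataset:
    """Per-subject observations for a censored-mediator mediation model.

    Parameters
    ----------
    outcome : array of float
        ``y_i``; for the binary family values must lie in {0, 1}.
    mediator_time : array of float
        Observed mediator ``m_i = min(t_i, c_i)``, strictly positive.
    event : array of int
        ``delta_i``: 1 if the mediator event was observed, 0 if censored.
    exposure : array-like of hashable labels
        Exposure category per subject (``k >= 2`` distinct labels).
    covariates : 2-D array, optional
        Additional covariates ``z_i`` (n x p); empty by default.
    weights : array of float, optional
        Sampling weights ``w_i > 0``; default all one.
    family : {"continuous", "binary"}
        Outcome family.
    """

    outcome: np.ndarray
    mediator_time: np.ndarray
    event: np.ndarray
    exposure: np.ndarray
    covariates: np.ndarray | None = None
    weights: np.ndarray | None = None
    family: str = "continuous"

    def __post_init__(self) -> None:
        self.outcome = np.asarray(self.outcome, dtype=float)
        self.mediator_time = np.asarray(self.mediator_time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        self.exposure = np.asarray(self.exposure)
        n = self.outcome.shape[0]
        if self.covariates is None:
            self.covariates = np.empty((n, 0))
        else:
            self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
            if self.covariates.shape[0] != n:
                self.covariates = self.covariates.T
        if self.weights is None:
            self.weights = np.ones(n)
        else:
            self.weights = np.asarray(self.weights, dtype=float)
        for name, arr in (
            ("mediator_time", self.mediator_time),
            ("event", self.event),
            ("exposure", self.exposure),
            ("weights", self.weights),
        ):
            if arr.shape[0] != n:
                raise ValueError(f"{name} has length {arr.shape[0]}, expected {n}")
        if self.family not in ("continuous", "binary"):
            raise ValueError(f"unknown outcome family {self.family!r}")
        if not np.all(self.mediator_time > 0):
            bad = int(np.argmin(self.mediator_time > 0))
            raise ValueError(f"mediator time must be positive (row {bad})")
        if not np.isin(self.event, (0, 1)).all():
            raise ValueError("event indicator must be 0 or 1")
        if self.event.sum() == 0:
            raise ValueError("no uncensored mediator observations")
        if self.family == "binary" and not np.isin(self.outcome, (0.0, 1.0)).all():
            raise ValueError("binary outcome must be coded 0/1")
        if not np.all(self.weights > 0):
            raise ValueError("sampling weights must be positive")
        if not (np.isfinite(self.outcome).all() and np.isfinite(self.mediator_time).all()
                and np.isfinite(self.covariates).all() and np.isfinite(self.weights).all()):
            raise ValueError("non-finite values in dataset")

    @property
    def n(self) -> int:
        return self.outcome.shape[0]

    @property
    def n_covariates(self) -> int:
        return self.covariates.shape[1]

    @property
    def log_mediator(self) -> np.ndarray:
        return np.log(self.mediator_time)

    @property
    def censoring_fraction(self) -> float:
        return float(1.0 - self.event.mean())

    def subset(self, idx: np.ndarray) -> "MediationDataset":
        """Row subset / resample (used by the bootstrap)."""
        return MediationDataset(
            outcome=self.outcome[idx],
            mediator_time=self.mediator_time[idx],
            event=self.event[idx],
            exposure=self.exposure[idx],
            covariates=self.covariates[idx],
            weights=self.weights[idx],
            family=self.family,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "outcome": self.outcome,
                "mediator_time": self.mediator_time,
                "event": self.event,
                "exposure": self.exposure,
                "weight": self.weights,
            }
        )
        for j in range(self.n_covariates):
            df[f"z{j + 1}"] = self.covariates[:, j]
        return df


@dataclass
class DummyDesign:
    """Dummy coding of a k-level exposure: reference first, then k-1 indicators.

    ``indicators[i, j] = 1`` iff subject i is in category ``categories[j + 1]``.
    The per-subject design row is ``A_i = (1, x_1i, ..., x_(k-1)i, z_i^T)``.
    """

    categories: tuple
    indicators: np.ndarray
    covariates: np.ndarray

    @property
    def k(self) -> int:
        return len(self.categories)

    @property
    def reference(self):
        return self.categories[0]

    @property
    def matrix(self) -> np.ndarray:
        """Full design matrix A (n x (1 + (k-1) + p))."""
        n = self.indicators.shape[0]
        return np.column_stack([np.ones(n), self.indicators, self.covariates])

    @property
    def coef_names(self) -> list[str]:
        names = ["(intercept)"] + [f"x[{c}]" for c in self.categories[1:]]
        names += [f"z{j + 1}" for j in range(self.covariates.shape[1])]
        return names

    def decode(self) -> np.ndarray:
        """Recover the category label of every subject from the indicators."""
        idx = np.zeros(self.indicators.shape[0], dtype=int)
        for j in range(self.k - 1):
            idx[self.indicators[:, j] == 1] = j + 1
        return np.asarray(self.categories, dtype=object)[idx]


@dataclass
class CategoryFrequencies:
    """Exposure-category frequencies and the derived effect weights.

    ``raw`` sums to one over all k categories (reference included).  The
    weights used to combine per-category effects are the raw frequencies of
    the non-reference categories renormalized to sum to one; raw (Eq-style,
    unnormalized) weighting is available via ``weights(normalize=False)``.
    """

    categories: tuple
    raw: np.ndarray
    source: str = "estimated-from-data"

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        if self.raw.shape[0] != len(self.categories):
            raise ValueError("one raw frequency per category required")
        if np.any(self.raw < 0):
            raise ValueError("frequencies must be non-negative")
        if abs(self.raw.sum() - 1.0) > 1e-12:
            raise ValueError("raw frequencies must sum to 1")

    def weights(self, normalize: bool = True) -> np.ndarray:
        """Effect weights f_j over the k-1 non-reference categories."""
        non_ref = self.raw[1:]
        if normalize:
            total = non_ref.sum()
            if total <= 0:
                raise ValueError("all non-reference categories have zero frequency")
            return non_ref / total
        return non_ref.copy()


def encode_dummies(
    dataset: MediationDataset,
    reference: object,
    order: Sequence | None = None,
) -> DummyDesign:
    """Dummy-code the exposure with ``reference`` as the baseline category.

    Category order is deterministic: reference first, then ``order`` if given,
    else the remaining observed labels sorted lexicographically.
    """
    observed = set(dataset.exposure.tolist())
    if reference not in observed:
        raise ValueError(f"reference category {reference!r} not present in data")
    if order is not None:
        rest = [c for c in order if c != reference]
        if set(rest) | {reference} != observed:
            raise ValueError("order must list every observed category exactly once")
    else:
        rest = sorted(observed - {reference}, key=str)
    categories = (reference, *rest)
    if len(categories) < 2:
        raise ValueError("exposure must have at least 2 categories")
    indicators = np.column_stack(
        [(dataset.exposure == c).astype(float) for c in categories[1:]]
    )
    return DummyDesign(categories=categories, indicators=indicators,
                       covariates=dataset.covariates)


def hwe_frequencies(maf: float, labels: Sequence = GENOTYPE_LABELS) -> CategoryFrequencies:
    """Hardy-Weinberg genotype frequencies ((1-p)^2, 2p(1-p), p^2) at MAF ``p``.

    Ordered (rr, Rr, RR) with the common homozygote rr as reference.
    """
    if not 0.0 < maf < 1.0:
        raise ValueError("minor allele frequency must lie in (0, 1)")
    p = float(maf)
    raw = np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
    return CategoryFrequencies(categories=tuple(labels), raw=raw, source="external")


def category_frequencies(
    dataset: MediationDataset,
    design: DummyDesign,
    external: Mapping | pd.Series | None = None,
    use_weights: bool = True,
) -> CategoryFrequencies:
    """Category frequencies in the design's category order.

    By default frequencies are (sampling-weighted) sample proportions, so that
    case-control samples weight back to the source population; ``external``
    supplies a frequency table verbatim instead (categories -> frequency).
    """
    if external is not None:
        try:
            raw = np.array([float(external[c]) for c in design.categories])
        except KeyError as exc:
            raise ValueError(f"external table missing category {exc.args[0]!r}") from None
        raw = raw / raw.sum()
        return CategoryFrequencies(design.categories, raw, source="external")
    w = dataset.weights if use_weights else np.ones(dataset.n)
    raw = np.array(
        [w[dataset.exposure == c].sum() for c in design.categories]
    )
    if raw[1:].sum() <= 0:
        raise ValueError("all non-reference categories empty; supply external frequencies")
    if np.any(raw == 0):
        empty = [c for c, r in zip(design.categories, raw) if r == 0]
        raise ValueError(
            f"categories {empty} have no subjects; supply external frequencies"
        )
    raw = raw / raw.sum()
    return CategoryFrequencies(design.categories, raw, source="estimated-from-data")
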