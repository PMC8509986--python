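"""End-to-end two-stage fit: dummy coding, stage 1, stage 2, overall effects."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .aft import AFTFit, fit_aft
from .data import (
    CategoryFrequencies,
    DummyDesign,
    MediationDataset,
    category_frequencies,
    encode_dummies,
)
from .effects import EffectEstimates, estimate_effects
from .outcome import OutcomeFit, fit_outcome, sampling_weights

__all__ = ["MediationFit", "fit_mediation"]


@dataclass
class MediationFit:
    """Bundle of everything produced by one run of the two-stage pipeline."""

    dataset: MediationDataset
    design: DummyDesign
    frequencies: CategoryFrequencies
    aft: AFTFit
    outcome: OutcomeFit
    effects: EffectEstimates

    def summary(self) -> dict:
        out = {"stage1": self.aft.summary(), "stage2": self.outcome.summary()}
        out["effects"] = self.effects.summary()
        out["frequencies"] = {
            str(c): float(f)
            for c, f in zip(self.frequencies.categories, self.frequencies.raw)
        }
        return out


def fit_mediation(
    dataset: MediationDataset,
    reference: object,
    order: Sequence | None = None,
    prevalence: float | None = None,
    external_frequencies: Mapping | None = None,
    use_weights: bool = True,
    conditional: bool = True,
    normalize: bool = True,
    z_star: np.ndarray | None = None,
    **fit_options,
) -> MediationFit:
    """Run both estimation stages and the overall effect measures.

    ``prevalence`` switches on case-control mode for a binary outcome:
    inverse-prevalence sampling weights are attached before fitting.  When
    the dataset already carries weights (e.g. from the simulator) they are
    used as-is unless ``prevalence`` is given.
    """
    if prevalence is not None:
        sw = sampling_weights(dataset, prevalence)
        dataset = MediationDataset(
            outcome=dataset.outcome,
            mediator_time=dataset.mediator_time,
            event=dataset.event,
            exposure=dataset.exposure,
            covariates=dataset.covariates,
            weights=sw.weights,
            family=dataset.family,
        )
    design = encode_dummies(dataset, reference, order=order)
    freqs = category_frequencies(
        dataset, design, external=external_frequencies, use_weights=use_weights
    )
    aft = fit_aft(dataset, design, use_weights=use_weights)
    outcome = fit_outcome(dataset, design, aft, conditional=conditional, **fit_options)
    effects = estimate_effects(
        dataset, design, aft, outcome, freqs, z_star=z_star, normalize=normalize
    )
    return MediationFit(
        dataset=dataset,
        design=design,
        frequencies=freqs,
        aft=aft,
        outcome=outcome,
        effects=effects,
    )
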