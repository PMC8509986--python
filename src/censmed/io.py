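"""Dataset readers/writers, run configuration, and result serialization.

Plain CSV (UTF-8, '.' decimal) is the single data interchange format; results
are written as JSON.  Column roles are assigned through a ``ColumnMapping``
or equivalent CLI flags; missing values are rejected rather than imputed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import MediationDataset

log = logging.getLogger("censmed")

__all__ = [
    "ColumnMapping",
    "RunConfig",
    "read_dataset",
    "write_dataset",
    "read_frequency_table",
    "write_json",
]


@dataclass
class ColumnMapping:
    """Column-to-role assignment for a subject-level CSV."""

    outcome: str = "outcome"
    mediator: str = "mediator_time"
    event: str = "event"
    exposure: str = "exposure"
    covariates: list[str] = field(default_factory=list)
    weight: str | None = None


@dataclass
class RunConfig:
    """Everything needed to reproduce a command-line run."""

    data: str
    mapping: ColumnMapping = field(default_factory=ColumnMapping)
    family: str = "continuous"
    reference: object = None
    prevalence: float | None = None
    frequency_table: str | None = None
    bootstrap: int = 200
    alpha: float = 0.05
    seed: int | None = None
    stratified: bool | None = None
    output: str = "."

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        mapping = ColumnMapping(**raw.pop("mapping", {}))
        return cls(mapping=mapping, **raw)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        return out


def read_dataset(
    path: str | Path,
    mapping: ColumnMapping | None = None,
    family: str = "continuous",
) -> MediationDataset:
    """Read and validate a subject-level CSV into a :class:`MediationDataset`."""
    mapping = mapping or ColumnMapping()
    df = pd.read_csv(path, float_precision="round_trip")
    required = [mapping.outcome, mapping.mediator, mapping.event, mapping.exposure]
    required += mapping.covariates
    if mapping.weight:
        required.append(mapping.weight)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    sub = df[required]
    if sub.isna().any().any():
        rows = sub.index[sub.isna().any(axis=1)].tolist()[:5]
        raise ValueError(f"{path}: missing values (first rows: {rows})")
    med = pd.to_numeric(df[mapping.mediator], errors="raise")
    nonpos = df.index[med <= 0].tolist()
    if nonpos:
        raise ValueError(f"{path}: non-positive mediator time at row {nonpos[0]}")
    ds = MediationDataset(
        outcome=df[mapping.outcome].to_numpy(dtype=float),
        mediator_time=med.to_numpy(dtype=float),
        event=df[mapping.event].to_numpy(),
        exposure=df[mapping.exposure].to_numpy(),
        covariates=df[mapping.covariates].to_numpy(dtype=float)
        if mapping.covariates
        else None,
        weights=df[mapping.weight].to_numpy(dtype=float) if mapping.weight else None,
        family=family,
    )
    counts = pd.Series(ds.exposure).value_counts().to_dict()
    log.info(
        "read %s: n=%d, censoring=%.1f%%, categories=%s",
        path,
        ds.n,
        100 * ds.censoring_fraction,
        counts,
    )
    return ds


def write_dataset(dataset: MediationDataset, path: str | Path) -> None:
    dataset.to_frame().to_csv(path, index=False)


def read_frequency_table(path: str | Path) -> dict:
    """Two-column CSV (category, frequency) -> mapping."""
    df = pd.read_csv(path, float_precision="round_trip")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected columns (category, frequency)")
    cat, freq = df.columns[:2]
    return dict(zip(df[cat], df[freq].astype(float)))


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    return obj


def write_json(payload: dict, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(_jsonify(payload), fh, indent=2)
        fh.write("\n")
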