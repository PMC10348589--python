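"""Run configuration, trial-table I/O, and reproducible pipeline stages.

All randomness flows from one master seed through ``numpy.random.SeedSequence``
spawning, so a (config, seed) pair fully determines every simulation stage.
Artifacts are stamped with a hash of the canonical config JSON.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .fitting import FitConfig, IntegrationConfig
from .observers import SearchConfig
from .simulate import (CONTROL_COLUMNS, MAIN_COLUMNS, LogNormalSpec,
                       ParamPrior)
from .task import RewardSpec, TaskGeometry

__all__ = ["RunConfig", "read_trials", "run_pipeline", "SchemaError"]


class SchemaError(ValueError):
    """A trial table violates its schema."""


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a run, serializable to YAML."""

    geometry: TaskGeometry = TaskGeometry()
    reward: RewardSpec = RewardSpec()
    search: SearchConfig = SearchConfig()
    integration: IntegrationConfig = IntegrationConfig()
    fit: FitConfig = FitConfig()
    prior: ParamPrior = ParamPrior()
    convention: str = "weighted"
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        prior = data.get("prior")
        if prior is not None:
            data["prior"] = ParamPrior(**{
                k: LogNormalSpec(**v) for k, v in prior.items()})
        for key, typ in (("geometry", TaskGeometry), ("reward", RewardSpec),
                         ("search", SearchConfig),
                         ("integration", IntegrationConfig),
                         ("fit", FitConfig)):
            if key in data and isinstance(data[key], dict):
                sub = dict(data[key])
                if key == "geometry":
                    for tkey in ("sector_angles_deg", "start"):
                        if tkey in sub:
                            sub[tkey] = tuple(sub[tkey])
                data[key] = typ(**sub)
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def stage_seed(self, stage: str) -> np.random.SeedSequence:
        """Deterministic per-stage seed derived from the master seed."""
        digest = hashlib.sha256(stage.encode()).digest()
        salt = int.from_bytes(digest[:4], "big")
        return np.random.SeedSequence(entropy=self.seed, spawn_key=(salt,))

    def provenance(self) -> dict:
        return {"config_hash": self.config_hash, "seed": self.seed,
                "version": __version__}


_SCHEMAS = {
    "control": {
        "required": CONTROL_COLUMNS[:7],
        "optional": CONTROL_COLUMNS[7:],
    },
    "main": {
        "required": [c for c in MAIN_COLUMNS if c not in
                     ("sensed_x", "sensed_y")],
        "optional": ["sensed_x", "sensed_y"],
    },
}


def read_trials(path, schema: str) -> pd.DataFrame:
    """Read and validate a trial table ('control' or 'main' schema).

    Raises :class:`SchemaError` with a row number on the first violation.
    """
    if schema not in _SCHEMAS:
        raise ValueError(f"schema must be 'control' or 'main', got {schema!r}")
    spec = _SCHEMAS[schema]
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty file, no trials to read") from None
    if len(df) == 0:
        raise SchemaError(f"{path}: empty dataset")
    missing = [c for c in spec["required"] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")

    numeric = [c for c in df.columns
               if c in spec["required"] + spec["optional"] and c != "kind"]
    for col in numeric:
        vals = pd.to_numeric(df[col], errors="coerce")
        allow_nan = col in ("circle_radius", "sensed_x", "sensed_y")
        bad = vals.isna() if not allow_nan else np.isinf(vals.fillna(0.0))
        if bad.any():
            row = int(np.argmax(bad.to_numpy())) + 2  # 1-based + header
            raise SchemaError(f"{path}, line {row}: bad value in '{col}'")
        df[col] = vals

    if schema == "main":
        kinds = set(df["kind"].unique())
        if not kinds <= {"feedback", "confidence"}:
            raise SchemaError(f"{path}: unknown trial kind(s) "
                              f"{kinds - {'feedback', 'confidence'}}")
        fb = df["kind"] == "feedback"
        if df.loc[fb, "circle_radius"].notna().any():
            row = int(np.argmax((fb & df["circle_radius"].notna())
                                .to_numpy())) + 2
            raise SchemaError(
                f"{path}, line {row}: circle_radius on a feedback trial")
        conf = df["kind"] == "confidence"
        if df.loc[conf, "circle_radius"].isna().any():
            row = int(np.argmax((conf & df["circle_radius"].isna())
                                .to_numpy())) + 2
            raise SchemaError(
                f"{path}, line {row}: confidence trial without circle_radius")
    return df


def run_pipeline(config: RunConfig, command: str, outdir,
                 **kwargs) -> dict:
    """Execute one pipeline stage and write its artifacts under ``outdir``.

    Returns a manifest of written files.  Stages: simulate, fit, compare,
    recover-models, recover-params, efficiency, summarize, ppc — the CLI is
    a thin wrapper over this function.
    """
    from . import cli
    stage = cli.STAGES.get(command)
    if stage is None:
        raise ValueError(f"unknown pipeline command: {command!r}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    return stage(config, outdir, **kwargs)
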