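"""Plain-text interfaces: YAML/JSON experiment configs and CSV exports.

All times are months.  Infinite right endpoints of censoring intervals are
written with the token ``inf``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .design import TrialDesign, scenario_1, scenario_2
from .estimands import AnalysisDataset
from .runner import ExperimentConfig

__all__ = [
    "config_from_dict",
    "load_config",
    "trial_to_csv",
    "dataset_to_csv",
]

_ARM_LABELS = {0: "control", 1: "experimental"}
_SCENARIOS = {1: scenario_1, 2: scenario_2}


def config_from_dict(d: dict) -> ExperimentConfig:
    """Build an :class:`ExperimentConfig` from a parsed config mapping.

    The design is given either as ``scenario: 1`` / ``scenario: 2`` or as a
    ``design:`` mapping with :class:`TrialDesign` fields.
    """
    d = dict(d)
    if "scenario" in d:
        design = _SCENARIOS[int(d.pop("scenario"))]()
    elif "design" in d:
        design = TrialDesign(**d.pop("design"))
    else:
        raise ValueError("config needs a 'scenario' or a 'design' section")
    if "shutdown_starts" in d:
        d["shutdown_starts"] = tuple(float(s) for s in d["shutdown_starts"])
    if "strategies" in d:
        d["strategies"] = tuple(d["strategies"])
    return ExperimentConfig(design=design, **d)


def load_config(path: str | Path) -> ExperimentConfig:
    """Read an experiment config from a YAML (or JSON) file."""
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    return config_from_dict(data)


def trial_to_csv(trial: pd.DataFrame, path: str | Path) -> None:
    """Write a patient table with readable arm labels (times in months)."""
    out = trial.copy()
    out["arm"] = out["arm"].map(_ARM_LABELS)
    out.to_csv(path, index=False)


def dataset_to_csv(dataset: AnalysisDataset, path: str | Path) -> None:
    """Write analysis rows: (id, arm, time, event) or (id, arm, left, right)."""
    out = dataset.data.copy()
    out.insert(0, "id", np.arange(len(out)))
    out["arm"] = out["arm"].map(_ARM_LABELS)
    out.to_csv(path, index=False)
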