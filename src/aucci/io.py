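"""Reading and writing study tables, scenario configs, and fixtures.

A *study table* is the minimal individual-level format: a CSV with a header
and two columns, ``status`` (0 = control, 1 = case) and ``value`` (the
marker measurement).  Scenario configuration files (YAML or JSON) drive the
simulation CLI.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import MarkerSample
from .sim import ScenarioConfig

__all__ = [
    "read_study_csv",
    "write_study_csv",
    "sample_to_frame",
    "frame_to_sample",
    "make_fixture",
    "load_scenarios",
]

REQUIRED_COLUMNS = ("status", "value")


def frame_to_sample(frame: pd.DataFrame, flip: bool = False) -> MarkerSample:
    """Validate a (status, value) frame and split it into the two groups.

    ``flip`` inverts the status coding (1 = control) for datasets that use
    the opposite convention.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(
            f"missing column(s) {missing}; expected a header with {REQUIRED_COLUMNS}"
        )
    status = pd.to_numeric(frame["status"], errors="coerce")
    value = pd.to_numeric(frame["value"], errors="coerce")
    bad_status = frame.index[~status.isin([0, 1])].tolist()
    if bad_status:
        raise ValueError(
            f"status must be 0 (control) or 1 (case); offending rows: {bad_status[:10]}"
        )
    bad_value = frame.index[value.isna()].tolist()
    if bad_value:
        raise ValueError(f"non-numeric marker values at rows: {bad_value[:10]}")
    case_flag = status.astype(int) == (0 if flip else 1)
    values1 = value[case_flag].to_numpy(dtype=float)
    values0 = value[~case_flag].to_numpy(dtype=float)
    if values0.size < 1 or values1.size < 1:
        raise ValueError(
            f"both status groups must be present (got {values0.size} controls, "
            f"{values1.size} cases)"
        )
    return MarkerSample(values0=values0, values1=values1)


def read_study_csv(path, flip: bool = False) -> MarkerSample:
    """Read and validate a two-column (status, value) CSV."""
    frame = pd.read_csv(path)
    return frame_to_sample(frame, flip=flip)


def sample_to_frame(sample: MarkerSample) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "status": np.concatenate(
                (np.zeros(sample.n0, dtype=int), np.ones(sample.n1, dtype=int))
            ),
            "value": np.concatenate((sample.values0, sample.values1)),
        }
    )


def write_study_csv(sample: MarkerSample, path) -> None:
    sample_to_frame(sample).to_csv(path, index=False)


def make_fixture(
    n0: int,
    n1: int,
    target_auc: float,
    seed: int,
    sigma0: float = 1.0,
    sigma1: float = 1.0,
) -> MarkerSample:
    """Synthetic study table with expected AUC equal to ``target_auc``.

    Controls are N(0, sigma0^2), cases N(delta, sigma1^2) with
    ``delta = Phi^{-1}(target_auc) * sqrt(sigma0^2 + sigma1^2)``, the same
    shift rule the simulation engine uses; the realized sample AUC scatters
    around the target with the usual U-statistic spread.
    """
    from scipy import stats

    if not 0.0 < target_auc < 1.0:
        raise ValueError(f"target_auc must lie in (0, 1), got {target_auc}")
    rng = np.random.default_rng(seed)
    delta = stats.norm.ppf(target_auc) * float(np.hypot(sigma0, sigma1))
    return MarkerSample(
        values0=rng.normal(0.0, sigma0, size=n0),
        values1=rng.normal(delta, sigma1, size=n1),
    )


def load_scenarios(path):
    """Parse a YAML/JSON simulation config into scenario cells.

    Schema::

        methods: [lt, wald, wald_cc]        # optional, default: all ten
        defaults: {reps: 10000, alpha: 0.05, seed: 1}
        scenarios:
          - {auc0: 0.9, n: 40, ratio: "1:1"}
          - {auc0: 0.8, n: 100, ratio: "1:2", sigma1: 2.0, scale: ordinal5}

    Per-scenario keys override the defaults.  Returns
    ``(list[ScenarioConfig], list[str] methods)``.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        doc = json.loads(text)
    else:
        doc = yaml.safe_load(text)
    if not isinstance(doc, dict) or "scenarios" not in doc:
        raise ValueError("config must be a mapping with a 'scenarios' list")
    defaults = doc.get("defaults", {}) or {}
    methods = doc.get("methods")
    configs = []
    for i, entry in enumerate(doc["scenarios"]):
        if not isinstance(entry, dict):
            raise ValueError(f"scenario #{i} is not a mapping")
        merged = {**defaults, **entry}
        try:
            configs.append(ScenarioConfig(**merged))
        except (TypeError, ValueError) as exc:
            raise ValueError(f"scenario #{i} is invalid: {exc}") from exc
    return configs, methods
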