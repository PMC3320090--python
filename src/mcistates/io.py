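"""Reading and writing the long-format visit tables and configuration files.

The canonical table has one row per subject-visit with columns ``subject_id``,
``visit``, ``time`` (years from entry), ``age``, the baseline covariates
(``female``, ``famhx``, ``apoe4``, ``low_educ``, ``htn``), the clinical flags
(``mci_cc``, ``dementia``, ``death``) and either raw test-score columns or a
precomputed ``state`` column.  Arbitrary input layouts are mapped onto this via
a YAML column configuration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .cleaning import BASELINE_COVARIATES, Trajectory
from .states import DEFAULT_BATTERY, State, TestSpec

__all__ = [
    "ColumnConfig",
    "load_column_config",
    "read_visit_table",
    "trajectories_from_table",
    "table_from_trajectories",
    "load_manual_edits",
    "write_fit_json",
]

CANONICAL_FLAGS = ("mci_cc", "dementia", "death")


@dataclass
class ColumnConfig:
    """Mapping of an input table's columns onto canonical roles.

    ``tests`` maps canonical test names to ``{column, domain, higher_is_worse}``;
    ``covariates`` maps canonical covariate names to source columns, with the
    special entry ``education_years`` converted to the ``low_educ`` indicator
    (<=12 years).
    """

    id: str = "subject_id"
    time: str = "time"
    age: str = "age"
    flags: dict = field(default_factory=lambda: {f: f for f in CANONICAL_FLAGS})
    covariates: dict = field(default_factory=lambda: {c: c for c in BASELINE_COVARIATES})
    tests: dict = field(default_factory=dict)

    def battery(self) -> dict[str, TestSpec]:
        if not self.tests:
            return dict(DEFAULT_BATTERY)
        return {
            name: TestSpec(spec["domain"], bool(spec.get("higher_is_worse", False)))
            for name, spec in self.tests.items()
        }


def load_column_config(path) -> ColumnConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = ColumnConfig()
    for key in ("id", "time", "age"):
        if key in raw:
            setattr(cfg, key, raw[key])
    if "flags" in raw:
        cfg.flags.update(raw["flags"])
    if "covariates" in raw:
        cfg.covariates = dict(raw["covariates"])
    if "tests" in raw:
        cfg.tests = dict(raw["tests"])
    return cfg


def read_visit_table(path, config: ColumnConfig | None = None) -> pd.DataFrame:
    """Read a delimited visit table and rename columns to canonical roles."""
    df = pd.read_csv(path)
    if config is None:
        return df
    rename = {config.id: "subject_id", config.time: "time", config.age: "age"}
    for canon, col in config.flags.items():
        rename[col] = canon
    for canon, col in config.covariates.items():
        if canon != "education_years":
            rename[col] = canon
    for canon, spec in config.tests.items():
        rename[spec.get("column", canon)] = canon
    out = df.rename(columns=rename)
    if "education_years" in config.covariates:
        out["low_educ"] = (out[config.covariates["education_years"]] <= 12).astype(float)
    return out


def trajectories_from_table(df: pd.DataFrame, state_col: str = "state") -> list[Trajectory]:
    """Group a classified canonical table into per-subject trajectories."""
    if state_col not in df.columns:
        raise ValueError(f"table lacks the {state_col!r} column; classify first")
    trajs = []
    for sid, g in df.groupby("subject_id", sort=True):
        g = g.sort_values("time")
        states = [State[s] if isinstance(s, str) else State(s) for s in g[state_col]]
        tb = None
        if "state_test_based" in g.columns:
            tb = [
                (State[s] if isinstance(s, str) else State(int(s))) if not pd.isna(s) else None
                for s in g["state_test_based"]
            ]
        covs = {}
        first = g.iloc[0]
        for c in BASELINE_COVARIATES:
            covs[c] = float(first[c]) if c in g.columns and not pd.isna(first[c]) else np.nan
        trajs.append(
            Trajectory(
                subject_id=sid,
                times=g["time"].to_numpy(float),
                states=states,
                age_at_entry=float(first["age"]) - float(first["time"]),
                covariates=covs,
                test_based=tb,
            )
        )
    return trajs


def table_from_trajectories(trajs) -> pd.DataFrame:
    rows = []
    for traj in trajs:
        for i, s in enumerate(traj.states):
            rows.append(
                {
                    "subject_id": traj.subject_id,
                    "visit": i,
                    "time": float(traj.times[i]),
                    "age": float(traj.ages[i]),
                    **traj.covariates,
                    "state": s.name,
                }
            )
    return pd.DataFrame(rows)


def load_manual_edits(path) -> dict:
    """Manual per-visit overrides: YAML mapping subject -> {visit: state name}."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return {
        subject: {int(v): State[name] for v, name in visits.items()}
        for subject, visits in raw.items()
    }


def write_fit_json(result, path) -> None:
    with open(path, "w") as fh:
        json.dump(result.to_json_dict(), fh, indent=2)


def load_fit_config(path):
    """Fitting options from YAML (quadrature, tolerances, starts, covariate lists)."""
    from .model import FitConfig, QuadratureRule

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = {}
    if "quadrature" in raw:
        q = raw["quadrature"]
        kwargs["quadrature"] = QuadratureRule(
            int(q.get("n_points", 1)), bool(q.get("adaptive", True))
        )
    for key in (
        "random_effects", "sigma_start", "gtol", "max_iter",
        "n_starts", "start_jitter", "start_seed", "compute_se", "separation_threshold",
    ):
        if key in raw:
            kwargs[key] = raw[key]
    for key in ("covariates_normal", "covariates_cc"):
        if key in raw:
            kwargs[key] = tuple(raw[key])
    return FitConfig(**kwargs)


def load_cohort_spec(path):
    """Cohort-generation settings from YAML; ``seed`` is mandatory."""
    from .synthetic import CohortSpec, default_true_params

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sigma_u = raw.pop("sigma_u", None)
    if sigma_u is not None:
        raw["params"] = default_true_params(float(sigma_u))
    return CohortSpec(**raw)
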