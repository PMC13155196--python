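"""Readers and writers: long-format CSV tables, the hospital-readmission
column layout, fit-result JSON, and config files (JSON or YAML)."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import DataValidationError, RecurrentData
from .hazards import StepBaseline

__all__ = [
    "read_long_csv",
    "write_long_csv",
    "adapt_readmission_layout",
    "fit_result_to_dict",
    "write_fit_result",
    "write_baseline_csv",
    "load_config",
]

DEFAULT_COLUMNS = ("subject_id", "recurrence_index", "gap_time", "event")


def read_long_csv(path, z_cols, v_cols, colmap=None, unit="years") -> RecurrentData:
    """Read a long-format recurrent-event CSV.

    ``colmap`` maps our canonical names (subject_id, recurrence_index,
    gap_time, event) to the file's column headers.  Validation errors carry
    the offending row numbers.
    """
    df = pd.read_csv(path)
    colmap = dict(colmap or {})
    rename = {v: k for k, v in colmap.items() if v in df.columns}
    df = df.rename(columns=rename)
    return RecurrentData.from_frame(df, z_cols=z_cols, v_cols=v_cols, unit=unit)


def write_long_csv(data, path) -> None:
    """Write records to CSV; write o read is the identity on valid tables."""
    if isinstance(data, RecurrentData):
        df = data.to_frame()
    else:
        df = pd.DataFrame(data)
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# colorectal readmission layout (id, t.start, t.stop, event, covariates)
# ---------------------------------------------------------------------------

_DUKES_LEVELS = {1: None, 2: "dukes_C", 3: "dukes_D"}        # ref: A-B (1)
_CHARLSON_LEVELS = {0: None, 1: "charlson_12", 3: "charlson_3plus"}  # ref: 0


def adapt_readmission_layout(df: pd.DataFrame) -> RecurrentData:
    """Adapt the calendar-interval hospital-readmission layout.

    Expects columns id, t.start, t.stop, event, chemo, sex, dukes,
    charlson; gap time = t.stop - t.start (days).  Categorical codings are
    expanded to reference-coded indicators (reference: male, non-treated,
    Dukes A-B, Charlson index 0) and the same covariates enter both the
    latency (Z) and the incidence (V) design, with an intercept prepended
    to V.
    """
    required = ["id", "t.start", "t.stop", "event", "chemo", "sex",
                "dukes", "charlson"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataValidationError(f"missing columns: {missing}")
    df = df.reset_index(drop=True)
    gap = pd.to_numeric(df["t.stop"]) - pd.to_numeric(df["t.start"])
    bad = df.index[~(gap > 0)].tolist()
    if bad:
        raise DataValidationError("non-positive computed gap t.stop - t.start",
                                  rows=bad)

    def _binary(col, positive):
        s = df[col]
        if s.dtype == object:
            return (s.astype(str).str.lower() == positive).astype(float)
        # frailtypack numeric coding: 1 = reference, 2 = positive level
        return (pd.to_numeric(s) == 2).astype(float)

    out = pd.DataFrame({
        "subject_id": df["id"],
        "gap_time": gap,
        "event": pd.to_numeric(df["event"]).astype(int),
        "chemo_treated": _binary("chemo", "treated"),
        "sex_female": _binary("sex", "female"),
    })
    dukes = pd.to_numeric(df["dukes"], errors="coerce")
    out["dukes_C"] = (dukes == 2).astype(float)
    out["dukes_D"] = (dukes == 3).astype(float)
    charl = pd.to_numeric(df["charlson"], errors="coerce")
    out["charlson_12"] = (charl == 1).astype(float)
    out["charlson_3plus"] = (charl == 3).astype(float)
    covs = ["sex_female", "chemo_treated", "dukes_C", "dukes_D",
            "charlson_12", "charlson_3plus"]
    return RecurrentData.from_frame(out, z_cols=covs, v_cols=covs, unit="days")


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

def fit_result_to_dict(fit) -> dict:
    p = fit.params
    return {
        "link": p.link,
        "gamma": list(map(float, p.gamma)),
        "beta": list(map(float, p.beta)),
        "alpha": float(p.alpha),
        "se_gamma": list(map(float, fit.se_gamma)),
        "se_beta": list(map(float, fit.se_beta)),
        "se_alpha": float(fit.se_alpha),
        "loglik": float(fit.loglik),
        "aic": float(fit.aic),
        "n_iter": int(fit.n_iter),
        "converged": bool(fit.converged),
        "accept_rate": float(fit.accept_rate),
        "flags": dict(fit.flags),
        "config": {k: (v if isinstance(v, (int, float, str, bool)) else str(v))
                   for k, v in fit.config.__dict__.items()},
    }


def write_fit_result(fit, path) -> None:
    Path(path).write_text(json.dumps(fit_result_to_dict(fit), indent=2))


def write_baseline_csv(baseline: StepBaseline, path) -> None:
    pd.DataFrame({"event_time": baseline.times,
                  "increment": baseline.increments}).to_csv(path, index=False)


def load_config(path) -> dict:
    """Load a JSON or YAML key-value config file (by extension)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        return yaml.safe_load(text) or {}
    return json.loads(text)
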