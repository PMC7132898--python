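"""Dataset and result I/O plus configuration parsing.

Datasets are comma-separated text with a mandatory header and columns
``time`` (positive real), ``event`` (0/1) and ``arm`` (0 = control,
1 = research).  Results round-trip through CSV or JSON at full float64
precision: floats are written in shortest round-trip decimal form (up to 17
significant digits) and read back with a correctly-rounded parser.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import SurvivalDataset
from .simulate import ControlDistribution, PiecewiseHREffect, UniformCensoring

__all__ = [
    "read_dataset",
    "write_dataset",
    "write_results",
    "results_to_frame",
    "load_config",
    "scenario_from_config",
]

def read_dataset(path) -> SurvivalDataset:
    """Read and validate a two-arm survival dataset from delimited text."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = {"time", "event", "arm"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    problems = []
    # data rows are 1-based after the header line
    for col in ("event", "arm"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[~vals.isin([0, 1])]
        for i in bad[:20]:
            problems.append(
                f"row {i + 1}: {col}={df[col].iloc[i]!r} is not 0/1"
                + (" (recode arm labels to 0=control, 1=research)"
                   if col == "arm" else "")
            )
    time = pd.to_numeric(df["time"], errors="coerce")
    bad = df.index[~(time > 0)]
    for i in bad[:20]:
        problems.append(f"row {i + 1}: time={df['time'].iloc[i]!r} is not a "
                        "positive number")
    if problems:
        raise ValueError(f"{path}: malformed rows:\n  " + "\n  ".join(problems))
    return SurvivalDataset(
        time.to_numpy(float),
        df["event"].to_numpy(int),
        df["arm"].to_numpy(int),
    )


def write_dataset(data: SurvivalDataset, path) -> None:
    data.to_frame().to_csv(path, index=False)


def results_to_frame(results) -> pd.DataFrame:
    """Tidy frame from TestResult objects (dict or iterable)."""
    if isinstance(results, dict):
        results = list(results.values())
    rows = []
    for r in results:
        rows.append(
            {
                "test": r.name,
                "statistic": r.statistic,
                "null_dist": r.null_dist,
                "df": r.df if r.df is not None else "",
                "p_value": r.p_value,
            }
        )
    return pd.DataFrame(rows)


def write_results(results, path, fmt: str | None = None) -> None:
    """Serialize test results (or any tidy frame) to CSV or JSON.

    Numeric round-trips are exact (shortest round-trip float representation).
    """
    path = Path(path)
    fmt = fmt or ("json" if path.suffix == ".json" else "csv")
    df = results if isinstance(results, pd.DataFrame) else results_to_frame(results)
    if len(df) == 0:
        raise ValueError("no results to write")
    if fmt == "csv":
        df.to_csv(path, index=False)
    elif fmt == "json":
        records = df.to_dict(orient="records")
        path.write_text(
            json.dumps(records, indent=1,
                       default=lambda o: o.item() if hasattr(o, "item") else str(o))
        )
    else:
        raise ValueError(f"unknown format {fmt!r}")


def load_config(path) -> dict:
    """Load a YAML or JSON configuration file (YAML is a JSON superset)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return cfg


def scenario_from_config(cfg: dict):
    """Build (distribution, censoring, effect) from a config mapping.

    Expected keys: ``distribution`` (family + parameters), ``censoring``
    (low/high), ``effect`` (kind, hr, t_star).
    """
    dist = ControlDistribution.from_config(cfg["distribution"])
    cens = UniformCensoring.from_config(cfg["censoring"])
    e = cfg.get("effect") or {"kind": "null"}
    # YAML parses a bare `null` as None; treat it as the null effect
    kind = e.get("kind") or "null"
    if kind == "null":
        eff = PiecewiseHREffect.null()
    elif kind == "ph":
        eff = PiecewiseHREffect.ph(float(e["hr"]))
    elif kind == "early":
        eff = PiecewiseHREffect.early(float(e["hr"]), float(e["t_star"]))
    elif kind == "late":
        eff = PiecewiseHREffect.late(float(e["hr"]), float(e["t_star"]))
    else:
        raise ValueError(f"unknown effect kind {kind!r}")
    return dist, cens, eff
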