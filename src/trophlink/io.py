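"""CSV/JSON readers and writers for the package's tabular schemas.

Everything is plain UTF-8 CSV with a header row and "." decimals. Sample and
station tables are tidy: one row per individual / per station.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import SourceSummary

SAMPLE_COLUMNS = [
    "sample_id",
    "station_id",
    "species",
    "functional_group",
    "d13c",
    "d15n",
    "c_to_n",
    "total_length",
]
STATION_COLUMNS = ["station_id", "depth", "sstemp", "bottemp", "salinity", "chla"]
SOURCE_COLUMNS = [
    "label",
    "mu_d13c",
    "sd_d13c",
    "mu_d15n",
    "sd_d15n",
    "tef_d13c",
    "tef_sd_d13c",
    "tef_d15n",
    "tef_sd_d15n",
]


def _require(df: pd.DataFrame, columns, what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{what} is missing column(s): {missing}")


def read_samples(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"sample_id": str, "station_id": str})
    _require(df, ["sample_id", "station_id", "species", "functional_group", "d13c", "d15n"], "sample table")
    return df


def write_samples(df: pd.DataFrame, path) -> None:
    cols = [c for c in SAMPLE_COLUMNS if c in df.columns]
    df[cols].to_csv(path, index=False)


def read_stations(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"station_id": str})
    _require(df, ["station_id", "depth"], "station table")
    return df


def write_stations(df: pd.DataFrame, path) -> None:
    cols = [c for c in STATION_COLUMNS if c in df.columns]
    df[cols].to_csv(path, index=False)


def read_sources(path) -> list[SourceSummary]:
    df = pd.read_csv(path)
    _require(df, SOURCE_COLUMNS, "source table")
    return [
        SourceSummary(
            label=str(r["label"]),
            mu=np.array([r["mu_d13c"], r["mu_d15n"]]),
            sd=np.array([r["sd_d13c"], r["sd_d15n"]]),
            tef_mu=np.array([r["tef_d13c"], r["tef_d15n"]]),
            tef_sd=np.array([r["tef_sd_d13c"], r["tef_sd_d15n"]]),
        )
        for _, r in df.iterrows()
    ]


def write_sources(sources: list[SourceSummary], path) -> None:
    pd.DataFrame(
        {
            "label": [s.label for s in sources],
            "mu_d13c": [s.mu[0] for s in sources],
            "sd_d13c": [s.sd[0] for s in sources],
            "mu_d15n": [s.mu[1] for s in sources],
            "sd_d15n": [s.sd[1] for s in sources],
            "tef_d13c": [s.tef_mu[0] for s in sources],
            "tef_sd_d13c": [s.tef_sd[0] for s in sources],
            "tef_d15n": [s.tef_mu[1] for s in sources],
            "tef_sd_d15n": [s.tef_sd[1] for s in sources],
        }
    ).to_csv(path, index=False)


def read_topology(path) -> dict[str, list[str]]:
    df = pd.read_csv(path)
    _require(df, ["predator_group", "prey_group"], "topology table")
    edges: dict[str, set[str]] = {}
    for _, r in df.iterrows():
        edges.setdefault(str(r["predator_group"]), set()).add(str(r["prey_group"]))
    return {pred: sorted(prey) for pred, prey in sorted(edges.items())}


def write_topology(topology: dict[str, list[str]], path) -> None:
    rows = [(pred, prey) for pred, preys in sorted(topology.items()) for prey in preys]
    pd.DataFrame(rows, columns=["predator_group", "prey_group"]).to_csv(path, index=False)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")
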