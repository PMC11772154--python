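"""Delimited-text IO for weekly record tables and flat config files."""

from __future__ import annotations

import dataclasses

import pandas as pd
import yaml

from .synthetic import SimConfig

__all__ = ["read_weekly", "write_weekly", "load_sim_config"]


def write_weekly(df, path, sep=","):
    """Write a weekly table with an ISO-date week_start column."""
    out = df.copy()
    if "week_start" in out:
        out["week_start"] = pd.to_datetime(out["week_start"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, sep=sep, index=False)


def read_weekly(path, sep=","):
    """Read a weekly table, parsing week_start as datetime."""
    df = pd.read_csv(path, sep=sep)
    if "week_start" in df:
        df["week_start"] = pd.to_datetime(df["week_start"])
    return df


def load_sim_config(path):
    """Load a :class:`SimConfig` from a YAML / flat key-value file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    fields = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = set(raw) - fields
    if unknown:
        raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
    if "drought_years" in raw and raw["drought_years"] is not None:
        raw["drought_years"] = tuple(raw["drought_years"])
    return SimConfig(**raw)
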