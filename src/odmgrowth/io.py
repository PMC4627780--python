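"""Reading and writing study datasets and configuration files."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .estimation import REQUIRED_COLUMNS, GrowthDataset

__all__ = ["read_growth_csv", "write_growth_csv", "load_config"]


class SchemaError(ValueError):
    """Input file does not have the expected columns."""


def read_growth_csv(path) -> GrowthDataset:
    """Read a long-format growth CSV (animal_id, day, region, volume_cm3).

    Malformed rows are reported with their line number in the file
    (header = line 1).
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    lines = df.index + 2  # header occupies line 1
    problems = []
    vol = pd.to_numeric(df["volume_cm3"], errors="coerce")
    day = pd.to_numeric(df["day"], errors="coerce")
    for idx in df.index[vol.isna() | day.isna()]:
        problems.append(f"line {lines[idx]}: non-numeric day or volume")
    for idx in df.index[vol < 0]:
        problems.append(f"line {lines[idx]}: negative volume {vol[idx]}")
    for idx in df.index[day < 0]:
        problems.append(f"line {lines[idx]}: negative day {day[idx]}")
    for idx in df.index[~df["region"].isin(("T", "H", "N"))]:
        problems.append(f"line {lines[idx]}: unknown region {df.loc[idx, 'region']!r}")
    if problems:
        raise ValueError(f"{path}: invalid rows:\n" + "\n".join(problems))
    df["volume_cm3"] = vol
    df["day"] = day
    return GrowthDataset(df)


def write_growth_csv(dataset: GrowthDataset, path) -> None:
    dataset.to_csv(path)


def load_config(path) -> dict:
    """Load a YAML or JSON configuration file (by extension)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)
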