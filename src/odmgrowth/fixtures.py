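"""Packaged reference tables of fitted model parameters.

Four tables ship with the package, keyed T2-T5:

* ``T2`` — four-parameter fits (kp, kR', KH, KN with standard errors) for a
  rich colon-carcinoma study with longitudinal hypoxia/necrosis and for a
  breast study with an end-of-study hypoxia point.
* ``T3`` — two-parameter fits (kp, kR'; KH, KN fixed) with identifiability
  diagnostics (kappa, gamma, FIM rank, residual) for 38 xenografted cell
  lines.  ``*`` marks practically unidentifiable lines, ``#`` arguably
  identifiable ones.
* ``T4`` — the same two-parameter fits for 5 explant-like models.
* ``T5`` — the stroma-extended model fit (kPG, kR', kS).

Censored entries (printed as ``>100``, ``<0.01`` ...) are kept as markers:
they parse to NaN in the numeric view and are excluded from summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = ["FixtureTable", "load_fixture", "TABLE_IDS"]

TABLE_IDS = ("T2", "T3", "T4", "T5")

#: Columns that are labels, not measurements.
_LABEL_COLUMNS = {"system", "tissue", "cell_line", "flag", "model", "parameter", "units"}


def _parse_cell(value):
    """Numeric value of a printed cell; censored/missing markers -> NaN."""
    s = str(value).strip()
    if s in ("", "-", "nan"):
        return np.nan
    if s.startswith(">") or s.startswith("<"):
        return np.nan
    try:
        return float(s)
    except ValueError:
        return np.nan


@dataclass
class FixtureTable:
    """A packaged table: printed strings plus a parsed numeric view."""

    table_id: str
    raw: pd.DataFrame

    @property
    def data(self) -> pd.DataFrame:
        """Numeric view: value columns parsed to float, censored -> NaN."""
        df = self.raw.copy()
        for col in df.columns:
            if col not in _LABEL_COLUMNS:
                df[col] = df[col].map(_parse_cell)
        return df

    @property
    def censored(self) -> pd.DataFrame:
        """Boolean mask of censored (``>``/``<``) entries."""
        return self.raw.map(
            lambda v: str(v).strip().startswith((">", "<"))
        )

    def __len__(self) -> int:
        return len(self.raw)

    def summary(self, column: str) -> dict:
        """min/max/median of a numeric column, censored values excluded."""
        values = self.data[column].dropna()
        return {
            "column": column,
            "n": int(values.size),
            "n_censored": int(self.censored[column].sum()),
            "min": float(values.min()),
            "max": float(values.max()),
            "median": float(values.median()),
        }


def load_fixture(table_id: str) -> FixtureTable:
    """Load a packaged table by id (``T2``/``T3``/``T4``/``T5``)."""
    key = str(table_id).upper()
    if key not in TABLE_IDS:
        raise KeyError(f"unknown fixture table {table_id!r}; valid ids: {TABLE_IDS}")
    path = resources.files(__package__) / "data" / f"{key.lower()}.csv"
    with resources.as_file(path) as p:
        raw = pd.read_csv(p, dtype=str, keep_default_na=False)
    return FixtureTable(table_id=key, raw=raw)
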