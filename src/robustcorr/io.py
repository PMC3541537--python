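"""Tabular input: paired numeric columns from CSV/TSV files."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["PairedTable", "load_table"]

_NA_VALUES = ["", "NA", "NaN", "nan"]


@dataclass
class PairedTable:
    """A paired sample read from a delimited file."""

    x: np.ndarray
    y: np.ndarray
    col_x: str
    col_y: str
    source: str
    n_dropped: int

    @property
    def n(self) -> int:
        return len(self.x)


def _pick(df: pd.DataFrame, sel) -> pd.Series:
    if isinstance(sel, int) or (isinstance(sel, str) and sel.isdigit()
                                and sel not in df.columns):
        i = int(sel)
        if not 0 <= i < df.shape[1]:
            raise ValueError(f"column index {i} out of range")
        return df.iloc[:, i]
    if sel not in df.columns:
        raise ValueError(f"missing column '{sel}'")
    return df[sel]


def load_table(path, col_x=0, col_y=1) -> PairedTable:
    """Load two numeric columns from a CSV or TSV file (header required).

    Columns are selected by name or 0-based index.  Rows with a missing
    value in either column are dropped (complete cases); at least 5
    complete rows must remain.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=None, engine="python",
                     na_values=_NA_VALUES, keep_default_na=False)
    sx = _pick(df, col_x)
    sy = _pick(df, col_y)
    x = pd.to_numeric(sx, errors="raise")
    y = pd.to_numeric(sy, errors="raise")
    ok = x.notna() & y.notna()
    n_dropped = int((~ok).sum())
    x, y = x[ok].to_numpy(float), y[ok].to_numpy(float)
    if len(x) < 5:
        raise ValueError("too few complete rows: need at least 5")
    return PairedTable(x, y, str(sx.name), str(sy.name), str(path), n_dropped)
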