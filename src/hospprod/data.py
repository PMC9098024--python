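"""Reading, writing and validating hospital datasets.

The on-disk format is plain CSV (UTF-8, comma-separated, dot decimal) with
the canonical header

    hospital_id,patient_days,beds,materials,electricity,doctors,nurses,services

patient_days in thousands, staff in FTEs, costs in 100,000 PLN.  All numeric
fields must be strictly positive: the analysis works on log-transformed
values, so a zero or negative entry has no log image and is rejected with a
message naming the offending row and column.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import COLUMNS

__all__ = ["read_csv", "write_csv", "validate_dataset", "DatasetError"]


class DatasetError(ValueError):
    """Malformed or out-of-domain hospital dataset."""


def validate_dataset(df: pd.DataFrame) -> pd.DataFrame:
    """Check schema, positivity and id uniqueness; return the frame."""
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise DatasetError(f"missing required column(s): {missing}")
    if len(df) == 0:
        raise DatasetError("dataset has no rows")
    if df["hospital_id"].duplicated().any():
        dupes = df.loc[df["hospital_id"].duplicated(), "hospital_id"].tolist()
        raise DatasetError(f"duplicate hospital_id values: {dupes}")
    for col in COLUMNS[1:]:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = ~np.isfinite(vals.to_numpy(dtype=float))
        if bad.any():
            row = df.index[bad][0]
            raise DatasetError(f"non-numeric value in column {col!r}, row {row}")
        nonpos = vals <= 0
        if nonpos.any():
            row = df.index[nonpos][0]
            rid = df.loc[row, "hospital_id"]
            raise DatasetError(
                f"non-positive value {vals[row]!r} in column {col!r}, "
                f"row {row} (hospital_id={rid!r}); all quantities must be > 0"
            )
        df[col] = vals.astype(float)
    return df


def read_csv(path: str | Path) -> pd.DataFrame:
    """Load and validate a hospital dataset from ``path``."""
    df = pd.read_csv(path)
    return validate_dataset(df)


def write_csv(dataset: pd.DataFrame, path: str | Path) -> None:
    """Write a dataset in the canonical column order; round-trips exactly."""
    dataset = dataset[list(COLUMNS)]
    dataset.to_csv(path, index=False)
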