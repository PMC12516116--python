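"""Reading and writing binary response matrices as delimited text.

Row = person, column = item, entries strictly 0/1.  Files may be comma- or
whitespace-delimited, with or without a header row; missing values are
rejected (complete cases only), not imputed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["read_responses", "write_responses"]


def read_responses(path) -> np.ndarray:
    """Read a response matrix from CSV/TSV/whitespace-delimited text."""
    df = pd.read_csv(path, sep=None, engine="python", header=None)
    # tolerate a header row of item labels
    first = df.iloc[0]
    if not first.map(lambda v: str(v).strip() in ("0", "1", "0.0", "1.0")).all():
        df = pd.read_csv(path, sep=None, engine="python", header=0)
    if df.isna().any().any():
        i = int(df.isna().any(axis=1).idxmax())
        raise ValueError(f"missing value in row {i}; supply complete cases only")
    try:
        X = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as err:
        raise ValueError(f"non-numeric entry in response matrix: {err}") from err
    bad = ~np.isin(X, (0.0, 1.0))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(f"non-binary entry {X[i, j]!r} at row {i}, column {j}")
    if X.shape[1] < 2:
        raise ValueError("need at least 2 items (columns)")
    return X


def write_responses(path, X) -> None:
    np.savetxt(path, np.asarray(X, dtype=int), fmt="%d", delimiter=",")
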