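"""Per-sample marker normalization.

MFI values are Z-scored within each sample and trimmed to [−5, 5] to
blunt the influence of outliers on clustering: for each marker,
``z = (x − mean) / sd`` over the sample's cells (sample sd, ddof=1),
clipped to the trim bounds.  A constant channel (sd = 0) is mapped to
all-zero scores with a warning rather than failing the run, since flat
background channels occur in practice.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np

from .datatypes import CellTable


def zscore_trim(
    table: CellTable, lower: float = -5.0, upper: float = 5.0
) -> CellTable:
    """Z-score each marker within the sample, then clip to [lower, upper].

    Returns a new :class:`CellTable` with the same cells and markers;
    non-marker columns are untouched.  Requires at least 2 cells.
    """
    if table.n_cells < 2:
        raise ValueError(
            f"sample {table.sample_id!r}: need >=2 cells to Z-score, "
            f"got {table.n_cells}"
        )
    df = table.df.copy()
    for marker in table.markers:
        x = df[marker].to_numpy(dtype=float)
        sd = x.std(ddof=1)
        if sd == 0:
            warnings.warn(
                f"sample {table.sample_id!r}: marker {marker!r} is constant; "
                "z-scores set to 0",
                stacklevel=2,
            )
            z = np.zeros_like(x)
        else:
            z = (x - x.mean()) / sd
        df[marker] = np.clip(z, lower, upper)
    return replace(table, df=df)


def normalize_cohort(
    tables: list[CellTable], lower: float = -5.0, upper: float = 5.0
) -> list[CellTable]:
    """Apply :func:`zscore_trim` independently to each sample."""
    return [zscore_trim(t, lower=lower, upper=upper) for t in tables]
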