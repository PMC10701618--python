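"""End-to-end orchestration of the phenotyping stages.

Chains normalization, consensus phenotyping of the stratified subset,
and kNN label propagation so that every cell in a cohort receives a
phenotype, the way the stages are meant to compose.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .datatypes import CellTable, LINEAGE_MARKERS
from .normalize import normalize_cohort
from .phenotype import consensus_phenotype, pool_tables
from .propagate import build_reference_embedding, propagate_labels


def phenotype_cohort(
    tables: Sequence[CellTable],
    n_sample: int = 2500,
    k_neighbors: int = 20,
    tau: float = 0.5,
    per_type: int = 500,
    k: int = 100,
    seed: int = 0,
    normalized: bool = False,
) -> pd.DataFrame:
    """Normalize, consensus-cluster, and propagate labels to all cells.

    Returns one row per cell in the cohort with ``sample_id, cell_id,
    phenotype``; cells in the clustered subset carry their three votes.
    """
    norm = list(tables) if normalized else normalize_cohort(list(tables))
    labeled = consensus_phenotype(
        norm, n_sample=n_sample, k_neighbors=k_neighbors, tau=tau, seed=seed
    )
    ref = build_reference_embedding(
        labeled.merge(
            pool_tables(norm)[["sample_id", "cell_id", *LINEAGE_MARKERS]],
            on=["sample_id", "cell_id"],
        ),
        per_type=per_type,
        k=k,
        seed=seed,
    )
    pool = pool_tables(norm)
    labels = propagate_labels(pool, ref)
    out = pool[["sample_id", "cell_id"]].copy()
    out["phenotype"] = labels.to_numpy()
    return out.merge(
        labeled.drop(columns=["phenotype"]),
        on=["sample_id", "cell_id"],
        how="left",
    )
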