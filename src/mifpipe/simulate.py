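"""Synthetic multiplex-IF cohorts with planted ground truth.

Emulates the inputs of a 12-patient melanoma anti-PD1 cohort profiled by
cyclic multiplex immunofluorescence: per-sample segmented-cell tables with
lineage markers (AQP1, CD31, CD4, CD8, MelanA, SOX10) and functional
markers (VCAM1, STING, PD1, GrzB), compartment polygons, plus expression
matrices and two-group count panels for the signature stages.  Every
generator plants a recoverable signal and returns the ground truth, so
each downstream stage can be tested against a known answer.

Marker intensities follow a log-normal on/off model: a marker's MFI is
``location · exp(N(0, scale))`` plus additive Gaussian measurement noise
of sd ``noise_sd``, floored at 0.  ``location`` is thus the natural-unit
median; at ``scale = noise_sd = 0`` the MFI equals the location exactly.

The spatial signal of interest is an excess of cytotoxic T cells near
inflamed (VCAM1+) endothelial cells in responder samples: with
probability ``proximity_prob[group]`` a CD8 cell is displaced from a
uniformly chosen inflamed EC by an isotropic Gaussian of sd
``proximity_sigma`` microns, otherwise placed uniformly in the field.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from .datatypes import (
    DEFAULT_PHENOTYPE_RULES,
    FUNCTIONAL_MARKERS,
    LINEAGE_MARKERS,
    PHENOTYPES,
    CellTable,
    ExpressionMatrix,
    GeneSet,
    RegionSet,
)

#: Default on/off log-normal (location, scale) per marker state.
_ON = (10.0, 0.25)
_OFF = (1.0, 0.25)


def default_marker_model() -> dict[tuple[str, str], tuple[float, float]]:
    model: dict[tuple[str, str], tuple[float, float]] = {}
    for marker in LINEAGE_MARKERS + FUNCTIONAL_MARKERS:
        model[(marker, "on")] = _ON
        model[(marker, "off")] = _OFF
    return model


@dataclass
class CohortConfig:
    """Study-design knobs for a synthetic multiplex cohort.

    Defaults reproduce the study conditions: 6 responder and 6
    non-responder samples, four phenotypes with melanoma dominating, a
    1×1 mm field, and a responder-only excess of CD8 cells near inflamed
    endothelium.
    """

    n_responders: int = 6
    n_nonresponders: int = 6
    cells_per_sample: int = 2000
    field_size: tuple[float, float] = (1000.0, 1000.0)
    phenotype_proportions: Mapping[str, float] = field(
        default_factory=lambda: {
            "Melanoma": 0.5,
            "BloodVessel": 0.2,
            "Thelper": 0.15,
            "CytotoxicT": 0.15,
        }
    )
    marker_model: Mapping[tuple[str, str], tuple[float, float]] = field(
        default_factory=default_marker_model
    )
    noise_sd: float = 0.5
    inflamed_fraction: float = 0.3
    sting_given_inflamed: float = 0.5
    pd1_fraction: float = 0.3
    grzb_fraction: float = 0.3
    proximity_prob: Mapping[str, float] = field(
        default_factory=lambda: {"R": 0.4, "NR": 0.0}
    )
    proximity_sigma: float = 15.0
    nuclear_size_mean: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        total = float(sum(self.phenotype_proportions.values()))
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"phenotype proportions sum to {total}, expected 1"
            )
        for group, p in self.proximity_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"proximity_prob[{group!r}]={p} outside [0,1]")
        if self.field_size[0] <= 0 or self.field_size[1] <= 0:
            raise ValueError("field_size must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


def zero_noise_config(**overrides) -> CohortConfig:
    """Degenerate config: scale=0, noise_sd=0, so MFIs equal locations."""
    model = {k: (loc, 0.0) for k, (loc, _) in default_marker_model().items()}
    return CohortConfig(marker_model=model, noise_sd=0.0, **overrides)


def separation_config(n_sd: float = 4.0, **overrides) -> CohortConfig:
    """Config whose on/off MFI distributions are ``n_sd`` noise-sds apart.

    Log-normal scale is zeroed and all noise routed through the additive
    Gaussian term, so the separation is exact: noise_sd = (on-off)/n_sd.
    """
    model = {k: (loc, 0.0) for k, (loc, _) in default_marker_model().items()}
    on, off = _ON[0], _OFF[0]
    return CohortConfig(
        marker_model=model, noise_sd=(on - off) / n_sd, **overrides
    )


@dataclass
class GroundTruth:
    """Planted truth accompanying every synthetic dataset.

    ``cells``: one row per emitted cell (sample_id, cell_id, phenotype,
    functional flags).  ``groups``: sample → R/NR.  ``genes``: per-gene
    signature membership / planted log2FC (expression modes only).
    """

    cells: pd.DataFrame | None = None
    groups: dict[str, str] = field(default_factory=dict)
    genes: pd.DataFrame | None = None


def _substream(seed: int, *names) -> np.random.Generator:
    """Named-stream splitter: one independent RNG per (seed, name...) key.

    Adding samples never perturbs earlier ones because each stream is
    keyed by name, not by draw order.
    """
    keys = [zlib.crc32(str(n).encode()) for n in names]
    return np.random.default_rng(np.random.SeedSequence([int(seed), *keys]))


def _draw_mfi(
    rng: np.random.Generator,
    n: int,
    loc: float,
    scale: float,
    noise_sd: float,
) -> np.ndarray:
    values = loc * np.exp(rng.normal(0.0, scale, size=n)) if scale > 0 else (
        np.full(n, float(loc))
    )
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=n)
    return np.maximum(values, 0.0)


def default_regions(sample_id: str, field_size: tuple[float, float]) -> RegionSet:
    """Three vertical bands: bulk | interface | non-tumoral."""
    w, h = field_size
    bands = (
        ("tumoral_bulk", 0.0, w / 3),
        ("interface", w / 3, 2 * w / 3),
        ("non_tumoral", 2 * w / 3, w),
    )
    regions = [
        (name, Polygon([(x0, 0), (x1, 0), (x1, h), (x0, h)]))
        for name, x0, x1 in bands
    ]
    return RegionSet(sample_id=sample_id, regions=regions)


def _simulate_sample(
    config: CohortConfig, sample_id: str, group: str
) -> tuple[CellTable, pd.DataFrame]:
    rng = _substream(config.seed, "sample", sample_id)
    w, h = config.field_size
    n = config.cells_per_sample

    phenos = list(config.phenotype_proportions)
    probs = np.array([config.phenotype_proportions[p] for p in phenos])
    counts = rng.multinomial(n, probs)
    phenotype = np.repeat(phenos, counts)

    # uniform placement everywhere; CD8 cells may be re-placed below
    xy = rng.uniform((0, 0), (w, h), size=(n, 2))

    # functional flags
    is_ec = phenotype == "BloodVessel"
    is_cd8 = phenotype == "CytotoxicT"
    vcam1 = is_ec & (rng.uniform(size=n) < config.inflamed_fraction)
    sting = vcam1 & (rng.uniform(size=n) < config.sting_given_inflamed)
    pd1 = is_cd8 & (rng.uniform(size=n) < config.pd1_fraction)
    grzb = is_cd8 & (rng.uniform(size=n) < config.grzb_fraction)

    # planted proximity: some CD8 cells land near a random inflamed EC
    pi = float(config.proximity_prob.get(group, 0.0))
    inflamed_idx = np.flatnonzero(vcam1)
    if pi > 0 and inflamed_idx.size:
        near = is_cd8 & (rng.uniform(size=n) < pi)
        k = int(near.sum())
        if k:
            anchors = xy[rng.choice(inflamed_idx, size=k, replace=True)]
            offs = rng.normal(0.0, config.proximity_sigma, size=(k, 2))
            xy[near] = np.clip(anchors + offs, (0, 0), (w, h))

    columns: dict[str, np.ndarray] = {
        "cell_id": np.array([f"{sample_id}_c{i}" for i in range(n)]),
        "x": xy[:, 0],
        "y": xy[:, 1],
        "nuclear_size": np.maximum(
            rng.normal(config.nuclear_size_mean, 8.0, size=n), 1.0
        ),
    }

    on_markers = {p: set(m) for p, m in DEFAULT_PHENOTYPE_RULES.items()}
    flag_state = {"VCAM1": vcam1, "STING": sting, "PD1": pd1, "GrzB": grzb}
    for marker in LINEAGE_MARKERS + FUNCTIONAL_MARKERS:
        if marker in flag_state:
            on = flag_state[marker]
        else:
            on = np.array([marker in on_markers[p] for p in phenotype])
        values = np.empty(n)
        loc_on, scale_on = config.marker_model[(marker, "on")]
        loc_off, scale_off = config.marker_model[(marker, "off")]
        values[on] = _draw_mfi(rng, int(on.sum()), loc_on, scale_on,
                               config.noise_sd)
        values[~on] = _draw_mfi(rng, int((~on).sum()), loc_off, scale_off,
                                config.noise_sd)
        columns[marker] = values

    table = CellTable(sample_id=sample_id, df=pd.DataFrame(columns),
                      group=group)
    truth = pd.DataFrame(
        {
            "sample_id": sample_id,
            "cell_id": columns["cell_id"],
            "phenotype": phenotype,
            "VCAM1": vcam1,
            "STING": sting,
            "PD1": pd1,
            "GrzB": grzb,
        }
    )
    return table, truth


def generate_cohort(
    config: CohortConfig,
) -> tuple[list[CellTable], list[RegionSet], GroundTruth]:
    """Simulate one multiplex cohort with planted phenotypes and proximity.

    Returns one :class:`CellTable` and one :class:`RegionSet` per sample
    plus the per-cell :class:`GroundTruth`.  Fully reproducible from
    ``config.seed``; per-sample substreams are name-keyed so adding
    samples never changes earlier ones.
    """
    min_prop = min(config.phenotype_proportions.values())
    if config.cells_per_sample * min_prop < 1:
        raise ValueError(
            "empty phenotype: cells_per_sample x smallest proportion < 1"
        )
    labels = [("R", i) for i in range(config.n_responders)] + [
        ("NR", i) for i in range(config.n_nonresponders)
    ]
    tables: list[CellTable] = []
    regions: list[RegionSet] = []
    truths: list[pd.DataFrame] = []
    groups: dict[str, str] = {}
    for group, i in labels:
        sample_id = f"{group}{i + 1}"
        table, truth = _simulate_sample(config, sample_id, group)
        tables.append(table)
        regions.append(default_regions(sample_id, config.field_size))
        truths.append(truth)
        groups[sample_id] = group
    cells = pd.concat(truths, ignore_index=True) if truths else None
    return tables, regions, GroundTruth(cells=cells, groups=groups)


# ------------------------------------------------------------- expression


def generate_expression(
    n_cells: int,
    n_genes: int,
    ec_fraction: float,
    signature: GeneSet,
    enrichment: float,
    seed: int = 0,
    dispersion: float = 0.3,
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Simulate a cells × genes count matrix with an EC-enriched gene set.

    Counts are negative-binomial (gamma-Poisson): per-gene base means are
    log-normal, a designated ``ec_fraction`` of cells has the signature
    genes' means multiplied by ``enrichment``.
    """
    if enrichment <= 0:
        raise ValueError("enrichment must be > 0")
    if not 0.0 <= ec_fraction <= 1.0:
        raise ValueError("ec_fraction outside [0,1]")
    rng = _substream(seed, "expression")
    gene_names = tuple(f"G{i}" for i in range(n_genes))
    sig_idx = [i for i, g in enumerate(gene_names) if g in set(signature.genes)]
    if set(signature.genes) - set(gene_names):
        missing = sorted(set(signature.genes) - set(gene_names))
        raise ValueError(f"signature genes outside universe: {missing[:5]}")

    cell_ids = tuple(f"cell{i}" for i in range(n_cells))
    n_ec = int(round(n_cells * ec_fraction))
    is_ec = np.zeros(n_cells, dtype=bool)
    if n_ec:
        is_ec[rng.choice(n_cells, size=n_ec, replace=False)] = True

    base = np.exp(rng.normal(np.log(5.0), 1.0, size=n_genes))
    means = np.tile(base, (n_cells, 1)) if n_cells else np.empty((0, n_genes))
    if n_cells and sig_idx:
        means[np.ix_(is_ec, sig_idx)] *= enrichment
    if n_cells:
        if dispersion > 0:
            lam = rng.gamma(1.0 / dispersion, means * dispersion)
        else:
            lam = means
        counts = rng.poisson(lam).astype(np.int64)
    else:
        counts = np.empty((0, n_genes), dtype=np.int64)

    mat = ExpressionMatrix(counts=counts, cell_ids=cell_ids,
                           gene_names=gene_names)
    truth = GroundTruth(
        cells=pd.DataFrame({"cell_id": cell_ids, "is_ec": is_ec}),
        genes=pd.DataFrame(
            {
                "gene": gene_names,
                "in_signature": [g in set(signature.genes) for g in gene_names],
            }
        ),
    )
    return mat, truth


# ----------------------------------------------------------- count panels


def generate_count_experiment(
    n_genes: int,
    n_per_group: int,
    de_fraction: float,
    planted_log2fc: float,
    dispersion: float,
    seed: int = 0,
    libsize_jitter: float = 0.2,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Two-group targeted count panel with a planted fold change.

    Returns a genes × samples DataFrame whose columns are named
    ``g1_*``/``g2_*``.  Non-DE genes share means across groups; DE genes'
    group-2 means are scaled by ``2**planted_log2fc``.  Library sizes are
    jittered ±20% by default (``libsize_jitter=0`` gives equal library
    sizes).  At ``dispersion == 0`` the matrix holds the exact
    (float) means so closed-form checks apply; otherwise counts are
    negative-binomial draws.
    """
    if not 0.0 <= de_fraction <= 1.0:
        raise ValueError("de_fraction outside [0,1]")
    if n_per_group < 2:
        raise ValueError("need >=2 samples per group")
    rng = _substream(seed, "counts")
    genes = [f"G{i}" for i in range(n_genes)]
    n_de = int(round(n_genes * de_fraction)) if planted_log2fc != 0 else 0
    is_de = np.zeros(n_genes, dtype=bool)
    if n_de:
        is_de[rng.choice(n_genes, size=n_de, replace=False)] = True

    base = np.exp(rng.normal(np.log(200.0), 1.0, size=n_genes))
    mean1 = base
    mean2 = base * np.where(is_de, 2.0 ** planted_log2fc, 1.0)

    j = float(libsize_jitter)
    lib = (rng.uniform(1 - j, 1 + j, size=2 * n_per_group) if j > 0
           else np.ones(2 * n_per_group))
    cols: dict[str, np.ndarray] = {}
    for j in range(n_per_group):
        cols[f"g1_{j}"] = mean1 * lib[j]
        cols[f"g2_{j}"] = mean2 * lib[n_per_group + j]
    matrix = pd.DataFrame(cols, index=genes)
    if dispersion > 0:
        lam = rng.gamma(1.0 / dispersion, matrix.to_numpy() * dispersion)
        matrix = pd.DataFrame(rng.poisson(lam).astype(np.int64),
                              index=genes, columns=matrix.columns)
    truth = GroundTruth(
        genes=pd.DataFrame(
            {
                "gene": genes,
                "is_de": is_de,
                "planted_log2fc": np.where(is_de, planted_log2fc, 0.0),
            }
        )
    )
    return matrix, truth


def count_groups(matrix: pd.DataFrame) -> pd.Series:
    """Group labels implied by generate_count_experiment column names."""
    return pd.Series(
        [c.split("_")[0] for c in matrix.columns], index=matrix.columns
    )
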