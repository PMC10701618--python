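"""Core in-memory containers for the multiplex-IF pipeline.

The central object is the :class:`CellTable`: one segmented-cell feature
table per tissue sample, holding coordinates in microns (image convention,
origin top-left, y increasing downward), nuclear size, and one mean
fluorescence intensity (MFI) column per marker.  Region annotations are
labeled polygons partitioning a sample into histological compartments;
gene sets and expression matrices support the signature-scoring stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

#: Lineage markers used for clustering and phenotype rules.
LINEAGE_MARKERS = ("AQP1", "CD31", "CD4", "CD8", "MelanA", "SOX10")

#: Functional markers used for positivity calls, never for clustering.
FUNCTIONAL_MARKERS = ("VCAM1", "STING", "PD1", "GrzB")

#: The four consensus phenotypes; NOS is the fallback, not a phenotype.
PHENOTYPES = ("Melanoma", "BloodVessel", "Thelper", "CytotoxicT")
NOS = "NOS"

#: Closed compartment vocabulary for region annotations.
COMPARTMENTS = ("tumoral_bulk", "interface", "non_tumoral")

#: When a cell falls inside several polygons, the first matching
#: compartment in this order wins.
COMPARTMENT_PRECEDENCE = ("interface", "tumoral_bulk", "non_tumoral")

#: Marker→phenotype rules: a cell type is called when any of its defining
#: markers scores high (OR logic).
DEFAULT_PHENOTYPE_RULES = {
    "Melanoma": ("SOX10", "MelanA"),
    "BloodVessel": ("AQP1", "CD31"),
    "Thelper": ("CD4",),
    "CytotoxicT": ("CD8",),
}

#: Which functional flags apply to which base phenotype.
FUNCTIONAL_BASE = {
    "VCAM1": "BloodVessel",
    "STING": "BloodVessel",
    "PD1": "CytotoxicT",
    "GrzB": "CytotoxicT",
}

META_COLUMNS = ("cell_id", "x", "y", "nuclear_size")


class CellTableError(ValueError):
    """Raised when a cell table violates its structural invariants."""


@dataclass
class CellTable:
    """Per-sample segmented-cell feature table.

    Parameters
    ----------
    sample_id
        Identifier of the tissue sample (core).
    df
        DataFrame with columns ``cell_id, x, y, nuclear_size`` plus one
        numeric MFI column per marker.  Coordinates are microns.
    group
        Response group: ``"R"``, ``"NR"`` or ``"unknown"``.
    """

    sample_id: str
    df: pd.DataFrame
    group: str = "unknown"

    def __post_init__(self) -> None:
        missing = [c for c in META_COLUMNS if c not in self.df.columns]
        if missing:
            raise CellTableError(
                f"cell table {self.sample_id!r} missing required column(s): "
                + ", ".join(missing)
            )
        ids = self.df["cell_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise CellTableError(
                f"duplicate cell_id {dup!r} in sample {self.sample_id!r}"
            )
        coords = self.df[["x", "y"]].to_numpy(dtype=float)
        if not np.isfinite(coords).all():
            raise CellTableError(
                f"non-finite coordinates in sample {self.sample_id!r}"
            )
        if self.group not in ("R", "NR", "unknown"):
            raise CellTableError(f"unknown group {self.group!r}")

    @property
    def markers(self) -> tuple[str, ...]:
        return tuple(c for c in self.df.columns if c not in META_COLUMNS)

    @property
    def n_cells(self) -> int:
        return len(self.df)

    def marker_matrix(self, markers: Sequence[str] | None = None) -> np.ndarray:
        """Dense (cells × markers) MFI matrix in the given marker order."""
        use = tuple(markers) if markers is not None else self.markers
        missing = [m for m in use if m not in self.df.columns]
        if missing:
            raise CellTableError(
                f"marker(s) not in table {self.sample_id!r}: " + ", ".join(missing)
            )
        return self.df[list(use)].to_numpy(dtype=float)

    def coordinates(self) -> np.ndarray:
        return self.df[["x", "y"]].to_numpy(dtype=float)


@dataclass
class RegionSet:
    """Labeled polygons partitioning one sample into compartments."""

    sample_id: str
    regions: list[tuple[str, Polygon]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for compartment, poly in self.regions:
            if compartment not in COMPARTMENTS:
                raise ValueError(
                    f"unknown compartment {compartment!r}; expected one of "
                    + ", ".join(COMPARTMENTS)
                )
            if len(poly.exterior.coords) - 1 < 3:
                raise ValueError("polygon needs at least 3 vertices")

    def compartments_present(self) -> set[str]:
        return {c for c, _ in self.regions}


@dataclass
class GeneSet:
    """Named, ordered collection of unique gene symbols."""

    name: str
    genes: tuple[str, ...]
    description: str = ""

    def __post_init__(self) -> None:
        # empty sets are legal (a threshold rule may select nothing);
        # duplicates are not
        self.genes = tuple(self.genes)
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.name!r} has duplicate symbols")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterable[str]:
        return iter(self.genes)


@dataclass
class ExpressionMatrix:
    """Cells × genes nonnegative count matrix with id lists.

    ``counts`` may be dense ndarray or scipy sparse; rows are cells.
    """

    counts: object
    cell_ids: tuple[str, ...]
    gene_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.cell_ids = tuple(self.cell_ids)
        self.gene_names = tuple(self.gene_names)
        n, g = self.counts.shape
        if n != len(self.cell_ids) or g != len(self.gene_names):
            raise ValueError(
                f"matrix shape {self.counts.shape} does not match "
                f"{len(self.cell_ids)} cells × {len(self.gene_names)} genes"
            )
        if self.dense().size and self.dense().min() < 0:
            raise ValueError("negative entries in count matrix")

    def dense(self) -> np.ndarray:
        arr = self.counts
        if hasattr(arr, "toarray"):
            arr = arr.toarray()
        return np.asarray(arr, dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape
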