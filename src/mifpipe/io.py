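"""Readers and writers for the pipeline's on-disk formats.

Formats: cell tables and count matrices as UTF-8 comma-separated CSV
(header mandatory, ``.`` decimal), region annotations as GeoJSON
FeatureCollections with a ``compartment`` property, gene sets as GMT,
expression matrices as MatrixMarket (MTX) with companion gene/cell name
files, and run configuration as YAML.
"""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml
from shapely.geometry import Polygon, mapping, shape

from .datatypes import (
    META_COLUMNS,
    CellTable,
    CellTableError,
    ExpressionMatrix,
    GeneSet,
    RegionSet,
)

log = logging.getLogger("mifpipe")


def setup_logging(level: str = "INFO") -> None:
    """One structured stderr line per pipeline stage."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
    )
    log.handlers[:] = [handler]
    log.setLevel(level.upper())


# ---------------------------------------------------------------- cell tables


def read_cell_table(
    path: str | Path,
    marker_manifest: Sequence[str] | None = None,
    sample_id: str | None = None,
    group: str = "unknown",
) -> CellTable:
    """Read one sample's cell table from CSV.

    Required columns: ``cell_id, x, y, nuclear_size`` plus one column per
    manifest marker.  Missing columns, duplicate cell ids and non-numeric
    MFI values are rejected with informative errors.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"cell_id": str})
    required = list(META_COLUMNS) + list(marker_manifest or [])
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CellTableError(
            f"{path.name}: missing required column(s): " + ", ".join(missing)
        )
    value_cols = [c for c in df.columns if c != "cell_id"]
    for col in value_cols:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise CellTableError(
                f"{path.name}: non-numeric value in column {col!r} at row {row}"
            )
        df[col] = numeric.astype(float)
    table = CellTable(
        sample_id=sample_id if sample_id is not None else path.stem,
        df=df,
        group=group,
    )
    log.info("read_cell_table %s rows=%d markers=%d", path, table.n_cells,
             len(table.markers))
    return table


def write_cell_table(table: CellTable, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    # %.17g round-trips float64 exactly, so write∘read is the identity
    table.df.to_csv(path, index=False, float_format="%.17g")
    log.info("write_cell_table %s rows=%d", path, table.n_cells)


# -------------------------------------------------------------------- regions


def read_regions(path: str | Path, sample_id: str | None = None) -> RegionSet:
    """Read compartment polygons from a GeoJSON FeatureCollection.

    Every feature must carry a ``compartment`` property from the closed
    vocabulary; unknown labels raise a vocabulary error.
    """
    path = Path(path)
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise ValueError(f"{path.name}: expected a GeoJSON FeatureCollection")
    regions: list[tuple[str, Polygon]] = []
    for feat in doc.get("features", []):
        props = feat.get("properties") or {}
        compartment = props.get("compartment")
        if compartment is None:
            raise ValueError(f"{path.name}: feature lacks 'compartment' property")
        geom = shape(feat["geometry"])
        if geom.geom_type != "Polygon":
            raise ValueError(
                f"{path.name}: unsupported geometry {geom.geom_type!r}"
            )
        regions.append((compartment, geom))
    rset = RegionSet(
        sample_id=sample_id or doc.get("sample_id") or path.stem,
        regions=regions,
    )
    log.info("read_regions %s polygons=%d", path, len(rset.regions))
    return rset


def write_regions(rset: RegionSet, path: str | Path) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {"compartment": compartment},
            "geometry": mapping(poly),
        }
        for compartment, poly in rset.regions
    ]
    doc = {
        "type": "FeatureCollection",
        "sample_id": rset.sample_id,
        "features": features,
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(doc, fh)


# ------------------------------------------------------------------ gene sets


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file: ``name TAB description TAB gene1 TAB gene2 ...``."""
    path = Path(path)
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path.name}:{lineno}: GMT line needs >=3 tab-separated "
                    f"fields, got {len(fields)}"
                )
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            sets.append(GeneSet(name=name, genes=tuple(genes), description=desc))
    return sets


def write_gmt(gene_sets: Sequence[GeneSet], path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for gs in gene_sets:
            fh.write("\t".join([gs.name, gs.description or "na", *gs.genes]) + "\n")


# ----------------------------------------------------------------- expression


def read_mtx(directory: str | Path) -> ExpressionMatrix:
    """Read a cells × genes MTX directory.

    Expects ``matrix.mtx`` plus one-name-per-line ``genes.txt`` and
    ``cells.txt`` companions.
    """
    directory = Path(directory)
    counts = scipy.io.mmread(directory / "matrix.mtx").tocsr()
    genes = (directory / "genes.txt").read_text().split()
    cells = (directory / "cells.txt").read_text().split()
    mat = ExpressionMatrix(counts=counts, cell_ids=tuple(cells),
                           gene_names=tuple(genes))
    log.info("read_mtx %s cells=%d genes=%d", directory, *mat.shape)
    return mat


def write_mtx(mat: ExpressionMatrix, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sparse = scipy.sparse.csr_matrix(mat.counts)
    scipy.io.mmwrite(directory / "matrix.mtx", sparse)
    (directory / "genes.txt").write_text("\n".join(mat.gene_names) + "\n")
    (directory / "cells.txt").write_text("\n".join(mat.cell_ids) + "\n")


# --------------------------------------------------------------------- config


def read_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def write_config(config: dict, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
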