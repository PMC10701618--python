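"""Compartments, functional positivity calls, and neighborhood curves.

Cells are assigned to pathology compartments (tumoral bulk, tumor–stroma
interface, non-tumoral) by point-in-polygon tests; inflamed vessels and
activated T cells are called by a cutoff on normalized marker intensity;
compartmental abundances are compared between responders and
non-responders by two-sided Wilcoxon rank-sum tests (unadjusted); and
vessel↔T-cell proximity is summarized as neighborhood curves — for each
radius r, the mean number of target cells within r of a reference cell —
compared between groups radius-by-radius with two-sided t-tests.

Curves use the cumulative (≤ r) convention, so they are monotone
nondecreasing in radius and plateau at the total target count.  Edge
effects are not corrected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from scipy import stats
from scipy.spatial import cKDTree

from .datatypes import (
    COMPARTMENT_PRECEDENCE,
    FUNCTIONAL_BASE,
    CellTable,
    RegionSet,
)

UNASSIGNED = "unassigned"

#: Default radius grid: 0–300 μm in 10 μm steps (0 excluded: radii > 0).
DEFAULT_RADII = tuple(float(r) for r in range(10, 310, 10))


def assign_compartment(cells: pd.DataFrame, regions: RegionSet) -> pd.Series:
    """Assign each cell to a compartment by point-in-polygon.

    Boundary points count as inside.  A cell falling in polygons of
    several compartments takes the first by the fixed precedence
    interface > tumoral_bulk > non_tumoral; a cell outside all polygons
    is ``"unassigned"``.
    """
    for compartment, poly in regions.regions:
        if not poly.is_valid:
            raise ValueError(
                f"invalid (self-intersecting?) polygon for {compartment!r} "
                f"in sample {regions.sample_id!r}"
            )
    points = shapely.points(cells[["x", "y"]].to_numpy(dtype=float))
    out = np.full(len(cells), UNASSIGNED, dtype=object)
    for compartment in reversed(COMPARTMENT_PRECEDENCE):
        for comp, poly in regions.regions:
            if comp != compartment:
                continue
            inside = shapely.covers(poly, points)
            out[inside] = compartment
    return pd.Series(out, index=cells.index, name="compartment")


def call_positive(
    cells: pd.DataFrame,
    marker: str,
    cutoff_z: float = 1.0,
    phenotype: pd.Series | None = None,
    base_phenotype: str | None = None,
) -> pd.Series:
    """Flag cells positive for a functional marker on normalized data.

    A cell is positive when its trimmed z-score is ≥ ``cutoff_z`` AND its
    base phenotype matches the marker's applicable type (VCAM1/STING →
    BloodVessel, PD1/GrzB → CytotoxicT), so e.g. a melanoma cell can
    never be called VCAM1+.
    """
    if marker not in cells.columns:
        raise ValueError(f"marker {marker!r} not present in cell table")
    flag = cells[marker].to_numpy(dtype=float) >= cutoff_z
    base = base_phenotype or FUNCTIONAL_BASE.get(marker)
    if phenotype is None and "phenotype" in cells.columns:
        phenotype = cells["phenotype"]
    if base is not None and phenotype is not None:
        flag = flag & (phenotype.to_numpy() == base)
    return pd.Series(flag, index=cells.index, name=f"{marker}_pos")


def cytometry_enrichment(
    counts: pd.DataFrame,
    groups: Mapping[str, str],
) -> pd.DataFrame:
    """Responder vs non-responder abundance test per compartment.

    ``counts`` holds one row per (sample_id, compartment) with a
    ``count`` column.  Each compartment gets a two-sided Wilcoxon
    rank-sum (Mann-Whitney U) test of R vs NR per-sample counts;
    p-values are deliberately not adjusted for multiple comparisons.
    """
    df = counts.copy()
    df["group"] = df["sample_id"].map(dict(groups))
    rows = []
    for compartment, sub in df.groupby("compartment", sort=True):
        r = sub.loc[sub["group"] == "R", "count"].to_numpy(dtype=float)
        nr = sub.loc[sub["group"] == "NR", "count"].to_numpy(dtype=float)
        for name, vals in (("R", r), ("NR", nr)):
            if vals.size == 0:
                raise ValueError(
                    f"group {name!r} has no samples in compartment "
                    f"{compartment!r}"
                )
        stat, p = stats.mannwhitneyu(r, nr, alternative="two-sided",
                                     method="auto")
        rows.append({"compartment": compartment, "statistic": float(stat),
                     "p_value": float(p)})
    return pd.DataFrame(rows)


@dataclass
class NeighborhoodCurve:
    """Mean target-cell count within each radius of a reference cell."""

    sample_id: str
    reference: str
    target: str
    radii: np.ndarray
    values: np.ndarray


def neighborhood_curve(
    reference_xy: np.ndarray,
    target_xy: np.ndarray,
    radii: Sequence[float] = DEFAULT_RADII,
    cumulative: bool = True,
) -> np.ndarray:
    """Mean number of target cells within radius r of a reference cell.

    For each radius: ``mean over reference cells of #{targets at
    Euclidean distance ≤ r}``.  Reference and target populations are
    disjoint subtypes, so self-pairs cannot occur.  With
    ``cumulative=False`` the per-bin increments are returned instead.
    """
    radii = np.asarray(radii, dtype=float)
    if radii.size == 0 or np.any(radii <= 0) or np.any(np.diff(radii) <= 0):
        raise ValueError("radii must be strictly increasing and positive")
    reference_xy = np.asarray(reference_xy, dtype=float).reshape(-1, 2)
    target_xy = np.asarray(target_xy, dtype=float).reshape(-1, 2)
    if reference_xy.shape[0] == 0:
        warnings.warn("no reference cells; neighborhood curve is NaN",
                      stacklevel=2)
        return np.full(radii.size, np.nan)
    if target_xy.shape[0] == 0:
        values = np.zeros(radii.size)
    else:
        ref_tree = cKDTree(reference_xy)
        tgt_tree = cKDTree(target_xy)
        pairs = ref_tree.count_neighbors(tgt_tree, radii)
        values = pairs.astype(float) / reference_xy.shape[0]
    if not cumulative:
        values = np.diff(values, prepend=0.0)
    return values


def sample_curves(
    cells_by_sample: Mapping[str, pd.DataFrame],
    reference_mask: Mapping[str, np.ndarray],
    target_mask: Mapping[str, np.ndarray],
    radii: Sequence[float] = DEFAULT_RADII,
    reference: str = "reference",
    target: str = "target",
) -> list[NeighborhoodCurve]:
    """One neighborhood curve per sample from boolean subtype masks."""
    curves = []
    for sample_id, df in cells_by_sample.items():
        xy = df[["x", "y"]].to_numpy(dtype=float)
        curves.append(
            NeighborhoodCurve(
                sample_id=sample_id,
                reference=reference,
                target=target,
                radii=np.asarray(radii, dtype=float),
                values=neighborhood_curve(
                    xy[np.asarray(reference_mask[sample_id], dtype=bool)],
                    xy[np.asarray(target_mask[sample_id], dtype=bool)],
                    radii,
                ),
            )
        )
    return curves


def compare_curves(
    curves: Sequence[NeighborhoodCurve],
    groups: Mapping[str, str],
) -> pd.DataFrame:
    """Two-sided Student's t-test of R vs NR curve values at each radius.

    Per-sample curve values are compared across groups radius by radius;
    no multiplicity adjustment is applied.  Degenerate radii where both
    groups have zero variance give p = 1 on equal means and p = 0
    (reported below any threshold) on unequal means.
    """
    radii = curves[0].radii
    table = pd.DataFrame(
        {c.sample_id: c.values for c in curves}, index=radii
    ).T
    grp = pd.Series({s: groups[s] for s in table.index})
    r_vals = table.loc[grp == "R"].to_numpy(dtype=float)
    nr_vals = table.loc[grp == "NR"].to_numpy(dtype=float)
    if r_vals.shape[0] < 2 or nr_vals.shape[0] < 2:
        raise ValueError("need >=2 samples per group at each radius")
    rows = []
    for j, r in enumerate(radii):
        a, b = r_vals[:, j], nr_vals[:, j]
        if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
            t = np.inf if a.mean() != b.mean() else 0.0
            p = 0.0 if a.mean() != b.mean() else 1.0
        else:
            t, p = stats.ttest_ind(a, b, equal_var=True)
        rows.append({"radius": float(r), "t": float(t), "p_value": float(p),
                     "mean_R": float(a.mean()), "mean_NR": float(b.mean())})
    return pd.DataFrame(rows)
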