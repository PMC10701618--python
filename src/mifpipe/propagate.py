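"""Label transfer from the clustered subset to every cell.

A 2D reference embedding is fitted on up to 500 consensus-labeled cells
per phenotype; every cell is projected into that space and receives the
majority label of its 100 nearest reference cells.  The default embedding
is a deterministic supervised 2D linear map: the lineage markers are
whitened in the linear-discriminant space of the reference labels, and
the 2D plane retaining the largest minimum pairwise class-mean separation
is selected by a fixed spherical search.  Because four class means span
three dimensions, an unsupervised 2D projection (PCA) necessarily
collapses one phenotype contrast — typically CD4 vs CD8 T cells — which
is why the label-aware map is the default.  PCA and a stochastic
neighbor embedding (UMAP) remain available behind the same transform
contract, which keeps the kNN-majority vote testable independently of
embedding stochasticity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.neighbors import NearestNeighbors

from .datatypes import LINEAGE_MARKERS, NOS


def _fibonacci_sphere(n: int = 4000) -> np.ndarray:
    """Deterministic quasi-uniform unit vectors on S^2."""
    i = np.arange(n)
    golden = (1 + 5**0.5) / 2
    z = 1 - 2 * (i + 0.5) / n
    r = np.sqrt(1 - z * z)
    theta = 2 * np.pi * i / golden
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


class DiscriminantMap2D:
    """Supervised, deterministic 2D linear projection.

    Fits class-whitened discriminant axes (≤ n_classes − 1), then — when
    three axes exist — drops the direction whose removal best preserves
    the minimum pairwise class-mean separation, found by scanning a
    fixed Fibonacci grid of candidate plane normals.  Fewer than two
    discriminant axes are zero-padded to 2D.
    """

    def fit(self, X: np.ndarray, y: np.ndarray) -> "DiscriminantMap2D":
        classes = np.unique(y)
        if classes.size < 2:
            self._lda = None
            self._pca = PCA(n_components=min(2, X.shape[1])).fit(X)
            self._basis = None
            return self
        n_comp = min(3, classes.size - 1, X.shape[1])
        self._lda = LinearDiscriminantAnalysis(n_components=n_comp).fit(X, y)
        self._pca = None
        Z = self._lda.transform(X)
        if Z.shape[1] <= 2:
            self._basis = None
            return self
        means = np.array([Z[y == c].mean(axis=0) for c in classes])
        diffs = np.array(
            [means[i] - means[j]
             for i in range(len(means)) for j in range(i + 1, len(means))]
        )
        best_sep, best_normal = -np.inf, None
        for normal in _fibonacci_sphere():
            kept = np.sqrt(
                np.maximum((diffs**2).sum(axis=1) - (diffs @ normal) ** 2, 0)
            )
            sep = kept.min()
            if sep > best_sep:
                best_sep, best_normal = sep, normal
        u, _, _ = np.linalg.svd(np.eye(3) - np.outer(best_normal, best_normal))
        self._basis = u[:, :2]
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self._lda is None:
            emb = self._pca.transform(X)
        else:
            emb = self._lda.transform(X)
            if self._basis is not None:
                emb = emb @ self._basis
        if emb.shape[1] < 2:
            emb = np.column_stack([emb, np.zeros((emb.shape[0], 2 - emb.shape[1]))])
        return emb


@dataclass
class ReferenceEmbedding:
    """Fitted 2D map plus the labeled reference cells that vote."""

    markers: tuple[str, ...]
    model: object
    ref_points: np.ndarray  # reference cells in embedding space
    ref_labels: np.ndarray
    k: int = 100

    def transform(self, matrix: np.ndarray) -> np.ndarray:
        return np.asarray(self.model.transform(matrix), dtype=float)


def build_reference_embedding(
    labeled: pd.DataFrame,
    per_type: int = 500,
    method: str = "discriminant",
    seed: int = 0,
    k: int = 100,
    markers: Sequence[str] = LINEAGE_MARKERS,
    include_nos: bool = False,
    label_column: str = "phenotype",
) -> ReferenceEmbedding:
    """Fit the 2D reference map on a per-type sample of labeled cells.

    Samples ``min(per_type, available)`` cells per phenotype (NOS is
    excluded by default), fits a 2D projection on the lineage markers,
    and stores everything needed to project new cells.
    """
    if labeled.empty:
        raise ValueError("no labeled cells to build a reference from")
    pool = labeled if include_nos else labeled[labeled[label_column] != NOS]
    if pool.empty:
        raise ValueError("no labeled cells left after excluding NOS")
    rng = np.random.default_rng(seed)
    picks = []
    for _, group in pool.groupby(label_column, sort=True):
        take = min(per_type, len(group))
        picks.append(group.iloc[
            np.sort(rng.choice(len(group), size=take, replace=False))
        ])
    ref = pd.concat(picks, ignore_index=True)
    X = ref[list(markers)].to_numpy(dtype=float)

    if method == "discriminant":
        model = DiscriminantMap2D().fit(X, ref[label_column].to_numpy())
    elif method == "pca":
        model = PCA(n_components=min(2, X.shape[1]), random_state=int(seed))
        model.fit(X)
    elif method in ("umap", "neighbor-embedding"):
        import umap  # optional dependency

        model = umap.UMAP(n_components=2, random_state=int(seed))
        model.fit(X)
    else:
        raise ValueError(f"unknown embedding method {method!r}")
    return ReferenceEmbedding(
        markers=tuple(markers),
        model=model,
        ref_points=np.asarray(model.transform(X), dtype=float),
        ref_labels=ref[label_column].to_numpy(),
        k=k,
    )


def knn_majority(
    query: np.ndarray,
    ref_points: np.ndarray,
    ref_labels: np.ndarray,
    k: int,
) -> np.ndarray:
    """Majority vote of the k nearest reference points (Euclidean).

    Ties between labels are broken by the label of the single nearest
    neighbor among the tied labels, which is deterministic and
    distance-respecting.
    """
    if query.shape[0] == 0:
        return np.array([], dtype=ref_labels.dtype)
    n_ref = ref_points.shape[0]
    if k > n_ref:
        warnings.warn(
            f"k={k} exceeds reference size {n_ref}; lowering k to {n_ref}",
            stacklevel=2,
        )
        k = n_ref
    nn = NearestNeighbors(n_neighbors=k).fit(ref_points)
    _, idx = nn.kneighbors(query)  # rows sorted by distance
    out = np.empty(query.shape[0], dtype=object)
    for i, row in enumerate(idx):
        labels = ref_labels[row]
        uniq, counts = np.unique(labels, return_counts=True)
        top = counts.max()
        tied = set(uniq[counts == top])
        if len(tied) == 1:
            out[i] = next(iter(tied))
        else:
            # first neighbor (closest) whose label is among the tied ones
            out[i] = next(lab for lab in labels if lab in tied)
    return out


def propagate_labels(
    cells: pd.DataFrame,
    ref: ReferenceEmbedding,
) -> pd.Series:
    """Project all cells into the reference map and kNN-majority label them."""
    if cells.empty:
        return pd.Series([], dtype=object, name="phenotype")
    X = cells[list(ref.markers)].to_numpy(dtype=float)
    emb = ref.transform(X)
    labels = knn_majority(emb, ref.ref_points, ref.ref_labels, ref.k)
    return pd.Series(labels, index=cells.index, name="phenotype")
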