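"""Consensus phenotyping of a stratified cell subset.

Three independent clusterings are run on the six lineage markers of a
stratified proportional random sample of cells (default 2,500): a kNN
graph with Jaccard-weighted edges partitioned by Louvain-style modularity
maximization, a self-organizing map whose nodes are meta-clustered by
Ward linkage, and k-means.  The graph method chooses its own number of
communities; that count is then handed to the SOM and k-means.  Each
method's clusters are mapped to phenotypes by a marker-score rule, and a
cell keeps a phenotype only when at least two methods agree; otherwise it
is "not otherwise specified" (NOS).
"""

from __future__ import annotations

from collections import Counter
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import networkx as nx
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans
from sklearn.neighbors import NearestNeighbors

from .datatypes import (
    DEFAULT_PHENOTYPE_RULES,
    LINEAGE_MARKERS,
    NOS,
    CellTable,
)

VOTE_COLUMNS = ("vote_graph", "vote_som", "vote_kmeans")


def pool_tables(tables: Sequence[CellTable]) -> pd.DataFrame:
    """Stack samples into one cell pool with a ``sample_id`` column."""
    frames = []
    for t in tables:
        df = t.df.copy()
        df.insert(0, "sample_id", t.sample_id)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def stratified_sample(
    pool: pd.DataFrame,
    n: int = 2500,
    strata: str = "sample_id",
    seed: int = 0,
) -> pd.DataFrame:
    """Stratified proportional random sample of cells, without replacement.

    Per-stratum allocation is proportional to stratum size with
    largest-remainder rounding; the total is ``min(n, len(pool))``.
    """
    if pool.empty:
        raise ValueError("empty cell pool")
    total = len(pool)
    n_take = min(n, total)
    sizes = pool.groupby(strata, sort=True).size()
    quota = n_take * sizes / total
    alloc = np.floor(quota).astype(int)
    remainder = quota - alloc
    short = n_take - int(alloc.sum())
    if short > 0:
        # stable tie-break: largest remainder first, then stratum order
        order = np.lexsort((np.arange(len(sizes)), -remainder.to_numpy()))
        for i in order[:short]:
            alloc.iloc[i] += 1
    rng = np.random.default_rng(seed)
    picks = []
    for stratum, k in alloc.items():
        idx = pool.index[pool[strata] == stratum].to_numpy()
        if k > 0:
            picks.append(rng.choice(idx, size=min(k, idx.size), replace=False))
    chosen = np.sort(np.concatenate(picks)) if picks else np.array([], dtype=int)
    return pool.loc[chosen]


# ------------------------------------------------------------- clusterings


def cluster_graph(
    matrix: np.ndarray, k_neighbors: int = 20, seed: int = 0
) -> np.ndarray:
    """Jaccard-weighted kNN-graph community detection.

    Builds a Euclidean kNN graph, weights each edge by the Jaccard
    overlap of the two endpoints' neighbor sets, and partitions it by
    Louvain modularity maximization.  Returns integer cluster ids.
    """
    n = matrix.shape[0]
    if n == 0:
        return np.array([], dtype=int)
    if np.allclose(matrix, matrix[0]):
        return np.zeros(n, dtype=int)  # degenerate: all cells identical
    k = min(k_neighbors, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(matrix)
    _, idx = nn.kneighbors(matrix)
    neigh = [set(row[1:]) for row in idx]  # drop self
    G = nx.Graph()
    G.add_nodes_from(range(n))
    for i in range(n):
        for j in neigh[i]:
            if G.has_edge(i, j):
                continue
            inter = len(neigh[i] & neigh[j])
            union = len(neigh[i] | neigh[j])
            if union and inter:
                G.add_edge(i, int(j), weight=inter / union)
    communities = nx.community.louvain_communities(G, weight="weight",
                                                   seed=int(seed))
    labels = np.empty(n, dtype=int)
    for cid, members in enumerate(communities):
        labels[list(members)] = cid
    return labels


def cluster_kmeans(
    matrix: np.ndarray, n_clusters: int, seed: int = 0
) -> np.ndarray:
    """k-means with k-means++ initialization and 10 restarts."""
    if n_clusters > matrix.shape[0]:
        raise ValueError(
            f"n_clusters={n_clusters} exceeds number of cells {matrix.shape[0]}"
        )
    km = KMeans(n_clusters=n_clusters, init="k-means++", n_init=10,
                random_state=int(seed))
    return km.fit_predict(matrix)


def _train_som(
    matrix: np.ndarray,
    grid: tuple[int, int],
    seed: int,
    epochs: int = 20,
) -> np.ndarray:
    """Batch-train a rectangular SOM; returns node weights (nodes × dims)."""
    rng = np.random.default_rng(seed)
    rows, cols = grid
    n_nodes = rows * cols
    gy, gx = np.divmod(np.arange(n_nodes), cols)
    grid_pos = np.column_stack([gy, gx]).astype(float)
    # init from random data points
    init_idx = rng.choice(matrix.shape[0], size=n_nodes,
                          replace=matrix.shape[0] < n_nodes)
    weights = matrix[init_idx].astype(float).copy()
    sigma0 = max(rows, cols) / 2.0
    for epoch in range(epochs):
        sigma = sigma0 * (0.05 / sigma0) ** (epoch / max(epochs - 1, 1))
        d2 = ((matrix[:, None, :] - weights[None, :, :]) ** 2).sum(axis=2)
        bmu = d2.argmin(axis=1)
        # Gaussian neighborhood on the grid around each BMU
        gdist2 = ((grid_pos[:, None, :] - grid_pos[None, :, :]) ** 2).sum(axis=2)
        h = np.exp(-gdist2 / (2.0 * sigma**2))  # nodes × nodes
        influence = h[bmu]  # cells × nodes
        denom = influence.sum(axis=0)
        num = influence.T @ matrix
        nonzero = denom > 1e-12
        weights[nonzero] = num[nonzero] / denom[nonzero, None]
    return weights


def cluster_som(
    matrix: np.ndarray,
    n_clusters: int,
    seed: int = 0,
    grid: tuple[int, int] = (8, 8),
) -> np.ndarray:
    """SOM followed by hierarchical meta-clustering of the nodes.

    Trains a rectangular self-organizing map, Ward-links the node
    weights into ``n_clusters`` meta-clusters, and assigns each cell the
    meta-cluster of its best-matching node.
    """
    n = matrix.shape[0]
    if n_clusters > n:
        raise ValueError(
            f"n_clusters={n_clusters} exceeds number of cells {n}"
        )
    if n_clusters == 1:
        return np.zeros(n, dtype=int)
    weights = _train_som(matrix, grid, seed)
    # collapse duplicate nodes to keep the linkage well posed
    Z = linkage(weights, method="ward")
    node_meta = fcluster(Z, t=n_clusters, criterion="maxclust") - 1
    d2 = ((matrix[:, None, :] - weights[None, :, :]) ** 2).sum(axis=2)
    bmu = d2.argmin(axis=1)
    labels = node_meta[bmu]
    # ensure every requested cluster id appears at most; relabel compactly
    _, compact = np.unique(labels, return_inverse=True)
    return compact


# ------------------------------------------------------------- annotation


def annotate_clusters(
    cluster_ids: np.ndarray,
    matrix: np.ndarray,
    marker_names: Sequence[str],
    rules: Mapping[str, Sequence[str]] | None = None,
    tau: float = 0.5,
) -> dict[int, str]:
    """Map clusters to phenotypes by their mean normalized marker scores.

    A phenotype's score for a cluster is the max cluster-mean z over its
    defining markers (OR logic).  The cluster gets the argmax phenotype
    when that score is at least ``tau``; ties and sub-threshold scores
    give NOS.
    """
    rules = dict(rules or DEFAULT_PHENOTYPE_RULES)
    name_to_col = {m: i for i, m in enumerate(marker_names)}
    for phenotype, markers in rules.items():
        unknown = [m for m in markers if m not in name_to_col]
        if unknown:
            raise ValueError(
                f"rule {phenotype!r} references unknown marker(s): "
                + ", ".join(unknown)
            )
    mapping: dict[int, str] = {}
    for cid in np.unique(cluster_ids):
        centroid = matrix[cluster_ids == cid].mean(axis=0)
        scores = {
            ph: max(centroid[name_to_col[m]] for m in markers)
            for ph, markers in rules.items()
        }
        best = max(scores.values())
        winners = [ph for ph, s in scores.items() if s == best]
        if best < tau or len(winners) != 1:
            mapping[int(cid)] = NOS
        else:
            mapping[int(cid)] = winners[0]
    return mapping


def consensus_vote(votes: Sequence[str]) -> str:
    """Majority label of exactly three votes; no majority → NOS.

    NOS itself counts as a vote value, so (NOS, NOS, X) → NOS.
    """
    if len(votes) != 3:
        raise ValueError(f"expected exactly 3 votes, got {len(votes)}")
    label, count = Counter(votes).most_common(1)[0]
    return label if count >= 2 else NOS


# ------------------------------------------------------------ orchestrator


def consensus_phenotype(
    tables: Sequence[CellTable],
    n_sample: int = 2500,
    k_neighbors: int = 20,
    tau: float = 0.5,
    seed: int = 0,
    rules: Mapping[str, Sequence[str]] | None = None,
    markers: Sequence[str] = LINEAGE_MARKERS,
    som_grid: tuple[int, int] = (8, 8),
) -> pd.DataFrame:
    """Run the full consensus phenotyping stage on normalized samples.

    Returns one row per sampled cell: ``sample_id, cell_id``, the three
    method votes, and the consensus ``phenotype``.  The community count
    found by the graph method is passed to SOM and k-means.
    """
    pool = pool_tables(tables)
    subset = stratified_sample(pool, n=n_sample, seed=seed)
    X = subset[list(markers)].to_numpy(dtype=float)

    labels_graph = cluster_graph(X, k_neighbors=k_neighbors, seed=seed)
    n_clusters = int(len(np.unique(labels_graph)))
    labels_som = cluster_som(X, n_clusters, seed=seed, grid=som_grid)
    labels_km = cluster_kmeans(X, n_clusters, seed=seed)

    out = subset[["sample_id", "cell_id"]].copy().reset_index(drop=True)
    for col, labels in zip(
        VOTE_COLUMNS, (labels_graph, labels_som, labels_km)
    ):
        ann = annotate_clusters(labels, X, markers, rules=rules, tau=tau)
        out[col] = [ann[int(c)] for c in labels]
    out["phenotype"] = [
        consensus_vote(v) for v in out[list(VOTE_COLUMNS)].itertuples(index=False)
    ]
    return out
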