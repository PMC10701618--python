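"""Inflammatory-signature derivation and per-cell gene-set scoring.

Two-group targeted count panels are tested gene-by-gene (total-count
normalization, log2(x+1), Welch t-test); the inflammatory signature is
the genes passing the thresholds log2FC ≥ 0.7 and p < 0.05.  Single
cells are then scored for a gene set by a rank-recovery AUC: genes are
ranked per cell by descending expression and the score is the area under
the gene-set recovery curve over the top-ranked fraction of genes,
normalized to [0, 1].  Being rank-based, the score is invariant to any
monotone transform of a cell's expression values.  Endothelial cells are
selected by score > 0.1 (strict), and signatures are compared across
samples by Spearman correlation.
"""

from __future__ import annotations

import math
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionMatrix, GeneSet


def de_log2fc_test(
    counts: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
) -> pd.DataFrame:
    """Per-gene fold change and Welch t-test on a two-group count panel.

    ``counts`` is genes × samples; ``groups`` maps each sample column to
    one of exactly two group labels.  Columns are total-count normalized
    to the mean library size, log2(x+1) transformed, and each gene gets
    log2FC = mean(group2) − mean(group1) (groups in sorted label order)
    with a two-sided Welch t p-value.  A gene that is all-zero in both
    groups reports log2FC 0 and p 1.

    Returns a DataFrame indexed by gene with ``log2fc`` and ``p_value``;
    the per-sample normalization factors are in ``.attrs["size_factors"]``.
    """
    groups = pd.Series(dict(groups) if not isinstance(groups, pd.Series)
                       else groups)
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {labels}")
    g1 = [c for c in counts.columns if groups[c] == labels[0]]
    g2 = [c for c in counts.columns if groups[c] == labels[1]]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("need >=2 samples per group")

    totals = counts.sum(axis=0).astype(float)
    factors = totals.mean() / totals
    logmat = np.log2(counts * factors + 1.0)

    a = logmat[g1].to_numpy(dtype=float)
    b = logmat[g2].to_numpy(dtype=float)
    lfc = b.mean(axis=1) - a.mean(axis=1)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-variance genes handled below
        _, p = stats.ttest_ind(b, a, axis=1, equal_var=False)
    p = np.asarray(p, dtype=float)
    # degenerate genes: zero variance in both groups
    degenerate = (a.var(axis=1, ddof=1) == 0) & (b.var(axis=1, ddof=1) == 0)
    p[degenerate & (lfc == 0)] = 1.0
    p[degenerate & (lfc != 0)] = 0.0
    # all-zero genes: no signal at all
    allzero = (counts[g1 + g2].to_numpy() == 0).all(axis=1)
    lfc[allzero] = 0.0
    p[allzero] = 1.0

    out = pd.DataFrame({"log2fc": lfc, "p_value": p}, index=counts.index)
    out.attrs["size_factors"] = factors
    out.attrs["groups"] = (labels[0], labels[1])
    return out


def select_signature_genes(
    de: pd.DataFrame,
    lfc_min: float = 0.7,
    p_max: float = 0.05,
    name: str = "signature",
) -> GeneSet:
    """Apply the signature thresholds: log2FC ≥ lfc_min AND p < p_max.

    The fold-change bound is inclusive and the p bound strict, matching
    the printed rule.  Genes are ordered by descending log2FC; an empty
    selection returns an empty gene set with a warning.
    """
    keep = de[(de["log2fc"] >= lfc_min) & (de["p_value"] < p_max)]
    keep = keep.sort_values("log2fc", ascending=False, kind="stable")
    if keep.empty:
        warnings.warn("no genes pass the signature thresholds", stacklevel=2)
    return GeneSet(name=name, genes=tuple(keep.index),
                   description=f"log2fc>={lfc_min},p<{p_max}")


def auc_recovery_score(
    mat: ExpressionMatrix,
    gene_set: GeneSet,
    top_fraction: float = 0.05,
) -> pd.Series:
    """Per-cell rank-recovery AUC of a gene set, in [0, 1].

    Genes are ranked per cell by descending expression (ties broken by
    gene order in the matrix); the recovery curve counts gene-set members
    among the top ``L = ceil(top_fraction · n_genes)`` ranks, and the
    score is the curve's area divided by the maximal rectangle ``L · m``
    (m = gene-set size within the universe, capped at L).  A set fully
    occupying the top ranks therefore scores just under 1 by the
    staircase-start deficit (m−1)/(2L).
    """
    n_cells, n_genes = mat.shape
    L = math.ceil(top_fraction * n_genes)
    if not 1 <= L <= n_genes:
        raise ValueError(
            f"top_fraction={top_fraction} gives invalid rank cutoff {L}"
        )
    member = np.array([g in set(gene_set.genes) for g in mat.gene_names])
    m = int(member.sum())
    if m == 0:
        warnings.warn(
            f"gene set {gene_set.name!r} is disjoint from the universe; "
            "all scores 0",
            stacklevel=2,
        )
        return pd.Series(np.zeros(n_cells), index=list(mat.cell_ids),
                         name=gene_set.name)
    m_eff = min(m, L)
    X = mat.dense()
    # stable argsort of -x: descending expression, ties by gene order
    order = np.argsort(-X, axis=1, kind="stable")[:, :L]
    hits = member[order]  # cells × L
    recovery = np.cumsum(hits, axis=1)
    score = recovery.sum(axis=1) / (L * m_eff)
    return pd.Series(score, index=list(mat.cell_ids), name=gene_set.name)


def select_ec_cells(scores: pd.Series, threshold: float = 0.1) -> pd.Index:
    """Cells whose signature score is strictly above the threshold."""
    return scores.index[scores.to_numpy() > threshold]


def per_sample_mean_score(
    scores: pd.Series,
    sample_of_cell: Mapping[str, str] | pd.Series,
    selected: Sequence[str] | None = None,
) -> pd.Series:
    """Per-sample signature value: mean score over that sample's cells.

    ``selected`` restricts the average to a cell subset (typically the
    score-selected ECs).
    """
    s = scores if selected is None else scores.loc[list(selected)]
    samples = pd.Series(dict(sample_of_cell)
                        if not isinstance(sample_of_cell, pd.Series)
                        else sample_of_cell)
    return s.groupby(samples.loc[s.index]).mean()


def spearman_signature_corr(
    values_a: Sequence[float], values_b: Sequence[float]
) -> tuple[float, float]:
    """Spearman rho (tie-corrected) with two-sided p across samples."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size != b.size or a.size < 3:
        raise ValueError("need >=3 paired sample values")
    if np.all(a == a[0]) or np.all(b == b[0]):
        warnings.warn("constant signature vector; rho undefined", stacklevel=2)
        return (float("nan"), float("nan"))
    rho, p = stats.spearmanr(a, b)
    return float(rho), float(p)
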