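import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import mifpipe as m
from mifpipe.signatures import (
    auc_recovery_score,
    de_log2fc_test,
    per_sample_mean_score,
    select_ec_cells,
    select_signature_genes,
    spearman_signature_corr,
)
from mifpipe.simulate import count_groups


def _panel(rows, n_per_group=3):
    """Build a genes x samples panel from per-gene (mean1, mean2) pairs."""
    cols = {}
    for j in range(n_per_group):
        cols[f"g1_{j}"] = [r[0] for r in rows]
        cols[f"g2_{j}"] = [r[1] for r in rows]
    return pd.DataFrame(cols, index=[f"G{i}" for i in range(len(rows))])


def _recovery_oracle(expression, membership, top_fraction):
    """Explicit recovery-curve-area oracle, independent of the scorer."""
    n = len(expression)
    L = math.ceil(top_fraction * n)
    order = sorted(range(n), key=lambda i: (-expression[i], i))
    hits, area = 0, 0
    for k in range(L):
        hits += membership[order[k]]
        area += hits
    m_eff = min(sum(membership), L)
    return area / (L * m_eff) if m_eff else 0.0


class TestDeLog2fcTest:
    def test_identical_groups_zero_lfc(self):
        panel = _panel([(5.0, 5.0), (9.0, 9.0)])
        de = de_log2fc_test(panel, count_groups(panel))
        assert (de.log2fc == 0).all()

    def test_noiseless_pseudocount_closed_form(self):
        """Constant 8-vs-2 columns: lfc = log2(9) - log2(3) = log2 3,
        the exact pseudocount value, not the nominal 2."""
        panel = _panel([(2.0, 8.0), (5.0, 5.0)])
        # equalize library sizes so normalization factors are 1
        panel.loc["G1", [c for c in panel if c.startswith("g1")]] = 10.0
        panel.loc["G1", [c for c in panel if c.startswith("g2")]] = 4.0
        assert panel.sum(axis=0).nunique() == 1
        de = de_log2fc_test(panel, count_groups(panel))
        assert de.log2fc.iloc[0] == pytest.approx(np.log2(3.0), abs=1e-9)

    def test_all_zero_gene(self):
        panel = _panel([(0.0, 0.0), (4.0, 4.0)])
        de = de_log2fc_test(panel, count_groups(panel))
        assert de.log2fc.iloc[0] == 0.0
        assert de.p_value.iloc[0] == 1.0

    def test_type_one_error_calibration(self):
        """No planted DE: p<0.05 fraction is 0.05 +/- 0.01 over reps."""
        rng = np.random.default_rng(0)
        hits, total = 0, 0
        for _ in range(200):
            counts = pd.DataFrame(
                rng.poisson(100.0, size=(1000, 12)),
                index=[f"G{i}" for i in range(1000)],
                columns=[f"g{1 + (j // 6)}_{j % 6}" for j in range(12)],
            )
            de = de_log2fc_test(counts, count_groups(counts))
            hits += (de.p_value < 0.05).sum()
            total += len(de)
        assert abs(hits / total - 0.05) <= 0.01


class TestSelectSignatureGenes:
    def _de(self, entries):
        return pd.DataFrame(
            {"log2fc": [e[0] for e in entries],
             "p_value": [e[1] for e in entries]},
            index=[f"G{i}" for i in range(len(entries))],
        )

    def test_threshold_boundaries(self):
        de = self._de([(0.8, 0.01), (0.69, 0.001), (0.7, 0.049), (5.0, 0.05)])
        gs = select_signature_genes(de)
        assert "G0" in gs.genes          # clears both thresholds
        assert "G1" not in gs.genes      # lfc 0.69 < 0.7
        assert "G2" in gs.genes          # lfc exactly 0.7 kept
        assert "G3" not in gs.genes      # p == 0.05 dropped (strict)

    def test_ordered_by_descending_lfc(self):
        de = self._de([(1.0, 0.01), (3.0, 0.01), (2.0, 0.01)])
        assert select_signature_genes(de).genes == ("G1", "G2", "G0")

    def test_empty_selection_warns(self):
        de = self._de([(0.1, 0.9)])
        with pytest.warns(UserWarning, match="no genes"):
            gs = select_signature_genes(de)
        assert len(gs) == 0

    def test_planted_recovery(self):
        """Sensitivity >= 0.95 at FDR <= 0.1 on the planted experiment."""
        matrix, truth = m.generate_count_experiment(
            1000, 6, 0.1, 2.0, 0.05, seed=2
        )
        de = de_log2fc_test(matrix, count_groups(matrix))
        gs = select_signature_genes(de)
        truth_set = set(truth.genes.gene[truth.genes.is_de])
        selected = set(gs.genes)
        tp = len(selected & truth_set)
        assert tp / len(truth_set) >= 0.95
        assert (len(selected) - tp) / max(len(selected), 1) <= 0.1


class TestAucRecoveryScore:
    def _mat(self, X, genes=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        genes = genes or tuple(f"G{i}" for i in range(X.shape[1]))
        cells = tuple(f"c{i}" for i in range(X.shape[0]))
        return m.ExpressionMatrix(counts=X, cell_ids=cells, gene_names=genes)

    def test_top_ranked_set_near_one(self):
        """Set of 5 occupying ranks 1-5 scores 1 - (m-1)/(2L), matching
        the oracle."""
        n, m_set = 100, 5
        x = np.concatenate([np.arange(n, 0, -1)])  # strictly decreasing
        member = [i < m_set for i in range(n)]
        mat = self._mat(x)
        gs = m.GeneSet("top", tuple(f"G{i}" for i in range(m_set)))
        score = auc_recovery_score(mat, gs, top_fraction=0.1).iloc[0]
        L = 10
        assert score == pytest.approx(1 - (m_set - 1) / (2 * L))
        assert score == pytest.approx(_recovery_oracle(x, member, 0.1))

    def test_set_below_threshold_scores_zero(self):
        x = np.arange(100, 0, -1)
        gs = m.GeneSet("bottom", tuple(f"G{i}" for i in range(90, 95)))
        score = auc_recovery_score(self._mat(x), gs, top_fraction=0.05)
        assert score.iloc[0] == 0.0

    def test_rank_swap_strictly_increases_score(self):
        x = np.arange(50, 0, -1).astype(float)
        gs = m.GeneSet("s", ("G4",))
        base = auc_recovery_score(self._mat(x), gs, top_fraction=0.2).iloc[0]
        x2 = x.copy()
        x2[[3, 4]] = x2[[4, 3]]  # move the set gene one rank up
        up = auc_recovery_score(self._mat(x2), gs, top_fraction=0.2).iloc[0]
        assert up > base

    def test_matches_oracle_on_random_instances(self):
        """500 random (ranking, set) instances agree with the explicit
        recovery-curve-area oracle exactly."""
        rng = np.random.default_rng(3)
        for _ in range(500):
            n = int(rng.integers(10, 60))
            x = rng.permutation(n).astype(float)
            m_set = int(rng.integers(1, n // 2 + 1))
            idx = rng.choice(n, size=m_set, replace=False)
            member = [i in set(idx) for i in range(n)]
            tf = float(rng.uniform(0.05, 0.5))
            gs = m.GeneSet("s", tuple(f"G{i}" for i in sorted(idx)))
            got = auc_recovery_score(self._mat(x), gs, top_fraction=tf).iloc[0]
            assert got == pytest.approx(_recovery_oracle(x, member, tf))

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(1, 100, size=80)
        gs = m.GeneSet("s", tuple(f"G{i}" for i in range(0, 40, 7)))
        a = auc_recovery_score(self._mat(x), gs)
        b = auc_recovery_score(self._mat(np.log1p(x) ** 3), gs)
        assert a.iloc[0] == b.iloc[0]

    def test_disjoint_set_warns_zero(self):
        x = np.arange(20)
        gs = m.GeneSet("alien", ("ZZZ1", "ZZZ2"))
        with pytest.warns(UserWarning, match="disjoint"):
            score = auc_recovery_score(self._mat(x), gs)
        assert (score == 0).all()


class TestSelectEcCells:
    def test_strict_boundary(self):
        scores = pd.Series({"c1": 0.1, "c2": 0.10001, "c3": 0.0})
        assert list(select_ec_cells(scores)) == ["c2"]

    def test_all_zero_empty(self):
        scores = pd.Series({"c1": 0.0, "c2": 0.0})
        assert len(select_ec_cells(scores)) == 0

    def test_planted_cohort_recovery(self):
        """Enrichment 8: >=95% of true ECs selected, <=5% contamination."""
        sig = m.GeneSet("s", tuple(f"G{i}" for i in range(50)))
        mat, truth = m.generate_expression(600, 1000, 0.2, sig, 8.0, seed=4)
        scores = auc_recovery_score(mat, sig)
        selected = set(select_ec_cells(scores))
        is_ec = dict(zip(truth.cells.cell_id, truth.cells.is_ec))
        tp = sum(1 for c in selected if is_ec[c])
        n_ec = int(truth.cells.is_ec.sum())
        assert tp / n_ec >= 0.95
        assert (len(selected) - tp) / max(len(selected), 1) <= 0.05


class TestSpearmanCorr:
    def test_perfectly_decreasing(self):
        rho, _ = spearman_signature_corr([1, 2, 3], [3, 2, 1])
        assert rho == pytest.approx(-1.0)

    def test_perfectly_increasing(self):
        rho, _ = spearman_signature_corr([1, 2, 3], [1, 2, 3])
        assert rho == pytest.approx(1.0)

    def test_tie_corrected_hand_computation(self):
        """6 points with one tie in y: rho equals the tie-corrected
        Pearson correlation of midranks."""
        a = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        b = [2.0, 1.0, 4.0, 4.0, 6.0, 5.0]
        rank_a = stats.rankdata(a)
        rank_b = stats.rankdata(b)  # midranks for the tie
        expected = np.corrcoef(rank_a, rank_b)[0, 1]
        rho, p = spearman_signature_corr(a, b)
        assert rho == pytest.approx(expected)

    def test_constant_vector_nan_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            rho, p = spearman_signature_corr([1, 1, 1], [1, 2, 3])
        assert math.isnan(rho) and math.isnan(p)

    def test_inversely_planted_signatures_anticorrelate(self):
        """A cohort whose EC cells are graded high on signature A and
        inversely on signature B yields rho < 0 with p < 0.05 in >=90%
        of seeded runs (score-selected ECs, per-sample means)."""
        sig_e = m.GeneSet("EC", tuple(f"G{i}" for i in range(30)))
        sig_a = m.GeneSet("A", tuple(f"G{i}" for i in range(30, 60)))
        sig_b = m.GeneSet("B", tuple(f"G{i}" for i in range(60, 90)))
        a_cols, b_cols = list(range(30, 60)), list(range(60, 90))
        strength = np.linspace(2.0, 10.0, 12)  # planted gradient, 12 samples
        wins = 0
        for seed in range(20):
            mat, truth = m.generate_expression(2400, 400, 0.3, sig_e, 8.0,
                                               seed=seed)
            dense = mat.dense()
            ec = truth.cells.is_ec.to_numpy()
            sample_of = np.repeat(np.arange(12), 200)
            for s, enr in enumerate(strength):
                rows = ec & (sample_of == s)
                dense[np.ix_(rows, a_cols)] *= enr
                dense[np.ix_(rows, b_cols)] *= 20.0 / enr
            mat2 = m.ExpressionMatrix(np.round(dense), mat.cell_ids,
                                      mat.gene_names)
            sel = select_ec_cells(auc_recovery_score(mat2, sig_e))
            sa = auc_recovery_score(mat2, sig_a)
            sb = auc_recovery_score(mat2, sig_b)
            so = pd.Series(sample_of, index=sa.index)
            va = per_sample_mean_score(sa, so, sel).sort_index()
            vb = per_sample_mean_score(sb, so, sel).sort_index()
            rho, p = spearman_signature_corr(va, vb)
            wins += (rho < 0) and (p < 0.05)
        assert wins >= 18
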