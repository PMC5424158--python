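"""Tests of immune profiling: NMF, zero-inflated LRT, AUC, markers, ORA, states."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import comb
from sklearn.decomposition import NMF as SkNMF
from sklearn.metrics import adjusted_rand_score

from sctumor import immune
from sctumor.immune import (
    hypergeometric_ora, nmf_cluster, roc_auc, select_markers,
    tcell_state_scores, zero_inflated_lrt,
)


def brute_force_auc(values, labels):
    """Exhaustive pos x neg pair enumeration."""
    pos = [v for v, l in zip(values, labels) if l]
    neg = [v for v, l in zip(values, labels) if not l]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p, n in itertools.product(pos, neg))
    return wins / (len(pos) * len(neg))


@pytest.fixture
def block_matrix(matrix_factory):
    """Three cell populations, each expressing its own 10-gene block."""
    rng = np.random.default_rng(0)
    X = np.zeros((30, 60))
    for b in range(3):
        X[b * 10:(b + 1) * 10, b * 20:(b + 1) * 20] = rng.uniform(3, 6, (10, 20))
    return matrix_factory(np.exp2(X) - 1 + 1e-9), [i // 20 for i in range(60)]


class TestNmf:
    def test_block_structure_recovered(self, block_matrix):
        m, truth = block_matrix
        res = nmf_cluster(m, m.gene_ids, k=3, seed=0)
        assert adjusted_rand_score(truth, res.assignment) == 1.0

    def test_same_seed_identical(self, block_matrix):
        m, _ = block_matrix
        a = nmf_cluster(m, m.gene_ids, k=3, seed=5, n_restarts=2)
        b = nmf_cluster(m, m.gene_ids, k=3, seed=5, n_restarts=2)
        pd.testing.assert_frame_equal(a.W, b.W)
        pd.testing.assert_frame_equal(a.H, b.H)

    def test_k_one_single_cluster(self, block_matrix):
        m, _ = block_matrix
        res = nmf_cluster(m, m.gene_ids, k=1, seed=0, n_restarts=2)
        assert res.assignment.nunique() == 1

    def test_error_trace_never_increases(self, block_matrix):
        m, _ = block_matrix
        res = nmf_cluster(m, m.gene_ids, k=3, seed=1, n_restarts=1)
        assert (np.diff(res.error_trace) <= 1e-8).all()

    def test_matches_sklearn_reconstruction_quality(self, block_matrix):
        m, _ = block_matrix
        res = nmf_cluster(m, m.gene_ids, k=3, seed=0)
        sk = SkNMF(n_components=3, solver="mu", beta_loss="frobenius",
                   init="random", random_state=0, max_iter=1000)
        W = sk.fit_transform(m.log.to_numpy())
        sk_err = np.linalg.norm(m.log.to_numpy() - W @ sk.components_, "fro")
        assert res.reconstruction_error <= sk_err * 1.1

    def test_invalid_inputs_rejected(self, block_matrix, matrix_factory):
        m, _ = block_matrix
        with pytest.raises(ValueError):
            nmf_cluster(m, m.gene_ids, k=99)
        with pytest.raises(ValueError):
            nmf_cluster(matrix_factory(np.zeros((5, 5))), [f"g{i}" for i in range(5)], k=2)


class TestZeroInflatedLrt:
    def test_identical_groups_not_significant(self):
        x = np.array([0, 0, 1.5, 2.0, 3.0, 0, 2.5])
        assert zero_inflated_lrt(x, x.copy()) == pytest.approx(1.0)

    def test_all_zero_versus_all_positive(self):
        rng = np.random.default_rng(1)
        p = zero_inflated_lrt(np.zeros(20), np.clip(rng.normal(3, 1, 20), 0.01, None))
        assert p < 1e-4

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            zero_inflated_lrt([1.0, 2.0], [1.0, 2.0, 3.0])

    def test_statistic_nonnegative_random_draws(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            a = np.where(rng.random(15) < 0.5, rng.uniform(0.5, 5, 15), 0.0)
            b = np.where(rng.random(15) < 0.7, rng.uniform(0.5, 5, 15), 0.0)
            p = zero_inflated_lrt(a, b)
            assert 0.0 <= p <= 1.0

    def test_p_decreases_with_effect_size(self):
        rng = np.random.default_rng(3)
        med_p = []
        for effect in (0.0, 0.5, 1.0, 1.5, 2.0):
            ps = []
            for rep in range(40):
                a = np.where(rng.random(40) < 0.6,
                             np.clip(rng.normal(2.0, 1, 40), 0.01, None), 0.0)
                b = np.where(rng.random(40) < 0.6,
                             np.clip(rng.normal(2.0 + effect, 1, 40), 0.01, None), 0.0)
                ps.append(zero_inflated_lrt(a, b))
            med_p.append(np.median(ps))
        assert all(x >= y - 1e-12 for x, y in zip(med_p, med_p[1:]))

    def test_null_calibration(self):
        # under the null zero-inflated model the chi2(2) reference should give
        # approximately nominal rejection
        rng = np.random.default_rng(4)
        rej = 0
        n_genes = 2000
        for _ in range(n_genes):
            def draw(n):
                x = np.where(rng.random(n) < 0.6,
                             np.clip(rng.normal(3.0, 1.0, n), 0.01, None), 0.0)
                return x
            rej += zero_inflated_lrt(draw(50), draw(50)) < 0.05
        assert 0.03 <= rej / n_genes <= 0.07

    def test_free_sigma_variant_runs(self):
        rng = np.random.default_rng(5)
        a = np.clip(rng.normal(2, 0.5, 30), 0.01, None)
        b = np.clip(rng.normal(2, 2.0, 30), 0.01, None)
        p2 = zero_inflated_lrt(a, b, pooled_sigma=True)
        p3 = zero_inflated_lrt(a, b, pooled_sigma=False)
        assert 0 <= p3 <= 1 and p3 < p2  # variance shift detectable only with free sigma


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([1, 2, 8, 9], [0, 0, 1, 1]) == 1.0

    def test_all_ties_is_half(self):
        assert roc_auc([5, 5, 5, 5], [0, 1, 0, 1]) == 0.5

    def test_four_point_toy_matches_pair_enumeration(self):
        values, labels = [3, 2, 1, 2], [1, 1, 0, 0]
        # pairs: (3>1)=1, (3>2)=1, (2>1)=1, (2==2)=0.5 -> 3.5/4
        assert roc_auc(values, labels) == pytest.approx(0.875)
        assert roc_auc(values, labels) == pytest.approx(brute_force_auc(values, labels))

    @given(st.lists(st.tuples(st.integers(0, 10), st.booleans()), min_size=4, max_size=40)
           .filter(lambda xs: any(l for _, l in xs) and any(not l for _, l in xs)))
    @settings(max_examples=100, deadline=None)
    def test_equals_brute_force_everywhere(self, pairs):
        values = [v for v, _ in pairs]
        labels = [l for _, l in pairs]
        assert roc_auc(values, labels) == pytest.approx(brute_force_auc(values, labels))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2, 3], [1, 1, 1])


class TestSelectMarkers:
    def _planted(self, matrix_factory, seed=6, n_markers=40, effect=3.0):
        rng = np.random.default_rng(seed)
        G, n1, n2 = 800, 50, 100
        base = rng.uniform(1.5, 4.0, G)

        def block(n, idx=None):
            mean = np.repeat(base[:, None], n, axis=1)
            if idx is not None:
                mean[idx, :] += effect
            val = mean + rng.normal(0, 1, mean.shape)
            lin = np.exp2(val)
            lin[rng.random(mean.shape) < 1 / (1 + np.exp(mean - 1.0))] = 0.0
            return lin

        lin = np.hstack([block(n1, np.arange(n_markers)), block(n2)])
        lin *= 1e6 / lin.sum(axis=0)
        m = matrix_factory(lin)
        assignment = pd.Series(["A"] * n1 + ["B"] * n2, index=m.cell_ids)
        return m, assignment, {f"g{i}" for i in range(n_markers)}

    def test_planted_markers_recovered_without_false_positives(self, matrix_factory):
        m, assignment, planted = self._planted(matrix_factory)
        table = select_markers(m, assignment)
        found = set(table.loc[table["cluster"] == "A", "gene_id"])
        assert len(found & planted) / len(planted) >= 0.9
        null_hits = found - planted
        assert len(null_hits) / (m.n_genes - len(planted)) < 0.01

    def test_no_differences_yields_empty(self, matrix_factory):
        rng = np.random.default_rng(7)
        m = matrix_factory(rng.uniform(1, 50, (100, 30)))
        assignment = pd.Series(["A"] * 15 + ["B"] * 15, index=m.cell_ids)
        assert len(select_markers(m, assignment)) == 0

    def test_high_auc_low_fold_excluded(self, matrix_factory):
        rng = np.random.default_rng(8)
        n1 = n2 = 40
        base = np.full((1, n1 + n2), 5.0)
        val = base + rng.normal(0, 0.05, base.shape)
        val[0, :n1] += np.log2(1.5)  # 1.5-fold: perfectly separable, under 2-fold
        m = matrix_factory(np.exp2(val))
        assignment = pd.Series(["A"] * n1 + ["B"] * n2, index=m.cell_ids)
        vals = m.log.iloc[0]
        assert roc_auc(vals, [g == "A" for g in assignment]) > 0.9
        assert len(select_markers(m, assignment)) == 0

    def test_invariant_to_cell_and_gene_order(self, matrix_factory):
        m, assignment, _ = self._planted(matrix_factory, seed=9, n_markers=10)
        table = select_markers(m, assignment)
        rng = np.random.default_rng(10)
        gene_perm = rng.permutation(m.gene_ids)
        cell_perm = rng.permutation(m.cell_ids)
        from sctumor.containers import ExpressionMatrix
        m2 = ExpressionMatrix(tpm=m.tpm.loc[gene_perm, cell_perm],
                              groups=m.groups.loc[cell_perm])
        table2 = select_markers(m2, assignment.loc[cell_perm])
        pd.testing.assert_frame_equal(table, table2)

    def test_tiny_cluster_skipped(self, matrix_factory):
        rng = np.random.default_rng(11)
        m = matrix_factory(rng.uniform(1, 50, (20, 10)))
        assignment = pd.Series(["A"] * 2 + ["B"] * 8, index=m.cell_ids)
        table = select_markers(m, assignment)
        assert (table["cluster"] != "A").all()


class TestOra:
    def test_exact_tail_tiny_example(self):
        universe = [f"g{i}" for i in range(10)]
        markers = universe[:3]
        p = hypergeometric_ora(markers, {"term": markers}, universe)
        # P(all 3 draws in the 3-gene term) = 1 / C(10,3)
        assert p["term"] == pytest.approx(1.0 / comb(10, 3))

    def test_disjoint_term_p_one(self):
        universe = [f"g{i}" for i in range(10)]
        p = hypergeometric_ora(universe[:3], {"t": universe[5:8]}, universe)
        assert p["t"] == 1.0

    def test_near_uniform_p_under_random_markers(self):
        rng = np.random.default_rng(12)
        universe = [f"g{i}" for i in range(500)]
        term = {"t": list(rng.choice(universe, 50, replace=False))}
        ps = np.array([hypergeometric_ora(list(rng.choice(universe, 40, replace=False)),
                                          term, universe)["t"]
                       for _ in range(1000)])
        # the discrete upper-tail p is stochastically >= Uniform(0,1):
        # valid (never anti-conservative) and not degenerate
        assert (ps < 0.05).mean() <= 0.07
        assert 0.45 <= ps.mean() <= 0.75

    def test_markers_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_ora(["x"], {"t": ["a"]}, ["a", "b"])

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_ora([], {"t": ["a"]}, [])


class TestTcellStates:
    STATES = ("naive", "costim", "regulatory", "exhaustion", "cytotoxicity")

    def _state_matrix(self, matrix_factory, seed=13, n_per_state=8, n_cells=40):
        rng = np.random.default_rng(seed)
        G = n_per_state * len(self.STATES) + 60
        tpm = rng.uniform(1, 20, (G, n_cells))
        sets = {s: [f"g{i}" for i in range(k * n_per_state, (k + 1) * n_per_state)]
                for k, s in enumerate(self.STATES)}
        return tpm, sets

    def test_exhaustion_high_cells_score_exhaustion_highest(self, matrix_factory):
        tpm, sets = self._state_matrix(matrix_factory)
        idx = [int(g[1:]) for g in sets["exhaustion"]]
        tpm[idx, :] *= 100
        m = matrix_factory(tpm)
        prof = tcell_state_scores(m, sets)
        assert (prof.scores.idxmax(axis=1) == "exhaustion").all()
        assert prof.scores.shape[1] == 5

    def test_two_planted_states_separate(self, matrix_factory):
        tpm, sets = self._state_matrix(matrix_factory, seed=14)
        reg = [int(g[1:]) for g in sets["regulatory"]]
        exh = [int(g[1:]) for g in sets["exhaustion"]]
        tpm[np.ix_(reg, range(20))] *= 100
        tpm[np.ix_(exh, range(20, 40))] *= 100
        m = matrix_factory(tpm)
        prof = tcell_state_scores(m, sets, n_clusters=2)
        truth = [0] * 20 + [1] * 20
        assert adjusted_rand_score(truth, prof.labels) >= 0.9

    def test_shuffled_gene_labels_collapse_contrast(self, matrix_factory):
        deltas_planted, deltas_shuffled = [], []
        for seed in range(15, 20):
            tpm, sets = self._state_matrix(matrix_factory, seed=seed)
            reg = [int(g[1:]) for g in sets["regulatory"]]
            tpm[np.ix_(reg, range(20))] *= 100
            m = matrix_factory(tpm)
            prof = tcell_state_scores(m, sets)
            d = prof.scores["regulatory"][:20].mean() - prof.scores["regulatory"][20:].mean()
            deltas_planted.append(d)
            rng = np.random.default_rng(seed)
            shuffled_genes = rng.permutation(m.gene_ids)
            m2 = matrix_factory(tpm, genes=list(shuffled_genes))
            prof2 = tcell_state_scores(m2, sets)
            d2 = prof2.scores["regulatory"][:20].mean() - prof2.scores["regulatory"][20:].mean()
            deltas_shuffled.append(abs(d2))
        assert all(dp > ds for dp, ds in zip(deltas_planted, deltas_shuffled))

    def test_no_cells_rejected(self, matrix_factory):
        m = matrix_factory(np.ones((10, 1))).subset_cells([])
        with pytest.raises(ValueError):
            tcell_state_scores(m, {"s": ["g0"]})
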