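"""Differential-expression statistics: Welch t-test, BH step-up FDR,
significance calls, Ward clustering, and group-separation scoring."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from alulnc.quantify import SampleSheet
from alulnc.simulate import simulate_counts
from alulnc.stats import (
    DeResult,
    bh_adjust,
    call_significant,
    differential_expression,
    hierarchical_cluster,
    separation_score,
    welch_ttest,
)


def _perm_pvalue(a, b, rng=None, n_perm=None):
    """Permutation p-value for the absolute mean difference; exhaustive when
    n_perm is None, Monte-Carlo otherwise."""
    pooled = np.concatenate([a, b])
    observed = abs(a.mean() - b.mean())
    n, k = len(pooled), len(a)
    count = total = 0
    if n_perm is None:
        for idx in itertools.combinations(range(n), k):
            mask = np.zeros(n, bool)
            mask[list(idx)] = True
            stat = abs(pooled[mask].mean() - pooled[~mask].mean())
            count += stat >= observed - 1e-12
            total += 1
    else:
        for _ in range(n_perm):
            perm = rng.permutation(n)
            stat = abs(pooled[perm[:k]].mean() - pooled[perm[k:]].mean())
            count += stat >= observed - 1e-12
            total += 1
    return count / total


class TestWelch:
    def test_null_case_large_p(self):
        rng = np.random.default_rng(0)
        values = np.concatenate([rng.normal(5, 1, 50), rng.normal(5, 1, 50)])
        groups = np.array([False] * 50 + [True] * 50)
        assert welch_ttest(values, groups) > 0.05

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(1)
        values = rng.normal(0, 1, 20)
        groups = np.array([True] * 8 + [False] * 12)
        assert welch_ttest(values, groups) == pytest.approx(welch_ttest(values, ~groups))

    def test_location_scale_invariance(self):
        rng = np.random.default_rng(2)
        values = rng.normal(0, 1, 16)
        groups = rng.random(16) < 0.5
        groups[:2], groups[-2:] = False, True
        p1 = welch_ttest(values, groups)
        p2 = welch_ttest(3.5 * values + 11.0, groups)
        assert p1 == pytest.approx(p2)

    def test_well_separated_groups_significant_by_both_routes(self):
        a = np.array([5.1, 5.2, 4.9, 5.0])
        b = np.array([7.1, 7.3, 6.8, 7.0])
        values = np.concatenate([a, b])
        groups = np.array([False] * 4 + [True] * 4)
        p = welch_ttest(values, groups)
        # at n=4+4 the exhaustive permutation floor is 2/70; the separation
        # is total, so both routes sit at their respective extremes
        assert p < 1e-4
        assert _perm_pvalue(a, b) == pytest.approx(2 / 70)

    def test_agrees_with_permutation_oracle_on_overlapping_groups(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0.0, 1.0, 12)
        b = rng.normal(0.9, 1.0, 12)
        p_t = welch_ttest(np.concatenate([a, b]), np.array([False] * 12 + [True] * 12))
        p_perm = _perm_pvalue(a, b, rng=np.random.default_rng(4), n_perm=20_000)
        assert p_t == pytest.approx(p_perm, abs=0.02)

    def test_degenerate_group_sizes_error(self):
        with pytest.raises(ValueError):
            welch_ttest([1.0, 2.0, 3.0], [True, False, False])


def _bh_brute_force(pvalues):
    n = len(pvalues)
    order = sorted(range(n), key=lambda i: pvalues[i])
    q = [0.0] * n
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, pvalues[i] * n / rank)
        q[i] = running
    return q


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.04]).tolist() == [0.04]

    def test_textbook_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=6))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_step_up_definition(self, pvalues):
        np.testing.assert_allclose(bh_adjust(pvalues), _bh_brute_force(pvalues), atol=1e-12)

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=2, max_size=20))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_monotone_in_sorted_order(self, pvalues):
        q = bh_adjust(pvalues)
        order = np.argsort(pvalues)
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all(q >= np.asarray(pvalues) - 1e-12) and np.all(q <= 1.0)

    def test_agrees_with_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(5)
        p = rng.uniform(0, 1, 200)
        np.testing.assert_allclose(bh_adjust(p), multipletests(p, method="fdr_bh")[1])


class TestCallSignificant:
    def _res(self, padj):
        return DeResult("x", 2.0, "inflammation", min(padj, 1.0), padj)

    def test_boundary_strict(self):
        assert call_significant([self._res(0.001)]) == []

    def test_below_alpha_included(self):
        results = [self._res(2e-5)]
        assert call_significant(results) == results

    def test_empty(self):
        assert call_significant([]) == []


class TestClustering:
    def test_two_samples_single_merge_at_distance(self):
        norm = np.array([[0.0, 3.0], [0.0, 4.0]])
        dend = hierarchical_cluster(norm, ["a", "b"])
        assert dend.linkage.shape == (1, 4)
        assert dend.linkage[0, 2] == pytest.approx(5.0)

    def test_duplicated_sample_merges_at_zero(self):
        norm = np.array([[1.0, 1.0, 9.0], [2.0, 2.0, 9.0]])
        dend = hierarchical_cluster(norm, ["a", "a2", "far"])
        assert dend.linkage[0, 2] == pytest.approx(0.0)

    def test_fewer_than_two_samples_error(self):
        with pytest.raises(ValueError):
            hierarchical_cluster(np.zeros((3, 1)), ["only"])

    def test_strong_two_group_structure_separates_at_root(self):
        rng = np.random.default_rng(6)
        shift = np.zeros((30, 20))
        shift[:, 10:] = 50.0
        norm = rng.normal(0, 1, (30, 20)) + shift
        ids = [f"s{i}" for i in range(20)]
        dend = hierarchical_cluster(norm, ids)
        labels = {sid: ("g1" if i < 10 else "g2") for i, sid in enumerate(ids)}
        assert separation_score(dend, labels) == 1.0

    def test_newick_contains_all_leaves(self):
        rng = np.random.default_rng(7)
        ids = [f"s{i}" for i in range(6)]
        dend = hierarchical_cluster(rng.normal(size=(5, 6)), ids)
        nwk = dend.to_newick()
        assert nwk.endswith(";") and all(sid in nwk for sid in ids)

    def test_random_labels_near_chance(self):
        rng = np.random.default_rng(8)
        ids = [f"s{i}" for i in range(40)]
        dend = hierarchical_cluster(rng.normal(size=(30, 40)), ids)
        scores = []
        for rep in range(50):
            perm = rng.permutation(40)
            labels = {ids[j]: ("a" if k < 20 else "b") for k, j in enumerate(perm)}
            scores.append(separation_score(dend, labels))
        assert 0.5 <= np.mean(scores) < 0.65

    def test_one_mislabeled_of_ten(self):
        norm = np.zeros((5, 10))
        norm[:, 5:] = 30.0
        ids = [f"s{i}" for i in range(10)]
        dend = hierarchical_cluster(norm + np.random.default_rng(9).normal(0, 0.1, (5, 10)), ids)
        labels = {sid: ("a" if i < 5 else "b") for i, sid in enumerate(ids)}
        labels["s0"] = "b"
        assert separation_score(dend, labels) == pytest.approx(0.9)


class TestDifferentialExpression:
    def test_null_simulation_type_one_control(self):
        """On null data the raw p<0.05 fraction stays inside binomial 99%
        bounds of 0.05 and BH at alpha=0.001 makes essentially no calls."""
        ids = [f"ins{i}" for i in range(1000)]
        matrix, sheet, _ = simulate_counts(ids, (20, 20), seed=1, de_fraction=0.0)
        from alulnc.quantify import normalize, size_factors

        norm = normalize(matrix, size_factors(matrix))
        results = differential_expression(matrix, norm, sheet)
        frac = np.mean([r.p < 0.05 for r in results])
        half_width = 2.576 * np.sqrt(0.05 * 0.95 / 1000)
        assert abs(frac - 0.05) < half_width
        assert len(call_significant(results, alpha=0.001)) <= 2

    def test_fold_change_direction_recorded(self):
        ids = [f"ins{i}" for i in range(20)]
        matrix, sheet, truth = simulate_counts(
            ids, (10, 10), seed=2, fc=8.0, de_fraction=0.5, dispersion=0.05
        )
        from alulnc.quantify import normalize, size_factors

        norm = normalize(matrix, size_factors(matrix))
        results = {r.insertion_id: r for r in differential_expression(matrix, norm, sheet)}
        for rid in truth.de_ids:
            expected = "inflammation" if truth.up_in_inflammation[rid] else "healthy"
            assert results[rid].up_in == expected
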