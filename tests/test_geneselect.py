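"""Co-expression module selection: preprocessing, adjacency, TOM, tree cut,
fold-change gating, time-course DE, and GO term gating."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import false_discovery_control

from anchortf.geneselect import (
    ExpressionMatrix,
    GeneModule,
    SelectionConfig,
    compute_adjacency,
    compute_tom,
    detect_modules,
    go_enrich_select,
    intersect_down,
    module_fold_change,
    preprocess_expression,
    timecourse_de,
)


def brute_tom(A):
    """Element-by-element loop implementation of topological overlap."""
    n = A.shape[0]
    k = A.sum(axis=1) - np.diag(A)
    T = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(A[i, u] * A[u, j] for u in range(n) if u not in (i, j))
            T[i, j] = (shared + A[i, j]) / (min(k[i], k[j]) + 1 - A[i, j])
    return T


def brute_first_merge_heights(X):
    """Average-linkage agglomeration from scratch; returns each leaf's first
    merge height (euclidean distance between cluster means is NOT used --
    this mirrors average linkage over pairwise distances)."""
    n = X.shape[0]
    clusters = {i: [i] for i in range(n)}
    D = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=2)
    first = {}
    next_id = n
    dist = {}
    for a in clusters:
        for b in clusters:
            if a < b:
                dist[(a, b)] = D[a, b]
    while len(clusters) > 1:
        (a, b), h = min(dist.items(), key=lambda kv: kv[1])
        for leaf in (a, b):
            if leaf < n and leaf not in first:
                first[leaf] = h
        merged = clusters.pop(a) + clusters.pop(b)
        dist = {k: v for k, v in dist.items() if a not in k and b not in k}
        for c, members in clusters.items():
            d = np.mean([D[x, y] for x in merged for y in members])
            dist[(min(c, next_id), max(c, next_id))] = d
        clusters[next_id] = merged
        next_id += 1
    return first


class TestPreprocess:
    def test_clean_matrix_unchanged(self, small_matrix):
        res = preprocess_expression(small_matrix, SelectionConfig())
        assert res.matrix.gene_ids == small_matrix.gene_ids
        assert res.matrix.sample_ids == small_matrix.sample_ids
        np.testing.assert_array_equal(res.matrix.values, small_matrix.values)
        assert res.removed_genes == [] and res.removed_samples == []

    def test_high_missingness_gene_dropped(self, small_matrix):
        vals = small_matrix.values.copy()
        vals[2, :3] = np.nan  # 50% missing > 20% threshold
        m = ExpressionMatrix(
            small_matrix.gene_ids, small_matrix.sample_ids, vals,
            small_matrix.sample_time,
        )
        res = preprocess_expression(m, SelectionConfig(max_missing_frac=0.2))
        assert res.removed_genes == ["g2"]
        assert "g2" not in res.matrix.gene_ids

    def test_mean_imputation(self, small_matrix):
        vals = small_matrix.values.copy()
        vals[1, 0] = np.nan
        m = ExpressionMatrix(
            small_matrix.gene_ids, small_matrix.sample_ids, vals,
            small_matrix.sample_time,
        )
        res = preprocess_expression(m, SelectionConfig())
        assert res.n_imputed == 1
        expected = np.nanmean(vals[1])
        assert res.matrix.values[1, 0] == pytest.approx(expected)

    def test_shifted_sample_flagged_as_outlier(self, rng):
        """A sample shifted by +10 sd must exceed mean + 2 sd of the merge
        heights computed by a from-scratch average-linkage oracle."""
        vals = rng.normal(0, 1, size=(10, 6))
        vals[:, 4] += 10.0
        m = ExpressionMatrix(
            [f"g{i}" for i in range(10)], [f"s{j}" for j in range(6)],
            vals, ["early"] * 3 + ["late"] * 3,
        )
        res = preprocess_expression(m, SelectionConfig())
        assert res.removed_samples == ["s4"]
        first = brute_first_merge_heights(vals.T)
        heights = sorted(first.values())
        assert first[4] == max(first.values())

    def test_degenerate_inputs(self, small_matrix):
        with pytest.raises(ValueError):
            preprocess_expression(
                ExpressionMatrix(["a", "b"], ["s0", "s1"],
                                 np.ones((2, 2)), ["e", "l"]),
                SelectionConfig(),
            )
        vals = np.full((3, 6), np.nan)
        m = ExpressionMatrix(
            ["a", "b", "c"], [f"s{j}" for j in range(6)], vals,
            ["e"] * 3 + ["l"] * 3,
        )
        with pytest.raises(ValueError, match="all genes"):
            preprocess_expression(m, SelectionConfig())


class TestAdjacency:
    def test_perfect_and_powered_correlations(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        # build y with exact correlation -0.8 against x
        zx = (x - x.mean()) / x.std()
        w = np.array([1.0, -1.0, 0.0, 1.0, -1.0])
        w = w - w.mean()
        w -= (w @ zx) / (zx @ zx) * zx
        zw = w / w.std()
        y = -0.8 * zx + np.sqrt(1 - 0.64) * zw
        m = ExpressionMatrix(
            ["a", "b", "c"], [f"s{j}" for j in range(5)],
            np.vstack([x, x * 2.0 + 1.0, y]), ["e", "e", "m", "l", "l"],
        )
        adj = compute_adjacency(m, soft_power=10)
        assert adj[0, 1] == pytest.approx(1.0)  # cor exactly 1
        assert adj[0, 2] == pytest.approx(0.8 ** 10, abs=1e-12)  # unsigned
        assert np.all(np.diag(adj) == 1.0)

    def test_half_correlation_tenth_power(self):
        assert 0.5 ** 10 == 0.0009765625  # the adjacency a 0.5 correlation maps to

    def test_zero_variance_gene_flagged_not_fatal(self, small_matrix):
        vals = small_matrix.values.copy()
        vals[0] = 5.0
        m = ExpressionMatrix(
            small_matrix.gene_ids, small_matrix.sample_ids, vals,
            small_matrix.sample_time,
        )
        with pytest.warns(UserWarning, match="zero-variance"):
            adj = compute_adjacency(m, 10)
        assert np.all(adj[0, 1:] == 0.0) and adj[0, 0] == 1.0


class TestTom:
    def test_fully_connected_and_empty(self):
        n = 3
        ones = np.ones((n, n))
        np.testing.assert_allclose(compute_tom(ones), np.ones((n, n)))
        eye = np.eye(n)
        tom = compute_tom(eye)
        assert np.all(tom[~np.eye(n, dtype=bool)] == 0.0)

    def test_matches_bruteforce_on_random_matrices(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 13))
            A = rng.random((n, n))
            A = (A + A.T) / 2
            np.fill_diagonal(A, 1.0)
            np.testing.assert_allclose(compute_tom(A), brute_tom(A), atol=1e-12)

    def test_rejects_asymmetric(self):
        A = np.array([[1.0, 0.2], [0.5, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            compute_tom(A)


class TestDetectModules:
    def test_identical_genes_single_module(self):
        n = 35
        tom = np.ones((n, n))
        det = detect_modules(tom, SelectionConfig(min_module_size=30))
        assert len(det.modules) == 1 and det.modules[0].size == n

    def test_planted_blocks_recovered(self, rng):
        n = 80
        A = np.full((n, n), 1e-4)
        A[:40, :40] = 0.8
        A[40:, 40:] = 0.8
        A += rng.normal(0, 1e-5, (n, n))
        A = np.clip((A + A.T) / 2, 0, 1)
        np.fill_diagonal(A, 1.0)
        det = detect_modules(compute_tom(A), SelectionConfig(min_module_size=30))
        assert len(det.modules) == 2
        blocks = sorted(tuple(sorted(m.gene_ids)) for m in det.modules)
        assert blocks[0] == tuple(sorted(f"g{i}" for i in range(40)))

    def test_too_few_genes_all_unassigned(self):
        tom = np.eye(10)
        with pytest.warns(UserWarning, match="unassigned"):
            det = detect_modules(tom, SelectionConfig(min_module_size=30))
        assert det.modules == [] and len(det.unassigned) == 10


class TestFoldChange:
    def test_examples_and_oracle(self, rng):
        vals = np.log2(
            np.array([[8.0, 8, 8, 2, 2, 2], [4.0, 4, 4, 4, 4, 4]])
        )
        m = ExpressionMatrix(
            ["a", "b"], [f"s{j}" for j in range(6)], vals,
            ["early"] * 3 + ["late"] * 3,
        )
        mod = GeneModule("M1", frozenset(["a"]))
        assert module_fold_change(mod, m, "early", "late") == pytest.approx(4.0)
        flat = GeneModule("M2", frozenset(["b"]))
        assert module_fold_change(flat, m, "early", "late") == pytest.approx(1.0)
        # mixed module equals independent summation on the linear scale
        both = GeneModule("M3", frozenset(["a", "b"]))
        lin = 2.0 ** vals
        expect = lin[:, :3].mean() / lin[:, 3:].mean()
        assert module_fold_change(both, m, "early", "late") == pytest.approx(expect)

    def test_missing_label_raises(self, small_matrix):
        mod = GeneModule("M1", frozenset(["g0"]))
        with pytest.raises(ValueError, match="absent"):
            module_fold_change(mod, small_matrix, "early", "nope")


class TestTimecourseDE:
    def test_constant_gene_not_called_and_strong_gene_called(self):
        vals = np.array(
            [
                [3.0, 3, 3, 3, 3, 3],
                np.log2([16.0, 16.01, 15.99, 4.0, 4.01, 3.99]),
            ]
        )
        m = ExpressionMatrix(
            ["flat", "down4x"], [f"s{j}" for j in range(6)], vals,
            ["early"] * 3 + ["late"] * 3,
        )
        df = timecourse_de(m, SelectionConfig()).set_index("gene")
        assert df.loc["flat", "p"] == 1.0 and not df.loc["flat", "called_down"]
        assert df.loc["down4x", "p"] < 1e-6
        assert df.loc["down4x", "called_down"]
        assert df.loc["down4x", "fold_change"] == pytest.approx(4.0, rel=1e-2)

    def test_single_replicate_errors_with_guidance(self):
        m = ExpressionMatrix(
            ["a", "b"], ["s0", "s1"], np.ones((2, 2)) + np.eye(2), ["e", "l"]
        )
        with pytest.raises(ValueError, match="fold-change-only"):
            timecourse_de(m, SelectionConfig())


class TestBenjaminiHochberg:
    def test_q_monotone_and_at_least_p(self, rng):
        for _ in range(10):
            p = rng.random(50)
            q = false_discovery_control(p, method="bh")
            order = np.argsort(p)
            assert np.all(np.diff(q[order]) >= -1e-12)
            assert np.all(q >= p - 1e-12)


class TestIntersectDown:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ({"a", "b", "c"}, {"b", "c", "d"}, {"b", "c"}),
            ({"Sox11", "Klf6"}, {"SOX11"}, {"sox11"}),
        ],
    )
    def test_intersection_normalized(self, a, b, expected):
        assert intersect_down(a, b) == expected

    def test_disjoint_warns_empty(self):
        with pytest.warns(UserWarning, match="empty"):
            assert intersect_down({"a"}, {"b"}) == set()

    def test_synonym_map(self):
        out = intersect_down({"OldName"}, {"newname"}, synonyms={"oldname": "newname"})
        assert out == {"newname"}


class TestGoEnrichment:
    def test_exact_p_from_enumeration(self):
        """Query exactly equal to a 5-member term in a 20-gene universe:
        p = 1 / C(20, 5)."""
        universe = {f"g{i}" for i in range(20)}
        term = {f"g{i}" for i in range(5)}
        sel = go_enrich_select(
            term, {"axon growth": term}, universe, ["axon growth"],
            SelectionConfig(),
        )
        from math import comb

        expect = 1 / comb(20, 5)
        row = sel.term_table.iloc[0]
        assert row["p"] == pytest.approx(expect, rel=1e-9)
        assert row["q"] == pytest.approx(expect, rel=1e-9)  # single term: q = p
        assert sel.selected_genes == term

    def test_disjoint_term_p_one(self):
        universe = {f"g{i}" for i in range(20)}
        sel = go_enrich_select(
            {"g0", "g1"}, {"other": {"g10", "g11"}}, universe, ["other"],
        )
        assert sel.term_table.iloc[0]["p"] == pytest.approx(1.0)
        assert sel.selected_genes == set()

    def test_empty_whitelist_rejected(self):
        with pytest.raises(ValueError, match="whitelist"):
            go_enrich_select({"a"}, {"t": {"a"}}, {"a", "b"}, [])
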