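"""Descriptor-reduction cascade: each filter's rule, idempotence and the
post-condition audit of the correlation filter."""

import numpy as np
import pytest

from ghstox import (
    DescriptorMatrix,
    filter_constant,
    filter_correlated,
    filter_missing,
    filter_near_constant,
    flag_score_outliers,
    pca_loading_filter,
    run_filter_cascade,
)
from ghstox.filtering import FilterError


def make_matrix(cols: dict[str, list[float]]) -> DescriptorMatrix:
    names = list(cols)
    values = np.column_stack([np.asarray(cols[c], dtype=float) for c in names])
    return DescriptorMatrix(
        row_ids=[f"r{i}" for i in range(values.shape[0])],
        column_names=names,
        values=values,
    )


class TestMissingFilter:
    def test_single_missing_cell_removes_column(self):
        m = make_matrix({"a": [1, 2, 3], "b": [1, np.nan, 3], "c": [4, 5, 6]})
        out, rep = filter_missing(m)
        assert rep.removed_columns == ["b"]
        assert out.column_names == ["a", "c"]
        assert not out.missing_mask.any()

    def test_no_missing_is_identity(self):
        m = make_matrix({"a": [1, 2, 3], "b": [4, 5, 6]})
        out, rep = filter_missing(m)
        assert rep.removed_columns == [] and out.column_names == m.column_names

    def test_fully_missing_column_removed(self):
        m = make_matrix({"a": [1, 2], "b": [np.nan, np.nan]})
        out, _ = filter_missing(m)
        assert out.column_names == ["a"]

    def test_all_columns_removed_is_an_error(self):
        m = make_matrix({"a": [np.nan, 1.0]})
        with pytest.raises(FilterError):
            filter_missing(m)


class TestConstantFilters:
    def test_constant_column_removed(self):
        m = make_matrix({"a": [7, 7, 7, 7], "b": [1, 2, 3, 4]})
        out, rep = filter_constant(m)
        assert rep.removed_columns == ["a"] and out.column_names == ["b"]

    def test_near_constant_one_deviant_removed_two_retained(self):
        m = make_matrix(
            {"nc": [0, 0, 0, 0, 1], "ok": [0, 0, 0, 1, 1], "x": [1, 2, 3, 4, 5]}
        )
        out, rep = filter_near_constant(m)
        assert rep.removed_columns == ["nc"]
        assert out.column_names == ["ok", "x"]


class TestCorrelationFilter:
    def test_tie_broken_by_removing_later_column(self):
        # c2 = 2*c1 (r=1); both have identical mean |r| vs c3 -> drop c2.
        m = make_matrix(
            {"c1": [1, 2, 3, 4], "c2": [2, 4, 6, 8], "c3": [1, 0, 0, 1]}
        )
        out, rep = filter_correlated(m, threshold=0.95)
        assert rep.removed_columns == ["c2"]
        assert out.column_names == ["c1", "c3"]

    def test_uncorrelated_is_identity(self, rng):
        X = rng.standard_normal((50, 6))
        m = make_matrix({f"c{j}": X[:, j] for j in range(6)})
        out, rep = filter_correlated(m)
        assert rep.removed_columns == []

    def test_three_collinear_columns_drop_exactly_two(self):
        x = np.arange(6.0)
        m = make_matrix({"a": x, "b": 3 * x + 1, "c": -2 * x, "d": [5, 1, 4, 1, 5, 9]})
        out, _ = filter_correlated(m)
        survivors = [c for c in out.column_names if c in {"a", "b", "c"}]
        assert len(survivors) == 1
        R = np.corrcoef(out.values, rowvar=False)
        np.fill_diagonal(R, 0)
        assert np.all(np.abs(R) <= 0.95)

    def test_invalid_threshold(self):
        m = make_matrix({"a": [1.0, 2, 3], "b": [3.0, 1, 2]})
        for bad in (0, -0.1, 1.5):
            with pytest.raises(FilterError):
                filter_correlated(m, threshold=bad)

    def test_postcondition_audit_random_matrices(self, rng):
        """Exhaustive O(p^2) scan finds no surviving pair above threshold."""
        for _ in range(10):
            base = rng.standard_normal((40, 8))
            dup = base[:, :3] + 0.05 * rng.standard_normal((40, 3))
            X = np.hstack([base, dup])
            m = make_matrix({f"c{j}": X[:, j] for j in range(X.shape[1])})
            out, _ = filter_correlated(m, threshold=0.95)
            R = np.abs(np.corrcoef(out.values, rowvar=False))
            np.fill_diagonal(R, 0)
            assert R.max() <= 0.95


class TestLoadingFilter:
    def test_dominant_factor_column_retained(self, rng):
        """A column equal to the dominant latent factor loads far above 0.06."""
        factor = rng.standard_normal(60)
        cols = {"signal": factor}
        for j in range(9):
            cols[f"echo{j}"] = factor + 0.3 * rng.standard_normal(60)
        m = make_matrix(cols)
        out, _ = pca_loading_filter(m, n_components=2, threshold=0.06)
        assert "signal" in out.column_names

    def test_zero_threshold_is_identity(self, rng):
        X = rng.standard_normal((20, 6))
        m = make_matrix({f"c{j}": X[:, j] for j in range(6)})
        out, rep = pca_loading_filter(m, n_components=3, threshold=0.0)
        assert rep.removed_columns == []

    def test_pure_noise_column_removed_with_high_probability(self):
        """With strong planted structure captured by the leading PCs, a pure
        noise column rarely reaches the loading threshold."""
        removed = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            factors = rng.standard_normal((160, 3))
            cols = {}
            for j in range(60):
                w = rng.standard_normal(3)
                cols[f"s{j}"] = factors @ w + 0.1 * rng.standard_normal(160)
            cols["noise"] = rng.standard_normal(160)
            m = make_matrix(cols)
            out, _ = pca_loading_filter(m, n_components=3, threshold=0.06)
            removed += "noise" not in out.column_names
        assert removed >= 16

    def test_too_many_components_rejected(self, rng):
        X = rng.standard_normal((5, 3))
        m = make_matrix({f"c{j}": X[:, j] for j in range(3)})
        with pytest.raises(Exception):
            pca_loading_filter(m, n_components=5)


class TestOutlierFlagging:
    def test_planted_outlier_along_pc1_flagged(self, rng):
        factors = rng.standard_normal((50, 2))
        X = np.hstack(
            [factors @ rng.standard_normal((2, 8)) + 0.2 * rng.standard_normal((50, 8))]
        )
        m = make_matrix({f"c{j}": X[:, j] for j in range(8)})
        model_dir = np.linalg.svd(X - X.mean(0), full_matrices=False)[2][0]
        sd = X.std(axis=0, ddof=1)
        X2 = X.copy()
        X2[7] = X.mean(0) + 20 * sd * model_dir / np.abs(model_dir).max()
        m2 = make_matrix({f"c{j}": X2[:, j] for j in range(8)})
        flagged = flag_score_outliers(m2, n_components=2, alpha=0.025)
        assert "r7" in flagged

    def test_false_flag_rate_matches_alpha(self):
        """Homogeneous Gaussian data: flag fraction ~ alpha (Monte-Carlo)."""
        alpha, n, trials = 0.05, 400, 30
        total_flags = 0
        for seed in range(trials):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((n, 5))
            m = make_matrix({f"c{j}": X[:, j] for j in range(5)})
            total_flags += len(flag_score_outliers(m, n_components=5, alpha=alpha))
        n_total = n * trials
        expect = alpha * n_total
        sd = np.sqrt(n_total * alpha * (1 - alpha))
        assert abs(total_flags - expect) < 2 * sd + 5

    def test_identical_rows_flag_nothing(self):
        m = make_matrix({"a": [1.0, 1, 1], "b": [2.0, 2, 2]})
        assert flag_score_outliers(m) == []


class TestCascade:
    def test_each_filter_is_idempotent(self, small_synth):
        _, matrix, _ = small_synth
        m1, _ = filter_missing(matrix)
        m1b, rep = filter_missing(m1)
        assert rep.removed_columns == []
        m2, _ = filter_constant(m1)
        _, rep = filter_constant(m2)
        assert rep.removed_columns == []
        m3, _ = filter_near_constant(m2)
        _, rep = filter_near_constant(m3)
        assert rep.removed_columns == []
        m4, _ = filter_correlated(m3)
        _, rep = filter_correlated(m4)
        assert rep.removed_columns == []

    def test_cascade_order_and_disjoint_reports(self, small_synth):
        _, matrix, _ = small_synth
        reduced, reports = run_filter_cascade(matrix)
        assert [r.filter_name for r in reports] == [
            "missing", "constant", "near_constant", "correlated", "pca_loading"
        ]
        all_removed = [c for r in reports for c in r.removed_columns]
        assert len(all_removed) == len(set(all_removed))
        assert len(reduced.column_names) + len(all_removed) == matrix.p
        assert [name for name, _ in reduced.filter_log] == [
            r.filter_name for r in reports
        ]
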