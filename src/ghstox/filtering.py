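"""Descriptor-reduction cascade and PCA-based outlier flagging.

The cascade runs in a fixed order — missing-value, constant, near-constant,
pairwise-correlation, PCA-loading — each stage consuming the previous
stage's output and emitting a machine-readable :class:`FilterReport`.
Score-space outlier flagging is advisory only: rows are flagged, never
removed, so removal stays an explicit pipeline step.

Conventions (the source descriptions leave these open):

* "near constant" = all values identical except in at most one row;
* correlation = Pearson |r| on raw columns (scale-invariant);
* offending pairs are processed greedily in descending |r|, removing the
  member with the larger mean |r| against all other input columns
  (criterion computed once, not updated after removals); ties remove the
  larger column index;
* the loading filter keeps a column iff max |loading| across the leading
  components is strictly greater than the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .dataset import DescriptorMatrix
from .pca import fit_pca


class FilterError(ValueError):
    pass


@dataclass
class FilterReport:
    filter_name: str
    removed_columns: list[str]
    parameters: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "filter_name": self.filter_name,
            "removed_columns": list(self.removed_columns),
            "parameters": dict(self.parameters),
        }


def _apply_removal(
    matrix: DescriptorMatrix, name: str, removed: list[str], params: dict
) -> tuple[DescriptorMatrix, FilterReport]:
    keep = [c for c in matrix.column_names if c not in set(removed)]
    if not keep:
        raise FilterError(f"{name}: all columns would be removed")
    out = matrix.select_columns(keep)
    out.filter_log.append((name, list(removed)))
    return out, FilterReport(filter_name=name, removed_columns=removed, parameters=params)


def filter_missing(matrix: DescriptorMatrix) -> tuple[DescriptorMatrix, FilterReport]:
    """Discard every descriptor with one or more missing values."""
    has_missing = matrix.missing_mask.any(axis=0)
    removed = [c for c, m in zip(matrix.column_names, has_missing) if m]
    return _apply_removal(matrix, "missing", removed, {})


def filter_constant(matrix: DescriptorMatrix) -> tuple[DescriptorMatrix, FilterReport]:
    """Remove columns whose values are all identical."""
    _require_complete(matrix, "filter_constant")
    X = matrix.values
    is_const = np.all(X == X[0, :], axis=0)
    removed = [c for c, m in zip(matrix.column_names, is_const) if m]
    return _apply_removal(matrix, "constant", removed, {})


def filter_near_constant(matrix: DescriptorMatrix) -> tuple[DescriptorMatrix, FilterReport]:
    """Remove columns identical in all but at most one row.

    A strictly constant column also satisfies the rule; running the cascade
    in order, such columns are gone before this stage.
    """
    _require_complete(matrix, "filter_near_constant")
    removed = []
    for j, name in enumerate(matrix.column_names):
        _, counts = np.unique(matrix.values[:, j], return_counts=True)
        if counts.max() >= matrix.n - 1:
            removed.append(name)
    return _apply_removal(matrix, "near_constant", removed, {})


def _require_complete(matrix: DescriptorMatrix, op: str) -> None:
    if matrix.missing_mask.any():
        raise FilterError(f"{op} requires a complete matrix; run filter_missing first")


def filter_correlated(
    matrix: DescriptorMatrix, threshold: float = 0.95
) -> tuple[DescriptorMatrix, FilterReport]:
    """Break up descriptor pairs with Pearson |r| above ``threshold``.

    For each offending pair, taken in descending |r|, the member with the
    larger mean absolute correlation to all other input columns is removed
    (if still present); ties remove the larger column index.  The retained
    set is guaranteed to contain no pair with |r| > threshold.
    """
    if not 0 < threshold <= 1:
        raise FilterError(f"threshold must be in (0, 1], got {threshold}")
    _require_complete(matrix, "filter_correlated")
    X = matrix.values
    p = matrix.p
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = matrix.column_names[int(np.flatnonzero(sd == 0)[0])]
        raise FilterError(
            f"filter_correlated requires non-constant columns (found {bad!r}); "
            "run the constant filter first"
        )
    with np.errstate(invalid="ignore"):
        R = np.corrcoef(X, rowvar=False)
    absR = np.abs(R)
    np.fill_diagonal(absR, 0.0)
    # Mean |r| of each column vs all other input columns, computed once.
    mean_abs = absR.sum(axis=0) / (p - 1) if p > 1 else np.zeros(p)
    iu, ju = np.triu_indices(p, k=1)
    offending = np.flatnonzero(absR[iu, ju] > threshold)
    order = offending[np.argsort(-absR[iu, ju][offending], kind="stable")]
    removed_idx: set[int] = set()
    for t in order:
        a, b = int(iu[t]), int(ju[t])
        if a in removed_idx or b in removed_idx:
            continue
        if mean_abs[a] > mean_abs[b]:
            removed_idx.add(a)
        elif mean_abs[b] > mean_abs[a]:
            removed_idx.add(b)
        else:
            removed_idx.add(max(a, b))
    removed = [matrix.column_names[j] for j in sorted(removed_idx)]
    return _apply_removal(matrix, "correlated", removed, {"threshold": threshold})


def pca_loading_filter(
    matrix: DescriptorMatrix, n_components: int = 10, threshold: float = 0.06
) -> tuple[DescriptorMatrix, FilterReport]:
    """Keep columns whose max |loading| over the leading PCs exceeds ``threshold``.

    Columns that never load above the threshold on any of the
    ``n_components`` strongest components carry no structured variance and
    are discarded as irrelevant.
    """
    _require_complete(matrix, "pca_loading_filter")
    model = fit_pca(matrix.values, n_components=n_components)
    max_abs_loading = np.abs(model.loadings).max(axis=1)
    removed = [
        c for c, m in zip(matrix.column_names, max_abs_loading) if not (m > threshold)
    ]
    return _apply_removal(
        matrix,
        "pca_loading",
        removed,
        {"n_components": n_components, "threshold": threshold},
    )


def flag_score_outliers(
    matrix: DescriptorMatrix, n_components: int = 10, alpha: float = 0.025
) -> list[str]:
    """Flag rows with an extreme Hotelling-type squared score distance.

    The squared distance sums ``score_c^2 / var(score_c)`` over the leading
    components and is compared with the chi-square upper-``alpha`` quantile
    on ``n_components`` degrees of freedom.  Rows are FLAGGED only; removal
    is a separate, explicit pipeline step.  Degenerate inputs with no score
    variance flag nothing.
    """
    _require_complete(matrix, "flag_score_outliers")
    X = matrix.values
    sd = X.std(axis=0, ddof=1) if matrix.n > 1 else np.zeros(matrix.p)
    usable = int(np.count_nonzero(sd > 0))
    if usable == 0:
        return []
    n_components = min(n_components, matrix.n - 1, usable)
    if n_components < 1:
        return []
    sub = matrix.select_columns(
        [c for c, s in zip(matrix.column_names, sd) if s > 0]
    )
    model = fit_pca(sub.values, n_components=n_components)
    var = model.component_variance
    positive = var > 1e-12
    if not positive.any():
        return []
    t2 = np.sum(model.scores[:, positive] ** 2 / var[positive], axis=1)
    cutoff = stats.chi2.ppf(1 - alpha, df=int(positive.sum()))
    return [rid for rid, v in zip(matrix.row_ids, t2) if v > cutoff]


def run_filter_cascade(
    matrix: DescriptorMatrix,
    correlation_threshold: float = 0.95,
    pca_components: int = 10,
    loading_threshold: float = 0.06,
    skip_correlation: bool = False,
) -> tuple[DescriptorMatrix, list[FilterReport]]:
    """Run the full cascade: missing -> constant -> near-constant ->
    correlated -> PCA loading.  Returns the reduced matrix and one report
    per stage."""
    reports: list[FilterReport] = []
    matrix, rep = filter_missing(matrix)
    reports.append(rep)
    matrix, rep = filter_constant(matrix)
    reports.append(rep)
    matrix, rep = filter_near_constant(matrix)
    reports.append(rep)
    if not skip_correlation:
        matrix, rep = filter_correlated(matrix, threshold=correlation_threshold)
        reports.append(rep)
    n_comp = min(pca_components, matrix.n - 1, matrix.p)
    matrix, rep = pca_loading_filter(
        matrix, n_components=n_comp, threshold=loading_threshold
    )
    reports.append(rep)
    return matrix, reports
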