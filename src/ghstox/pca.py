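"""Autoscaling and principal component analysis for descriptor matrices.

PCA here serves two roles: a descriptor-relevance filter (columns whose
loadings never exceed a threshold across the leading components carry no
structured variance) and the interpretation layer — score plots colored by
toxicity class and correlation-loading plots with the 50%/100%
explained-variance circles.

Implementation is SVD-based on the autoscaled matrix.  Sign convention:
the largest-|loading| entry of each component is made positive, so loadings
and scores are deterministic across runs and platforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np


class PCAError(ValueError):
    pass


def autoscale(
    values: np.ndarray,
    column_names: Optional[Sequence[str]] = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column-wise standardization to mean 0, sample SD 1 (n-1 denominator).

    Returns ``(scaled, means, scales)``.  A zero-variance column is an
    error naming the column: it cannot be autoscaled.
    """
    X = np.asarray(values, dtype=float)
    if np.isnan(X).any():
        raise PCAError("autoscale requires a complete matrix (missing values present)")
    means = X.mean(axis=0)
    scales = X.std(axis=0, ddof=1)
    zero = np.flatnonzero(scales == 0)
    if zero.size:
        name = column_names[zero[0]] if column_names is not None else f"#{zero[0]}"
        raise PCAError(f"zero-variance column {name!r} cannot be autoscaled")
    return (X - means) / scales, means, scales


@dataclass
class PCAModel:
    """Fitted PCA: scaling parameters, loadings, scores and variance shares.

    ``explained_fraction`` is each retained component's share of the TOTAL
    variance (all ``min(n-1, p)`` components), so the shares of a full
    decomposition sum to 1.
    """

    means: np.ndarray
    scales: np.ndarray
    loadings: np.ndarray  # (p, C), orthonormal columns
    scores: np.ndarray  # (n, C)
    explained_fraction: np.ndarray  # (C,)
    component_variance: np.ndarray  # (C,) score variances (n-1 denominator)

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def transform(self, values: np.ndarray) -> np.ndarray:
        """Project new rows using the training scaling and loadings."""
        X = (np.asarray(values, dtype=float) - self.means) / self.scales
        return X @ self.loadings

    def correlation_loadings(self) -> np.ndarray:
        """Loadings rescaled to variable-component correlations.

        For autoscaled data the correlation between variable j and component
        c is ``loading[j, c] * sqrt(var(score_c))``; the squared entries of a
        row sum to the fraction of that variable's variance explained, so a
        variable fully captured by the plotted components lies on the unit
        circle.
        """
        return self.loadings * np.sqrt(self.component_variance)


def fit_pca(values: np.ndarray, n_components: int) -> PCAModel:
    """Fit PCA on a raw matrix (autoscaling applied internally).

    Components are ordered by non-increasing explained variance.
    ``n_components`` must not exceed ``min(n-1, p)``.
    """
    X = np.asarray(values, dtype=float)
    n, p = X.shape
    max_rank = min(n - 1, p)
    if not 1 <= n_components <= max_rank:
        raise PCAError(
            f"n_components must be in [1, min(n-1, p)] = [1, {max_rank}], got {n_components}"
        )
    Z, means, scales = autoscale(X)
    # Economy SVD: Z = U S Vt; loadings = V columns, score variance = s^2/(n-1).
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    total_variance = float(np.sum(s**2)) / (n - 1)
    loadings = Vt[:n_components].T.copy()
    scores = U[:, :n_components] * s[:n_components]
    # Deterministic sign: largest-|loading| entry of each component positive.
    for c in range(n_components):
        j = int(np.argmax(np.abs(loadings[:, c])))
        if loadings[j, c] < 0:
            loadings[:, c] *= -1
            scores[:, c] *= -1
    comp_var = (s[:n_components] ** 2) / (n - 1)
    explained = comp_var / total_variance
    return PCAModel(
        means=means,
        scales=scales,
        loadings=loadings,
        scores=scores,
        explained_fraction=explained,
        component_variance=comp_var,
    )


def loading_circle_radius(fraction: float) -> float:
    """Radius of the explained-variance circle on a correlation-loading plot.

    A variable whose first two components explain fraction ``f`` of its
    variance lies at distance ``sqrt(f)`` from the origin, so the 100%
    circle has radius 1 and the 50% circle radius ``sqrt(0.5)``.
    """
    if not 0 < fraction <= 1:
        raise PCAError(f"fraction must be in (0, 1], got {fraction}")
    return math.sqrt(fraction)


def render_score_loading_report(
    model: PCAModel,
    labels: Sequence[int],
    column_names: Sequence[str],
    out_dir: str | Path,
    prefix: str = "pca",
    annotate_top: int = 8,
) -> dict:
    """Write a class-colored score plot, a loading plot with the 50%/100%
    variance circles, and a text table of per-component explained variance.

    Returns a summary dict with the file paths and the explained-variance
    percentages of the two plotted components.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .dataset import ROMAN

    if model.n_components < 2:
        raise PCAError("score/loading report needs at least 2 components")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    labels = np.asarray(labels)
    pc1, pc2 = model.explained_fraction[0] * 100, model.explained_fraction[1] * 100

    colors = {1: "tab:blue", 2: "tab:red", 3: "tab:green"}
    fig, ax = plt.subplots(figsize=(6, 5))
    for cls in sorted(set(labels.tolist())):
        mask = labels == cls
        ax.scatter(
            model.scores[mask, 0],
            model.scores[mask, 1],
            s=18,
            label=f"class {ROMAN.get(cls, cls)}",
            color=colors.get(cls),
            alpha=0.75,
        )
    ax.axhline(0, color="grey", lw=0.5)
    ax.axvline(0, color="grey", lw=0.5)
    ax.set_xlabel(f"PC1 ({pc1:.1f}% variance)")
    ax.set_ylabel(f"PC2 ({pc2:.1f}% variance)")
    ax.legend()
    ax.set_title(f"Score plot (PC1+PC2 = {pc1 + pc2:.1f}%)")
    score_path = out_dir / f"{prefix}_scores.png"
    fig.savefig(score_path, dpi=120, bbox_inches="tight")
    plt.close(fig)

    cl = model.correlation_loadings()
    fig, ax = plt.subplots(figsize=(5.5, 5.5))
    theta = np.linspace(0, 2 * np.pi, 256)
    for frac, style in ((1.0, "-"), (0.5, "--")):
        r = loading_circle_radius(frac)
        ax.plot(r * np.cos(theta), r * np.sin(theta), style, color="grey", lw=1)
    ax.scatter(cl[:, 0], cl[:, 1], s=12, color="tab:purple", alpha=0.8)
    radii = np.hypot(cl[:, 0], cl[:, 1])
    for j in np.argsort(radii)[::-1][:annotate_top]:
        ax.annotate(column_names[j], (cl[j, 0], cl[j, 1]), fontsize=7)
    ax.axhline(0, color="grey", lw=0.5)
    ax.axvline(0, color="grey", lw=0.5)
    ax.set_xlabel(f"PC1 ({pc1:.1f}% variance)")
    ax.set_ylabel(f"PC2 ({pc2:.1f}% variance)")
    ax.set_title("Correlation loadings (outer: 100%, inner: 50%)")
    ax.set_aspect("equal")
    loading_path = out_dir / f"{prefix}_loadings.png"
    fig.savefig(loading_path, dpi=120, bbox_inches="tight")
    plt.close(fig)

    lines = ["component\texplained_pct\tcumulative_pct"]
    cum = 0.0
    for c, frac in enumerate(model.explained_fraction, start=1):
        cum += frac * 100
        lines.append(f"PC{c}\t{frac * 100:.2f}\t{cum:.2f}")
    table_path = out_dir / f"{prefix}_variance.tsv"
    table_path.write_text("\n".join(lines) + "\n")

    return {
        "score_plot": str(score_path),
        "loading_plot": str(loading_path),
        "variance_table": str(table_path),
        "pc1_pct": float(pc1),
        "pc2_pct": float(pc2),
        "pc1_plus_pc2_pct": float(pc1 + pc2),
    }
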