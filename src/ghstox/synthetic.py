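"""Synthetic chemicals + descriptor benchmark with planted structure.

Real acute-toxicity QSAR tables pair a few hundred chemicals with a
thousand-plus machine-computed descriptors, of which only a handful carry
signal while the rest are noise, near-duplicates of each other, constant
padding, or hold missing values.  The generator emulates exactly that
landscape and returns a ground-truth manifest so every pipeline stage can
be scored on recovery:

* a small informative set drives log10(LD50) linearly plus unit noise;
* duplicate columns correlate |r| >= 0.96 with their source;
* constant and near-constant padding columns;
* missing cells confined to designated "fragile" noise columns, so the
  missing-value filter never destroys testable structure;
* a few rows displaced by 10 column-SD along a random direction
  (multivariate outliers);
* the GHS class split is matched exactly to the target fractions by
  mapping latent-variable quantiles onto the 300/2000 mg/kg cuts.

Identical config + seed gives bit-identical output.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .dataset import (
    ChemicalRecord,
    DescriptorMatrix,
    GHS_CLASS_I_MAX,
    GHS_CLASS_II_MAX,
)


class SynthError(ValueError):
    pass


@dataclass
class SynthConfig:
    """Generator knobs; defaults mirror a ~436 x 1000 descriptor table
    with three GHS classes split 103:171:162."""

    n_chemicals: int = 436
    n_informative: int = 10
    n_noise: int = 960
    n_correlated_pairs: int = 20
    n_constant: int = 5
    n_near_constant: int = 5
    missing_rate: float = 0.02
    n_outliers: int = 5
    effect_size: float = 1.0
    class_target_fractions: tuple[float, float, float] = (103 / 436, 171 / 436, 162 / 436)
    seed: int = 0

    def validate(self) -> None:
        counts = (
            self.n_chemicals,
            self.n_informative,
            self.n_noise,
            self.n_correlated_pairs,
            self.n_constant,
            self.n_near_constant,
            self.n_outliers,
        )
        if any(c < 0 for c in counts):
            raise SynthError("all counts must be >= 0")
        if self.n_chemicals < 10:
            raise SynthError("need at least 10 chemicals")
        if not 0 <= self.missing_rate < 1:
            raise SynthError("missing_rate must be in [0, 1)")
        if self.effect_size < 0:
            raise SynthError("effect_size must be >= 0")
        if abs(sum(self.class_target_fractions) - 1) > 1e-9:
            raise SynthError("class_target_fractions must sum to 1")
        if self.n_correlated_pairs > self.n_informative + self.n_noise:
            raise SynthError("more correlated pairs than available source columns")
        if self.n_outliers > self.n_chemicals // 4:
            raise SynthError("too many outlier rows")


@dataclass
class GroundTruth:
    informative_columns: list[str]
    correlated_columns: list[str]  # the planted duplicates
    correlated_pairs: list[tuple[str, str]]  # (source, duplicate)
    constant_columns: list[str]
    near_constant_columns: list[str]
    fragile_columns: list[str]  # noise columns carrying the missing cells
    outlier_rows: list[str]
    coefficients: dict[str, float]  # nonzero for informative columns only

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        d["correlated_pairs"] = [tuple(p) for p in d["correlated_pairs"]]
        return cls(**d)


def _class_counts(n: int, fractions: Sequence[float]) -> tuple[int, int, int]:
    """Integer class sizes nearest the target fractions, summing to n."""
    n1 = round(fractions[0] * n)
    n2 = round((fractions[0] + fractions[1]) * n) - n1
    n3 = n - n1 - n2
    if min(n1, n2, n3) < 1:
        raise SynthError(f"target fractions give an empty class: ({n1}, {n2}, {n3})")
    return n1, n2, n3


def generate(
    config: SynthConfig,
) -> tuple[list[ChemicalRecord], DescriptorMatrix, GroundTruth]:
    """Generate the chemicals table, descriptor matrix and ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_chemicals
    row_ids = [f"CHEM{i + 1:04d}" for i in range(n)]

    inf_names = [f"INF{j + 1:03d}" for j in range(config.n_informative)]
    noise_names = [f"NOI{j + 1:04d}" for j in range(config.n_noise)]
    X_inf = rng.standard_normal((n, config.n_informative))
    X_noise = rng.standard_normal((n, config.n_noise))

    signs = rng.choice([-1.0, 1.0], size=config.n_informative)
    betas = config.effect_size * signs
    latent = X_inf @ betas + rng.standard_normal(n)

    # Map latent quantiles onto the 300/2000 mg/kg cuts so realized class
    # counts hit the targets exactly (low latent = low LD50 = class I).
    n1, n2, _ = _class_counts(n, config.class_target_fractions)
    order = np.sort(latent)
    t1 = 0.5 * (order[n1 - 1] + order[n1])
    t2 = 0.5 * (order[n1 + n2 - 1] + order[n1 + n2])
    lo, hi = math.log10(GHS_CLASS_I_MAX), math.log10(GHS_CLASS_II_MAX)
    b = (hi - lo) / (t2 - t1)
    a = lo - b * t1
    log_ld50 = a + b * latent
    ld50 = 10.0**log_ld50

    # Multivariate outliers: displace rows 10 column-SD along a random
    # direction in the informative+noise space.  Displacement happens BEFORE
    # duplicate columns are derived, so an outlying chemical is outlying
    # coherently in a descriptor and its near-duplicate — as a structurally
    # extreme molecule would be — and planted correlations survive.
    base = np.concatenate([X_inf, X_noise], axis=1)
    outlier_rows: list[str] = []
    if config.n_outliers:
        sd = base.std(axis=0, ddof=1)
        chosen = rng.choice(n, size=config.n_outliers, replace=False)
        for i in chosen:
            u = rng.standard_normal(base.shape[1])
            u /= np.linalg.norm(u)
            base[i] += 10.0 * sd * u
            outlier_rows.append(row_ids[int(i)])
        outlier_rows.sort()
        X_inf = base[:, : config.n_informative]
        X_noise = base[:, config.n_informative:]

    # Duplicate columns: source + small noise, population r ~ 0.989.
    source_pool = inf_names + noise_names
    src_idx = rng.choice(len(source_pool), size=config.n_correlated_pairs, replace=False)
    dup_names = [f"DUP{j + 1:03d}" for j in range(config.n_correlated_pairs)]
    pairs: list[tuple[str, str]] = []
    dup_cols = np.empty((n, config.n_correlated_pairs))
    for j, s in enumerate(src_idx):
        eta = 0.15
        src = base[:, s]
        while True:
            dup = src + eta * src.std(ddof=1) * rng.standard_normal(n)
            if abs(np.corrcoef(src, dup)[0, 1]) >= 0.96:
                break
            eta *= 0.5
        dup_cols[:, j] = dup
        pairs.append((source_pool[int(s)], dup_names[j]))

    const_names = [f"CON{j + 1:03d}" for j in range(config.n_constant)]
    const_cols = np.tile(rng.uniform(-5, 5, size=config.n_constant), (n, 1))
    ncn_names = [f"NCN{j + 1:03d}" for j in range(config.n_near_constant)]
    ncn_cols = np.tile(rng.uniform(-5, 5, size=config.n_near_constant), (n, 1))
    for j in range(config.n_near_constant):
        row = rng.integers(n)
        ncn_cols[row, j] += rng.uniform(1.0, 3.0)

    values = np.concatenate([X_inf, X_noise, dup_cols, const_cols, ncn_cols], axis=1)
    names = inf_names + noise_names + dup_names + const_names + ncn_names

    # Missing cells only in designated fragile noise columns.
    fragile: list[str] = []
    missing = np.zeros_like(values, dtype=bool)
    if config.missing_rate > 0 and config.n_noise > 0:
        n_fragile = max(1, config.n_noise // 20)
        frag_idx = rng.choice(config.n_noise, size=n_fragile, replace=False)
        frag_idx = np.sort(frag_idx)
        for j in frag_idx:
            col = len(inf_names) + int(j)
            cells = rng.random(n) < config.missing_rate
            if not cells.any():
                cells[rng.integers(n)] = True
            missing[:, col] = cells
            fragile.append(noise_names[int(j)])
    values = values.copy()
    values[missing] = np.nan

    records = [
        ChemicalRecord(id=rid, ld50=float(v)) for rid, v in zip(row_ids, ld50)
    ]
    matrix = DescriptorMatrix(
        row_ids=row_ids, column_names=names, values=values, missing_mask=missing
    )
    truth = GroundTruth(
        informative_columns=inf_names,
        correlated_columns=dup_names,
        correlated_pairs=pairs,
        constant_columns=const_names,
        near_constant_columns=ncn_names,
        fragile_columns=fragile,
        outlier_rows=outlier_rows,
        coefficients={c: float(b) for c, b in zip(inf_names, betas)},
    )
    return records, matrix, truth


def hypergeom_enrichment_p(
    n_universe: int, n_informative: int, n_selected: int, overlap: int
) -> float:
    """P(X >= overlap) for a uniform draw of ``n_selected`` from the universe."""
    return float(stats.hypergeom.sf(overlap - 1, n_universe, n_informative, n_selected))


def recovery_report(
    truth: GroundTruth,
    filter_reports: Optional[Sequence] = None,
    candidate_columns: Optional[Sequence[str]] = None,
    selected_columns: Optional[Sequence[str]] = None,
    flagged_outliers: Optional[Sequence[str]] = None,
) -> dict:
    """Score pipeline outputs against the planted structure.

    Reports whichever parts the supplied outputs allow: nuisance-column
    removal fractions from the filter reports, GA-selection overlap with
    the informative set plus its hypergeometric enrichment p-value, and
    outlier-flagging recall.
    """
    report: dict = {}
    if filter_reports is not None:
        removed: set[str] = set()
        for r in filter_reports:
            removed |= set(r.removed_columns)

        def frac(cols: list[str]) -> Optional[float]:
            return len(removed & set(cols)) / len(cols) if cols else None

        report["filter_recovery"] = {
            "constant_removed_fraction": frac(truth.constant_columns),
            "near_constant_removed_fraction": frac(truth.near_constant_columns),
            "fragile_removed_fraction": frac(truth.fragile_columns),
            "correlated_pairs_broken_fraction": (
                sum(
                    1
                    for s, d in truth.correlated_pairs
                    if s in removed or d in removed
                )
                / len(truth.correlated_pairs)
                if truth.correlated_pairs
                else None
            ),
        }
    if selected_columns is not None and candidate_columns is not None:
        informative_in_play = set(truth.informative_columns) & set(candidate_columns)
        overlap = len(set(selected_columns) & informative_in_play)
        report["selection_recovery"] = {
            "n_selected": len(list(selected_columns)),
            "overlap_with_informative": overlap,
            "informative_available": len(informative_in_play),
            "enrichment_p": hypergeom_enrichment_p(
                len(list(candidate_columns)),
                len(informative_in_play),
                len(list(selected_columns)),
                overlap,
            ),
        }
    if flagged_outliers is not None:
        planted = set(truth.outlier_rows)
        if planted:
            recall = len(set(flagged_outliers) & planted) / len(planted)
        else:
            recall = None
        report["outlier_recovery"] = {
            "n_flagged": len(list(flagged_outliers)),
            "recall": recall,
        }
    return report
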