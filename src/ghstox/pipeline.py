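"""End-to-end orchestration: curate -> discretize -> filter -> split ->
GA/k-NN -> evaluate -> PCA report.

A single global seed expands deterministically into per-stage seeds (split,
GA, scrambling), so every stage is individually reproducible and two runs
with the same config + seed produce byte-identical JSON reports.  All
thresholds (0.95 correlation, 0.06 loading, 10 PCs, 300/2000 mg/kg class
cuts, 5 folds, 80/20 split) are config defaults, never hard-coded in the
stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from . import __version__
from .dataset import (
    ChemicalRecord,
    DescriptorMatrix,
    align_tables,
    curate_structures,
    read_chemicals_table,
    read_descriptor_matrix,
    write_chemicals_table,
    write_descriptor_matrix,
)
from .filtering import flag_score_outliers, run_filter_cascade
from .ga import GAConfig, finalize_model, ga_select, scrambling_comparison
from .knn import knn_fit_predictions, knn_predict, cv_predictions, make_cv_folds
from .metrics import (
    class_metrics,
    confusion,
    metrics_report_json,
    metrics_table,
)
from .pca import fit_pca, render_score_loading_report
from .splitting import stratified_split
from .synthetic import GroundTruth, SynthConfig, generate, recovery_report

log = logging.getLogger("ghstox")

STAGE_ORDER = (
    "curate",
    "discretize",
    "filter",
    "outliers",
    "split",
    "ga_knn",
    "evaluate",
    "pca_report",
)


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Declarative run configuration (versioned schema ghstox/1)."""

    chemicals_csv: Optional[str] = None
    descriptors_csv: Optional[str] = None
    ground_truth_json: Optional[str] = None
    out_dir: str = "ghstox_run"
    seed: int = 0
    # curation
    curate: bool = True
    curate_remove_patterns: bool = False
    # filter cascade
    correlation_threshold: float = 0.95
    pca_components: int = 10
    loading_threshold: float = 0.06
    skip_correlation: bool = False
    # outliers
    outlier_alpha: float = 0.025
    remove_flagged_outliers: bool = True
    # split
    test_fraction: float = 0.2
    # model
    ga: GAConfig = field(default_factory=GAConfig)
    k_grid: tuple[int, ...] = tuple(range(1, 11))
    n_folds: int = 5
    # figures
    render_figures: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        schema = raw.pop("schema", "ghstox/1")
        if schema != "ghstox/1":
            raise PipelineError(f"unknown config schema {schema!r}")
        ga_raw = raw.pop("ga", {})
        cfg = cls(**raw)
        cfg.ga = GAConfig(**ga_raw)
        if "k_grid" in raw:
            cfg.k_grid = tuple(raw["k_grid"])
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["schema"] = "ghstox/1"
        d["k_grid"] = list(self.k_grid)
        return d


def expand_seeds(seed: int) -> dict[str, int]:
    """One global seed -> independent per-stage seeds (all < 2^31)."""
    state = np.random.SeedSequence(seed).generate_state(3, dtype=np.uint32)
    return {
        "split": int(state[0] % 2**31),
        "ga": int(state[1] % 2**31),
        "synthetic": int(state[2] % 2**31),
    }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(
    config: PipelineConfig,
    records: Optional[Sequence[ChemicalRecord]] = None,
    matrix: Optional[DescriptorMatrix] = None,
    truth: Optional[GroundTruth] = None,
) -> dict:
    """Execute all stages in order; returns the manifest dict.

    Inputs come either from the config's CSV paths or as in-memory objects
    (as produced by :func:`ghstox.synthetic.generate`).  Each stage failure
    aborts with a stage-named error; outputs written so far are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = expand_seeds(config.seed)
    manifest: dict = {
        "tool": "ghstox",
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": seeds,
        "stage_order": list(STAGE_ORDER),
        "config": config.to_dict(),
        "input_hashes": {},
    }

    stage = "load"
    try:
        if records is None or matrix is None:
            if not (config.chemicals_csv and config.descriptors_csv):
                raise PipelineError("no input tables given (paths or in-memory)")
            manifest["input_hashes"]["chemicals_csv"] = _sha256(Path(config.chemicals_csv))
            manifest["input_hashes"]["descriptors_csv"] = _sha256(
                Path(config.descriptors_csv)
            )
            records = read_chemicals_table(config.chemicals_csv)
            matrix = read_descriptor_matrix(config.descriptors_csv)
        if truth is None and config.ground_truth_json:
            truth = GroundTruth.from_json(config.ground_truth_json)
        records, matrix = align_tables(records, matrix)

        stage = "curate"
        if config.curate:
            records, removal = curate_structures(
                records, remove_patterns=config.curate_remove_patterns
            )
            _dump_json(removal, out / "curation_report.json")
            matrix = matrix.select_rows([r.id for r in records])

        stage = "discretize"
        labels = np.array([r.ghs_class for r in records], dtype=int)
        class_order = sorted(set(labels.tolist()))

        stage = "filter"
        matrix, reports = run_filter_cascade(
            matrix,
            correlation_threshold=config.correlation_threshold,
            pca_components=config.pca_components,
            loading_threshold=config.loading_threshold,
            skip_correlation=config.skip_correlation,
        )
        if config.skip_correlation:
            log.warning("correlation filter skipped by explicit config flag")
        with open(out / "filter_reports.jsonl", "w") as fh:
            for r in reports:
                fh.write(json.dumps(r.to_dict(), sort_keys=True) + "\n")
        manifest["n_descriptors_after_filter"] = matrix.p

        stage = "outliers"
        flagged = flag_score_outliers(
            matrix, n_components=min(config.pca_components, matrix.n - 1, matrix.p),
            alpha=config.outlier_alpha,
        )
        _dump_json(
            {"flagged": flagged, "removed": bool(config.remove_flagged_outliers)},
            out / "outliers.json",
        )
        if config.remove_flagged_outliers and flagged:
            keep = [r.id for r in records if r.id not in set(flagged)]
            records = [r for r in records if r.id in set(keep)]
            matrix = matrix.select_rows(keep)
            labels = np.array([r.ghs_class for r in records], dtype=int)
        manifest["n_chemicals_modeled"] = matrix.n

        stage = "split"
        split = stratified_split(
            matrix.row_ids, labels, test_fraction=config.test_fraction,
            seed=seeds["split"],
        )
        split.save(out)
        _dump_json(split.to_dict(), out / "split.json")
        train_matrix = matrix.select_rows(split.train_ids)
        test_matrix = matrix.select_rows(split.test_ids)
        id_to_label = {r.id: r.ghs_class for r in records}
        y_train = np.array([id_to_label[i] for i in split.train_ids], dtype=int)
        y_test = np.array([id_to_label[i] for i in split.test_ids], dtype=int)

        stage = "ga_knn"
        ga_cfg = dataclasses.replace(config.ga, base_seed=seeds["ga"])
        ga_result = ga_select(
            train_matrix.values, y_train, ga_cfg, column_names=train_matrix.column_names
        )
        ga_result.save(out / "ga_result.json")
        if ga_cfg.n_runs_real >= 2 and ga_cfg.n_runs_scrambled >= 2:
            _dump_json(scrambling_comparison(ga_result), out / "scrambling.json")
        selected, model, model_summary = finalize_model(
            ga_result,
            train_matrix.values,
            y_train,
            train_matrix.column_names,
            k_grid=config.k_grid,
            n_folds=config.n_folds,
        )
        model.save(out / "model.json")
        _dump_json(model_summary, out / "model_summary.json")

        stage = "evaluate"
        sel_train = train_matrix.select_columns(selected)
        sel_test = test_matrix.select_columns(selected)
        fit_preds = knn_fit_predictions(model)
        folds = make_cv_folds(len(y_train), n_folds=config.n_folds)
        cv_preds = cv_predictions(sel_train.values, y_train, k=model.k, folds=folds)
        ext_preds = knn_predict(model, sel_test.values)
        m_fit = class_metrics(confusion(y_train, fit_preds, class_order))
        m_cv = class_metrics(confusion(y_train, cv_preds, class_order))
        m_ext = class_metrics(confusion(y_test, ext_preds, class_order))
        table = metrics_table(m_fit, m_cv, m_ext)
        (out / "metrics.txt").write_text(table)
        (out / "metrics.json").write_text(metrics_report_json(m_fit, m_cv, m_ext) + "\n")
        manifest["ner"] = {
            "fitting": m_fit.ner, "cv": m_cv.ner, "external": m_ext.ner,
        }

        stage = "pca_report"
        if config.render_figures and len(selected) >= 3 and sel_train.n >= 4:
            n_comp = min(2, sel_train.n - 1, len(selected))
            if n_comp >= 2:
                train_pca = fit_pca(sel_train.values, n_components=2)
                render_score_loading_report(
                    train_pca, y_train, selected, out, prefix="pca_train"
                )
                if sel_test.n >= 3:
                    test_pca = fit_pca(sel_test.values, n_components=2)
                    render_score_loading_report(
                        test_pca, y_test, selected, out, prefix="pca_test"
                    )

        if truth is not None:
            rec = recovery_report(
                truth,
                filter_reports=reports,
                candidate_columns=train_matrix.column_names,
                selected_columns=selected,
                flagged_outliers=flagged,
            )
            _dump_json(rec, out / "recovery.json")
            manifest["recovery"] = rec
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise PipelineError(f"pipeline stage {stage!r} failed: {exc}") from exc

    _dump_json(manifest, out / "manifest.json")
    return manifest


def simulate_to_dir(config: SynthConfig, out_dir: str | Path) -> tuple[Path, Path, Path]:
    """Generate a synthetic dataset and write the three standard files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records, matrix, truth = generate(config)
    chem = out / "chemicals.csv"
    desc = out / "descriptors.csv"
    gt = out / "ground_truth.json"
    write_chemicals_table(records, chem)
    write_descriptor_matrix(matrix, desc)
    truth.to_json(gt)
    return chem, desc, gt
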