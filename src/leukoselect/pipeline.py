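"""End-to-end orchestration: generate/load -> extract -> split -> select -> classify.

Feature selection is fitted on training rows only and the resulting mask is
applied to the test rows; the ``paper_faithful`` flag switches to the pooled
variant (selection and standardization over the combined train+test matrix),
which leaks test information and is provided for fidelity comparisons only.

Determinism: a single global seed derives one sub-seed per stage, so a run
is a pure function of its config and re-running it writes byte-identical
reports. Stage wall-times are logged and persisted separately (they are the
only non-deterministic output).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._seeding import stage_seed
from .classify import ClassifierSpec, SplitSpec, confusion, metrics, stratified_split, train_and_predict
from .features import ExtractorSpec, FeatureMatrix, extract_features, standardize_matrix
from .selection import FitnessSpec, SelectionResult, select
from .synthetic import SyntheticDatasetSpec, load_samples, read_manifest, sample_dataset

__all__ = ["RunConfig", "RunReport", "ComparisonReport", "run_pipeline", "compare_selectors"]

logger = logging.getLogger("leukoselect")


@dataclass(frozen=True)
class RunConfig:
    """Everything one pipeline run depends on. Exactly one dataset source is set."""

    dataset_spec: SyntheticDatasetSpec | None = None
    image_dir: str | None = None
    feature_csv: str | None = None
    extractor: ExtractorSpec = field(default_factory=ExtractorSpec)
    selector: str = "pso"
    selector_params: object | None = None
    fitness: FitnessSpec = field(default_factory=FitnessSpec)
    classifiers: tuple[ClassifierSpec, ...] = (
        ClassifierSpec("svm_linear"),
        ClassifierSpec("knn"),
        ClassifierSpec("dtree"),
    )
    split: SplitSpec = field(default_factory=SplitSpec)
    out_dir: str | None = None
    seed: int = 0
    paper_faithful: bool = False

    def __post_init__(self) -> None:
        sources = [s is not None for s in (self.dataset_spec, self.image_dir, self.feature_csv)]
        if sum(sources) != 1:
            raise ValueError("exactly one dataset source (synthetic spec, image dir, feature CSV) required")
        if self.selector not in ("pso", "aco", "gwo", "exhaustive", "none"):
            raise ValueError(f"unknown selector {self.selector!r}")


@dataclass(frozen=True)
class RunReport:
    """Per-classifier metrics plus the selection result and a config echo."""

    config_echo: dict
    extractor_source: str
    n_samples: int
    n_features_total: int
    n_features_selected: int
    selection: SelectionResult | None
    classifier_metrics: dict[str, dict]
    predictions: pd.DataFrame = field(repr=False, compare=False)
    feature_names: tuple[str, ...] = ()
    version: str = __version__

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "config": self.config_echo,
            "extractor_source": self.extractor_source,
            "n_samples": self.n_samples,
            "n_features_total": self.n_features_total,
            "n_features_selected": self.n_features_selected,
            "selection": self.selection.to_dict(self.feature_names) if self.selection else None,
            "classifier_metrics": self.classifier_metrics,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def _config_echo(config: RunConfig) -> dict:
    def encode(obj):
        if hasattr(obj, "__dataclass_fields__"):
            return {k: encode(getattr(obj, k)) for k in obj.__dataclass_fields__}
        if isinstance(obj, (tuple, list)):
            return [encode(v) for v in obj]
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return obj

    echo = {k: encode(getattr(config, k)) for k in config.__dataclass_fields__}
    echo["out_dir"] = None  # where a run is written is not part of what it computed
    return echo


_PARAM_TYPES = {"pso": "PsoParams", "aco": "AcoParams", "gwo": "GwoParams"}


def _params_for(selector: str, params) -> object | None:
    """Resolve selector params: a dict keyed by selector name, a matching params
    object, or None for defaults."""
    if params is None:
        return None
    if isinstance(params, dict):
        return params.get(selector)
    if type(params).__name__ == _PARAM_TYPES.get(selector):
        return params
    return None


def _acquire_features(config: RunConfig) -> tuple[FeatureMatrix, str]:
    """Resolve the dataset source into a raw (unstandardized) feature matrix."""
    if config.feature_csv is not None:
        fm = FeatureMatrix.from_csv(config.feature_csv)
        return fm, "external"
    extractor = replace(config.extractor, standardize="none")
    if config.dataset_spec is not None:
        spec = replace(config.dataset_spec, seed=stage_seed(config.seed, "generate"))
        samples = sample_dataset(spec)
        source = "descriptor_bank"
    else:
        manifest = read_manifest(config.image_dir)
        samples = load_samples(manifest, config.image_dir)
        source = "descriptor_bank"
    t0 = time.perf_counter()
    fm = extract_features(samples, extractor)
    logger.info(
        "stage=extract seed=%s in_shape=%s out_shape=%s elapsed=%.2fs",
        config.seed, (len(samples),), fm.values.shape, time.perf_counter() - t0,
    )
    return fm, source


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full flow and optionally persist report/predictions/selection."""
    timings: dict[str, float] = {}

    def timed(stage):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()

            def __exit__(self, *exc):
                timings[stage] = time.perf_counter() - self.t0

        return _T()

    with timed("acquire"):
        fm, source = _acquire_features(config)

    with timed("split"):
        split = stratified_split(
            fm.labels, replace(config.split, seed=stage_seed(config.seed, "split"))
        )
    train_idx = np.asarray(split.train_indices)
    test_idx = np.asarray(split.test_indices)
    logger.info("stage=split seed=%s train=%d test=%d", split.seed, len(train_idx), len(test_idx))

    with timed("standardize"):
        if config.extractor.standardize == "none":
            fm_std = fm
        elif config.paper_faithful or config.extractor.standardize == "pooled":
            fm_std = standardize_matrix(fm)
        else:
            fm_std = standardize_matrix(fm, train_indices=train_idx)

    train_fm = fm_std.select_rows(train_idx)
    test_fm = fm_std.select_rows(test_idx)

    selection: SelectionResult | None = None
    with timed("select"):
        if config.selector != "none":
            fit_spec = replace(config.fitness, rng_seed=stage_seed(config.seed, "fitness"))
            params = _params_for(config.selector, config.selector_params)
            if params is not None and hasattr(params, "rng_seed"):
                params = replace(params, rng_seed=stage_seed(config.seed, "select"))
            sel_input = fm_std if config.paper_faithful else train_fm
            selection = select(config.selector, sel_input, fit_spec, params)
            logger.info(
                "stage=select selector=%s best_fitness=%.4f n_selected=%d n_evaluations=%d",
                config.selector, selection.best_fitness, selection.n_selected, selection.n_evaluations,
            )
            train_fm = train_fm.select_columns(selection.mask)
            test_fm = test_fm.select_columns(selection.mask)

    classifier_metrics: dict[str, dict] = {}
    pred_frames = []
    with timed("classify"):
        for cspec in config.classifiers:
            cspec = replace(cspec, seed=stage_seed(config.seed, f"clf:{cspec.kind}"))
            y_pred = train_and_predict(train_fm.values, train_fm.labels, test_fm.values, cspec)
            report = metrics(confusion(test_fm.labels, y_pred))
            classifier_metrics[cspec.kind] = {
                "metrics_percent": report.as_percentages(),
                "confusion": {"tp": report.cm.tp, "fn": report.cm.fn, "tn": report.cm.tn, "fp": report.cm.fp},
            }
            pred_frames.append(
                pd.DataFrame(
                    {
                        "sample_id": test_fm.sample_ids,
                        "label": test_fm.labels,
                        "classifier": cspec.kind,
                        "prediction": y_pred,
                    }
                )
            )
            logger.info(
                "stage=classify kind=%s accuracy=%.4f", cspec.kind, report.accuracy
            )

    predictions = pd.concat(pred_frames, ignore_index=True)
    report = RunReport(
        config_echo=_config_echo(config),
        extractor_source=source,
        n_samples=fm.n_samples,
        n_features_total=fm.n_features,
        n_features_selected=selection.n_selected if selection else fm.n_features,
        selection=selection,
        classifier_metrics=classifier_metrics,
        predictions=predictions,
        feature_names=tuple(fm.feature_names),
    )

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(report.to_json() + "\n")
        predictions.to_csv(out / "predictions.csv", index=False)
        if selection is not None:
            (out / "selection.json").write_text(
                json.dumps(selection.to_dict(fm.feature_names), indent=2, sort_keys=True) + "\n"
            )
        (out / "timings.json").write_text(json.dumps(timings, indent=2) + "\n")
    return report


@dataclass(frozen=True)
class ComparisonReport:
    """Selector x classifier accuracy grid plus the underlying run reports."""

    runs: dict[str, RunReport]
    metrics_grid: pd.DataFrame = field(repr=False)

    def before_after(self, metric: str = "accuracy") -> pd.DataFrame:
        """Recognition rate without selection ('none') next to each selector's."""
        if "none" not in self.runs:
            raise ValueError("before/after table needs the 'none' (all features) condition")
        grid = self.metrics_grid.loc[self.metrics_grid["metric"] == metric]
        wide = grid.pivot(index="selector", columns="classifier", values="value")
        rows = [wide.loc[["none"]].rename(index={"none": "before"})]
        for sel in wide.index:
            if sel != "none":
                rows.append(wide.loc[[sel]].rename(index={sel: f"after ({sel})"}))
        return pd.concat(rows)

    def render_grid(self) -> str:
        wide = self.metrics_grid.pivot(index=["selector", "metric"], columns="classifier", values="value")
        return wide.to_string(float_format=lambda v: f"{v:.1f}")


def compare_selectors(config: RunConfig, selectors=("pso", "aco", "gwo", "none")) -> ComparisonReport:
    """Run the pipeline once per selector and tabulate Tables-2/3-shaped metrics."""
    if not selectors:
        raise ValueError("need at least one selector")
    runs: dict[str, RunReport] = {}
    records = []
    for sel in selectors:
        sub = replace(
            config,
            selector=sel,
            out_dir=None if config.out_dir is None else str(Path(config.out_dir) / sel),
        )
        report = run_pipeline(sub)
        runs[sel] = report
        for kind, payload in report.classifier_metrics.items():
            display = {"svm_linear": "SVM", "knn": "K-NN", "dtree": "DT"}[kind]
            for metric, value in payload["metrics_percent"].items():
                records.append(
                    {"selector": sel, "classifier": display, "metric": metric, "value": value}
                )
    grid = pd.DataFrame.from_records(records)
    return ComparisonReport(runs=runs, metrics_grid=grid)
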