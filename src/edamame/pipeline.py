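"""End-to-end pipeline: score EHQI, derive phenology features, fit
response surfaces and harvest windows, and screen predictors.

``run_pipeline`` ties the stages together for one trial's CSV inputs
and accounts for every row: input rows = scored rows + dropped rows.
Predictor screening runs on least-square-style means (EHQI and
features averaged within cultivar x environment x planting x harvest),
the aggregation level at which quality prediction is usually reported;
plot-level screening is available via ``aggregate="plots"``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .io import read_quality_csv, read_weather_csv, write_model_json, window_to_dict
from .model_selection import StepwiseResult, fit_neural, stepwise_select, variable_importance
from .phenology import FEATURE_NAMES, PhenoDates, derive_features
from .quality_index import ScoreReport, score_dataset
from .response_surface import HarvestWindow, ResponseSurfaceError, SurfaceModel, fit_surface, harvest_window

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

logger = logging.getLogger(__name__)

#: Predictors offered to the neural screen (the ten non-squared terms).
NEURAL_FEATURES = tuple(
    f for f in FEATURE_NAMES if f not in ("planting_doy_sq", "harvest_doy_sq")
)


@dataclass
class PipelineConfig:
    """Paths, policies and thresholds for one pipeline run."""

    quality_csv: str
    weather_csv: str
    out_dir: str | None = None
    clamp_policy: str = "reject"
    gdd_base_C: float = 7.0
    entry_p: float = 0.15
    stay_p: float = 0.15
    window_tolerance: float = 0.02
    selection: str = "stepwise"
    aggregate: str = "means"
    run_nn: bool = False
    nn_nodes: int = 10
    nn_restarts: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("entry_p", "stay_p", "window_tolerance"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.aggregate not in ("means", "plots"):
            raise ValueError(f"aggregate must be 'means' or 'plots', got {self.aggregate!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


@dataclass
class PipelineResult:
    """All artifacts of one run, plus the row-accounting report."""

    scored: pd.DataFrame
    features: pd.DataFrame
    models: dict[str, SurfaceModel]
    windows: dict[str, HarvestWindow]
    stepwise: dict[str, StepwiseResult]
    neural: dict[str, object] = field(default_factory=dict)
    report: dict = field(default_factory=dict)


def _derive_feature_table(scored: pd.DataFrame, weather, base_C: float) -> pd.DataFrame:
    need = ("ve_doy", "r1_doy")
    for col in need:
        if col not in scored.columns:
            raise ValueError(
                f"feature derivation needs column {col!r} in the quality table"
            )
    rows = []
    for _, row in scored.iterrows():
        wx = weather[row["environment"]] if isinstance(weather, dict) else weather
        dates = PhenoDates(
            planting_doy=int(row["planting_doy"]),
            ve_doy=int(row["ve_doy"]),
            r1_doy=int(row["r1_doy"]),
            harvest_doy=int(row["harvest_doy"]),
            year=int(row["year"]) if "year" in row else 0,
        )
        feats = derive_features(dates, wx, base_C).as_dict()
        feats.update(
            plot_id=row["plot_id"], cultivar=row["cultivar"],
            environment=row["environment"], ehqi=row["ehqi"],
        )
        rows.append(feats)
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute score -> features -> fit/window -> stepwise (-> neural).

    Every stage failure aborts with context; rows dropped during
    scoring are reported, and the run log reconciles input vs output
    row counts.
    """
    logger.info("pipeline start: edamame %s, python %s, seed %d",
                __version__, platform.python_version(), config.seed)
    records = read_quality_csv(config.quality_csv)
    weather = read_weather_csv(config.weather_csv)

    scored, score_report = score_dataset(records, clamp_policy=config.clamp_policy)
    features = _derive_feature_table(scored, weather, config.gdd_base_C)

    models: dict[str, SurfaceModel] = {}
    windows: dict[str, HarvestWindow] = {}
    stepwise: dict[str, StepwiseResult] = {}
    neural: dict[str, object] = {}

    for cultivar, sub in scored.groupby("cultivar"):
        models[cultivar] = fit_surface(
            sub, selection=config.selection,
            entry_p=config.entry_p, stay_p=config.stay_p,
        )
        try:
            windows[cultivar] = harvest_window(
                models[cultivar], config.window_tolerance,
                planting_doy=float(sub["planting_doy"].median()),
            )
        except ResponseSurfaceError as exc:
            logger.warning("no harvest window for %s: %s", cultivar, exc)

    feat_table = features
    if config.aggregate == "means":
        feat_table = (
            features.groupby(
                ["cultivar", "environment", "planting_doy", "harvest_doy"],
                as_index=False,
            )[[*(f for f in FEATURE_NAMES if f not in ("planting_doy", "harvest_doy")), "ehqi"]]
            .mean()
        )
    for cultivar, sub in feat_table.groupby("cultivar"):
        stepwise[cultivar] = stepwise_select(
            sub["ehqi"], sub[list(FEATURE_NAMES)],
            entry_p=config.entry_p, stay_p=config.stay_p,
            strict=False,  # interval sums are exact identities
        )
        if config.run_nn:
            model = fit_neural(
                sub["ehqi"], sub[list(NEURAL_FEATURES)],
                n_nodes=config.nn_nodes, n_restarts=config.nn_restarts,
                seed=config.seed,
            )
            model.importance = variable_importance(
                model, sub[list(NEURAL_FEATURES)], seed=config.seed
            )
            neural[cultivar] = model

    report = {
        "edamame_version": __version__,
        "seed": config.seed,
        "rows_in": score_report.n_input,
        "rows_scored": score_report.n_scored,
        "rows_dropped": score_report.n_dropped,
        "rows_clamped": score_report.n_clamped,
        "dropped_rows": score_report.dropped_rows,
    }
    assert report["rows_in"] == report["rows_scored"] + report["rows_dropped"]

    result = PipelineResult(
        scored=scored, features=features, models=models, windows=windows,
        stepwise=stepwise, neural=neural, report=report,
    )
    if config.out_dir:
        _write_artifacts(result, config)
    return result


def _write_artifacts(result: PipelineResult, config: PipelineConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.scored.to_csv(out / "scored.csv", index=False)
    result.features.to_csv(out / "features.csv", index=False)
    for cultivar, model in result.models.items():
        write_model_json(model, out / f"surface_{cultivar}.json")
    windows = {c: window_to_dict(w) for c, w in result.windows.items()}
    (out / "windows.json").write_text(json.dumps(windows, indent=2, sort_keys=True))
    stepwise = {
        c: {
            "selected_terms": list(r.selected_terms),
            "coefficients": r.coefficients,
            "aic_path": list(r.aic_path),
            "final_rmse": r.final_rmse,
            "final_adj_r2": r.final_adj_r2,
        }
        for c, r in result.stepwise.items()
    }
    (out / "stepwise.json").write_text(json.dumps(stepwise, indent=2, sort_keys=True))
    if result.neural:
        nn = {
            c: {
                "val_r2": m.val_r2, "val_rmse": m.val_rmse,
                "train_r2": m.train_r2, "train_rmse": m.train_rmse,
                "penalty_strength": m.penalty_strength,
                "importance": m.importance.to_dict(orient="records")
                if m.importance is not None else None,
            }
            for c, m in result.neural.items()
        }
        (out / "neural.json").write_text(json.dumps(nn, indent=2, sort_keys=True))
    (out / "run_log.json").write_text(
        json.dumps(result.report, indent=2, sort_keys=True)
    )
    logger.info("artifacts written to %s", out)
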