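"""Orchestration of the two-sensor vs single-sensor calibration study.

Workflow: obtain a dataset (synthetic or from files), randomly partition
the leaves into a calibration set and an external-prediction set, then
for each sensor (reflectance-only vs two-sensor absorbance) and each
pigment fit a NIPALS PLS model with the component count chosen by
leave-one-out cross-validation, and report the three phases:

* calibration       -- fitted model applied back to the calibration set
* cross_validation  -- leave-one-out predictions at the selected rank
* prediction        -- the untouched external set

The result is a table of per-phase fit metrics in the layout of a
standard multivariate-calibration comparison table, plus the
regression-coefficient (beta) spectrum of every model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import plsr
from .metrics import FitReport, regression_metrics
from .spectra import SpectralDataset
from .synthetic import GeneratorConfig, SyntheticStudy, generate_dataset

logger = logging.getLogger(__name__)

SENSORS = ("reflectance", "absorbance")
PIGMENTS = ("chl_a", "chl_b", "chl_ab", "car")
PIGMENT_LABELS = {
    "chl_a": "Chl a",
    "chl_b": "Chl b",
    "chl_ab": "Chl a+b",
    "car": "Car",
}
PIGMENT_COLUMN = {
    "chl_a": "chl_a_g_m2",
    "chl_b": "chl_b_g_m2",
    "chl_ab": "chl_ab_g_m2",
    "car": "car_g_m2",
}
_PHASE_LABELS = {
    "calibration": "Calibration",
    "cross_validation": "Cross-Validation",
    "prediction": "Prediction",
}


@dataclass
class ExperimentConfig:
    """Full study configuration."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    n_calibration: int = 100
    n_prediction: int = 50
    split_seed: int = 77
    sensors: tuple[str, ...] = SENSORS
    pigments: tuple[str, ...] = PIGMENTS
    max_components: int = 10
    outlier_removal: bool = False

    def __post_init__(self) -> None:
        for s in self.sensors:
            if s not in SENSORS:
                raise ValueError(f"unknown sensor {s!r}")
        for p in self.pigments:
            if p not in PIGMENTS:
                raise ValueError(f"unknown pigment {p!r}")
        if self.n_calibration < self.max_components + 2:
            raise ValueError("calibration set too small for max_components")
        if self.n_prediction < 3:
            raise ValueError("prediction set must hold at least 3 samples")


def split_dataset(
    dataset: SpectralDataset, n_calibration: int, n_prediction: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Random disjoint calibration/prediction partition (index arrays).

    Uniform without replacement; the same seed always yields the same
    partition, with indices in stable (sorted) order.
    """
    n = len(dataset)
    if n_calibration + n_prediction != n:
        raise ValueError(
            f"partition sizes {n_calibration}+{n_prediction} != dataset size {n}"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    cal = np.sort(perm[:n_calibration])
    pred = np.sort(perm[n_calibration:])
    return cal, pred


def build_design_matrix(dataset: SpectralDataset, sensor: str) -> np.ndarray:
    """Per-sample spectra as rows: R(lambda) or derived A(lambda)."""
    if sensor == "reflectance":
        return dataset.reflectance_matrix()
    if sensor == "absorbance":
        return dataset.absorbance_matrix()
    raise ValueError(f"unknown sensor {sensor!r}")


@dataclass
class ModelResult:
    """One fitted sensor x pigment model with its three phase reports."""

    sensor: str
    pigment: str
    n_components: int
    model: plsr.PLSModel
    reports: dict[str, FitReport]
    outliers: plsr.OutlierReport
    n_dropped: int = 0


@dataclass
class ComparisonReport:
    """All models of one study run plus the dataset bookkeeping."""

    results: list[ModelResult]
    calibration_ids: list[str]
    prediction_ids: list[str]
    config: ExperimentConfig

    def get(self, sensor: str, pigment: str) -> ModelResult:
        for res in self.results:
            if res.sensor == sensor and res.pigment == pigment:
                return res
        raise KeyError((sensor, pigment))

    def to_frame(self) -> pd.DataFrame:
        """Long-format metric table, ordered sensor -> phase -> pigment."""
        rows = []
        for sensor in self.config.sensors:
            for phase in ("calibration", "cross_validation", "prediction"):
                for pigment in self.config.pigments:
                    res = self.get(sensor, pigment)
                    rep = res.reports[phase]
                    rows.append({
                        "sensor": sensor,
                        "phase": phase,
                        "pigment": PIGMENT_LABELS[pigment],
                        "r": rep.r,
                        "r2": rep.r2,
                        "slope": rep.slope,
                        "offset": rep.offset,
                        "rmse": rep.rmse,
                        "rpd": rep.rpd,
                        # bias is only reported for the external phase
                        "bias": rep.bias if phase == "prediction" else np.nan,
                        "n_components": res.n_components,
                        "n": rep.n,
                    })
        return pd.DataFrame(rows)


def _fit_one(
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    X_pred: np.ndarray,
    y_pred: np.ndarray,
    sensor: str,
    pigment: str,
    max_components: int,
    outlier_removal: bool,
) -> ModelResult:
    loo_preds, rmse_cv = plsr.loo_cross_validate(X_cal, y_cal, max_components)
    n_comp = plsr.select_components(rmse_cv, n_samples=len(y_cal))
    model = plsr.fit_nipals(X_cal, y_cal, n_comp)
    outliers = plsr.outlier_diagnostics(model, X_cal)

    n_dropped = 0
    if outlier_removal and outliers.n_flagged:
        keep = ~outliers.flags
        n_dropped = int(outliers.flags.sum())
        logger.info("%s/%s: dropping %d flagged calibration samples",
                    sensor, pigment, n_dropped)
        X_cal, y_cal = X_cal[keep], y_cal[keep]
        loo_preds, rmse_cv = plsr.loo_cross_validate(
            X_cal, y_cal, max_components
        )
        n_comp = plsr.select_components(rmse_cv, n_samples=len(y_cal))
        model = plsr.fit_nipals(X_cal, y_cal, n_comp)

    reports = {
        "calibration": regression_metrics(
            y_cal, model.predict(X_cal), "calibration"
        ),
        "cross_validation": regression_metrics(
            y_cal, loo_preds[:, n_comp - 1], "cross_validation"
        ),
        "prediction": regression_metrics(
            y_pred, model.predict(X_pred), "prediction"
        ),
    }
    return ModelResult(
        sensor=sensor, pigment=pigment, n_components=n_comp,
        model=model, reports=reports, outliers=outliers, n_dropped=n_dropped,
    )


def run_comparison(
    config: ExperimentConfig,
    dataset: SpectralDataset,
    pigment_table: pd.DataFrame,
) -> ComparisonReport:
    """Fit every sensor x pigment model and evaluate the three phases."""
    pigment_table = pigment_table.set_index(
        pigment_table["sample_id"].astype(str)
    )
    missing = set(dataset.sample_ids) - set(pigment_table.index)
    if missing:
        raise ValueError(f"pigment table missing samples: {sorted(missing)[:5]}")
    cal_idx, pred_idx = split_dataset(
        dataset, config.n_calibration, config.n_prediction, config.split_seed
    )
    cal_ids = [dataset.sample_ids[i] for i in cal_idx]
    pred_ids = [dataset.sample_ids[i] for i in pred_idx]

    results = []
    for sensor in config.sensors:
        X = build_design_matrix(dataset, sensor)
        for pigment in config.pigments:
            y = pigment_table.loc[dataset.sample_ids,
                                  PIGMENT_COLUMN[pigment]].to_numpy(float)
            if np.allclose(y, y[0]):
                raise ValueError(f"pigment {pigment} has no variance")
            results.append(_fit_one(
                X[cal_idx], y[cal_idx], X[pred_idx], y[pred_idx],
                sensor, pigment, config.max_components,
                config.outlier_removal,
            ))
    return ComparisonReport(
        results=results, calibration_ids=cal_ids, prediction_ids=pred_ids,
        config=config,
    )


def run_synthetic_study(
    config: ExperimentConfig,
) -> tuple[SyntheticStudy, ComparisonReport]:
    """Generate the synthetic population and run the full comparison."""
    study = generate_dataset(config.generator)
    if config.n_calibration + config.n_prediction != config.generator.n_samples:
        raise ValueError("split sizes must sum to the generated sample count")
    report = run_comparison(config, study.dataset, study.pigments)
    return study, report


def render_table(report: ComparisonReport, fmt: str = "markdown") -> str:
    """Render the comparison as csv/json (full precision) or markdown (2 dp)."""
    df = report.to_frame()
    if fmt == "csv":
        return df.to_csv(index=False)
    if fmt == "json":
        return df.to_json(orient="records", indent=1)
    if fmt == "markdown":
        disp = df.copy()
        for col in ("r", "r2", "slope", "offset", "rmse", "rpd"):
            disp[col] = disp[col].map(lambda v: f"{v:.2f}")
        disp["bias"] = df["bias"].map(
            lambda v: "-" if pd.isna(v) else f"{v:.3f}"
        )
        disp["sensor"] = disp["sensor"].str.capitalize()
        disp["phase"] = disp["phase"].map(_PHASE_LABELS)
        disp = disp.drop(columns=["n_components", "n"])
        header = "| " + " | ".join(disp.columns) + " |"
        sep = "|" + "|".join(["---"] * len(disp.columns)) + "|"
        body = ["| " + " | ".join(str(v) for v in row) + " |"
                for row in disp.itertuples(index=False)]
        return "\n".join([header, sep, *body])
    raise ValueError(f"unknown format {fmt!r}")


def beta_table(report: ComparisonReport, grid) -> pd.DataFrame:
    """Long-format beta spectra of every fitted model."""
    frames = []
    for res in report.results:
        df = plsr.beta_spectrum(res.model, grid)
        df.insert(0, "pigment", PIGMENT_LABELS[res.pigment])
        df.insert(0, "sensor", res.sensor)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
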