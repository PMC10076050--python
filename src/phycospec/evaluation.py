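"""Model performance metrics, RPD quality classes, and the model grid.

Metrics follow the chemometric conventions of Vis-NIR calibration work:

* RMSE  = sqrt(mean((y - yhat)^2))
* RPD   = SD(y) / RMSE, with SD the n-1 sample standard deviation of the
  evaluation split's reference values
* MAPE  = mean(|y - yhat|) / mean(y) * 100  — note the denominator is the
  *mean* of the measured values (not each y_i); the conventional per-sample
  variant is available behind a flag
* R^2   = 1 - SS_res / SS_tot (Nash-Sutcliffe form, penalizes bias);
  squared Pearson correlation available for comparison

RPD quality classes: > 3.0 quantitative; 2.0-3.0 qualitative; < 2.0
insufficient. A MAPE below 15% flags high prediction accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import CalibrationModel, fit_pigment_model, split_train_test
from .datatypes import PIGMENTS, SampleSet
from .errors import DegenerateReferenceError, InvalidArgumentError, ShapeError
from .preprocess import PRESET_NAMES

RPD_QUANTITATIVE = 3.0
RPD_QUALITATIVE = 2.0
MAPE_HIGH_ACCURACY = 15.0


def _check_pair(y, yhat) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.size != yhat.size:
        raise ShapeError(f"length mismatch: {y.size} vs {yhat.size}")
    if y.size == 0:
        raise ShapeError("empty vectors")
    return y, yhat


def rmse(y, yhat) -> float:
    """Root mean square error, same units as y (mg/g)."""
    y, yhat = _check_pair(y, yhat)
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def rpd(y, yhat) -> float:
    """Ratio of performance to deviation: SD(y) / RMSE(y, yhat).

    Perfect predictions give ``inf`` (callers flag it); a constant reference
    vector raises :class:`DegenerateReferenceError`.
    """
    y, yhat = _check_pair(y, yhat)
    if y.size < 2:
        raise ShapeError("RPD needs at least 2 samples")
    sd = float(np.std(y, ddof=1))
    if sd == 0:
        raise DegenerateReferenceError("reference values are constant")
    err = rmse(y, yhat)
    if err == 0:
        return float("inf")
    return sd / err


def mape(y, yhat, per_sample_denominator: bool = False) -> float:
    """Mean absolute percent error, normalized by mean(y) (percent).

    Set ``per_sample_denominator`` for the conventional variant that divides
    each residual by its own y_i.
    """
    y, yhat = _check_pair(y, yhat)
    if per_sample_denominator:
        if np.any(y == 0):
            raise DegenerateReferenceError("per-sample MAPE undefined at y_i = 0")
        return float(np.mean(np.abs(y - yhat) / np.abs(y)) * 100.0)
    m = float(np.mean(y))
    if m == 0:
        raise DegenerateReferenceError("mean of reference values is zero")
    return float(np.mean(np.abs(y - yhat)) / abs(m) * 100.0)


def r_squared(y, yhat, method: str = "nash_sutcliffe") -> float:
    """Coefficient of determination.

    ``nash_sutcliffe``: 1 - SS_res/SS_tot (default, penalizes bias);
    ``pearson``: squared Pearson correlation of y and yhat.
    """
    y, yhat = _check_pair(y, yhat)
    if y.size < 2:
        raise ShapeError("R^2 needs at least 2 samples")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise DegenerateReferenceError("reference values are constant")
    if method == "nash_sutcliffe":
        return 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot
    if method == "pearson":
        if np.std(yhat) == 0:
            return 0.0
        return float(np.corrcoef(y, yhat)[0, 1] ** 2)
    raise InvalidArgumentError(f"unknown R^2 method {method!r}")


def classify_rpd(rpd_value: float) -> str:
    """Map an RPD value to its quality class.

    Strictly above 3.0 is ``quantitative``; the 3.0 boundary itself falls in
    ``qualitative`` (2.0 <= RPD <= 3.0); below 2.0 is ``insufficient``.
    """
    if not rpd_value > 0:
        raise InvalidArgumentError("RPD must be positive")
    if rpd_value > RPD_QUANTITATIVE:
        return "quantitative"
    if rpd_value >= RPD_QUALITATIVE:
        return "qualitative"
    return "insufficient"


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------


@dataclass
class EvaluationReport:
    """Train/test metrics of one fitted pigment model."""

    pigment: str
    preset: str
    model_type: str
    r2_train: float
    r2_test: float
    rmse_train: float
    rmse_test: float
    mape_test: float
    rpd_test: float
    hyperparams: dict
    n_train: int
    n_test: int
    rpd_class: str
    accuracy_flag: bool  # MAPE below the 15% high-accuracy bar
    rpd_infinite: bool = False

    def to_dict(self) -> dict:
        d = {
            "pigment": self.pigment,
            "preset": self.preset,
            "model_type": self.model_type,
            "r2_train": self.r2_train,
            "rmse_train": self.rmse_train,
            "r2_test": self.r2_test,
            "rmse_test": self.rmse_test,
            "mape_test": self.mape_test,
            "rpd_test": None if self.rpd_infinite else self.rpd_test,
            "rpd_infinite": self.rpd_infinite,
            "rpd_class": self.rpd_class,
            "accuracy_flag": self.accuracy_flag,
            "n_train": self.n_train,
            "n_test": self.n_test,
        }
        d.update({f"hp_{k}": v for k, v in self.hyperparams.items()})
        return d


def evaluate_model(
    model: CalibrationModel,
    train: SampleSet,
    test: SampleSet,
    pigment: str | None = None,
) -> EvaluationReport:
    """All metrics on both splits; MAPE/RPD/class computed on the test split."""
    pigment = model.pigment if pigment is None else pigment
    y_tr, y_te = train.y(pigment), test.y(pigment)
    p_tr = model.predict(train.spectra)
    p_te = model.predict(test.spectra)

    rpd_te = rpd(y_te, p_te)
    infinite = np.isinf(rpd_te)
    mape_te = mape(y_te, p_te)
    return EvaluationReport(
        pigment=pigment,
        preset=model.preset,
        model_type=model.model_type,
        r2_train=r_squared(y_tr, p_tr),
        r2_test=r_squared(y_te, p_te),
        rmse_train=rmse(y_tr, p_tr),
        rmse_test=rmse(y_te, p_te),
        mape_test=mape_te,
        rpd_test=rpd_te,
        hyperparams=model.hyperparams,
        n_train=train.n,
        n_test=test.n,
        rpd_class=classify_rpd(rpd_te) if not infinite else "quantitative",
        accuracy_flag=mape_te < MAPE_HIGH_ACCURACY,
        rpd_infinite=bool(infinite),
    )


@dataclass
class GridResult:
    """Every preprocessing x model cell plus the per-pigment optimum."""

    reports: list[EvaluationReport]
    optima: dict[str, EvaluationReport]
    models: dict[tuple[str, str, str], CalibrationModel] = field(default_factory=dict)
    optimal_models: dict[str, CalibrationModel] = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([r.to_dict() for r in self.reports])


def _better(a: EvaluationReport, b: EvaluationReport | None) -> bool:
    """Is report ``a`` better than ``b``? Higher test RPD, ties by lower MAPE."""
    if b is None:
        return True
    if a.rpd_test != b.rpd_test:
        return a.rpd_test > b.rpd_test
    return a.mape_test < b.mape_test


def run_model_grid(
    samples: SampleSet,
    presets: tuple[str, ...] = PRESET_NAMES,
    model_types: tuple[str, ...] = ("plsr", "svr"),
    pigments: tuple[str, ...] = PIGMENTS,
    seed: int = 0,
    n_test: int | None = None,
    max_lv: int = 50,
    k_folds: int = 5,
    keep_models: bool = True,
) -> GridResult:
    """Fit and evaluate every pigment x preset x model-type combination.

    One seeded train/test split is reused for every cell so PLSR and SVR see
    identical data. The per-pigment optimum maximizes test RPD (ties broken
    by lower test MAPE).
    """
    if not (presets and model_types and pigments):
        raise InvalidArgumentError("presets, model_types and pigments must be nonempty")
    train, test = split_train_test(samples, n_test=n_test, seed=seed)

    reports: list[EvaluationReport] = []
    models: dict[tuple[str, str, str], CalibrationModel] = {}
    optima: dict[str, EvaluationReport] = {}
    optimal_models: dict[str, CalibrationModel] = {}
    for pigment in pigments:
        best: EvaluationReport | None = None
        for preset in presets:
            for model_type in model_types:
                model = fit_pigment_model(
                    train,
                    pigment,
                    preset=preset,
                    model_type=model_type,
                    max_lv=max_lv,
                    k_folds=k_folds,
                    seed=seed,
                )
                report = evaluate_model(model, train, test)
                reports.append(report)
                if keep_models:
                    models[(pigment, preset, model_type)] = model
                if _better(report, best):
                    best = report
                    if keep_models:
                        optimal_models[pigment] = model
        optima[pigment] = best
    return GridResult(
        reports=reports, optima=optima, models=models, optimal_models=optimal_models
    )


@dataclass
class ValidationReport:
    """External-validation metrics plus per-sample residuals (y - yhat)."""

    pigment: str
    r2: float
    rmse: float
    mape: float
    residuals: np.ndarray
    n: int


def validate_external(
    model: CalibrationModel, field_set: SampleSet, pigment: str | None = None
) -> ValidationReport:
    """Evaluate a fitted model on an external (e.g. field-collected) set."""
    pigment = model.pigment if pigment is None else pigment
    if field_set.n == 0:
        raise InvalidArgumentError("external sample set is empty")
    y = field_set.y(pigment)
    yhat = model.predict(field_set.spectra)
    return ValidationReport(
        pigment=pigment,
        r2=r_squared(y, yhat),
        rmse=rmse(y, yhat),
        mape=mape(y, yhat),
        residuals=y - yhat,
        n=field_set.n,
    )
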