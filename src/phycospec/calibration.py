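"""Per-pigment calibration models: PLSR (NIPALS + LOOCV) and RBF-SVR.

Two model families are fit on preprocessed mean spectra against reference
pigment contents:

* **PLSR** via the NIPALS algorithm — successive latent variables maximize
  the covariance between X-scores and the target, with X deflation after
  each component. The number of latent variables ``n_lv`` (up to 50) is
  chosen by leave-one-out cross-validation at the minimum RMSECV, ties
  broken toward the smaller model. Any train-statistic preprocessing is
  refit inside each fold so the RMSECV estimate is leakage-free.

* **epsilon-SVR** with an RBF kernel ``k(u, v) = exp(-g * ||u - v||^2)``,
  solved by libsvm (scikit-learn) on internally z-scored features and
  target. ``C`` and ``g`` are selected on a powers-of-two grid by seeded
  k-fold cross-validation RMSE, ties broken toward smaller C then smaller g.

The SVR kernel is always evaluated by this module (precomputed-kernel mode),
so a fitted model is a self-contained set of support vectors, dual
coefficients and scaling state, and grid search can share one code path with
single fits.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.model_selection import KFold
from sklearn.svm import SVR as _SkSVR

from .datatypes import PIGMENTS, SampleSet, WavelengthGrid
from .errors import (
    ConvergenceError,
    DegenerateTargetError,
    InvalidArgumentError,
    ShapeError,
)
from .preprocess import PreprocessSpec, make_preset

DEFAULT_MAX_LV = 50
#: powers-of-two search grids covering the useful RBF-SVR range
DEFAULT_C_GRID = 2.0 ** np.arange(-5, 22)
DEFAULT_G_GRID = 2.0 ** np.arange(-18, 6)
DEFAULT_EPSILON = 0.1  # on the unit-variance-scaled target

_WEIGHT_EPS = 1e-13


# ---------------------------------------------------------------------------
# train/test split
# ---------------------------------------------------------------------------


def split_train_test(
    samples: SampleSet, n_test: int | None = None, seed: int = 0
) -> tuple[SampleSet, SampleSet]:
    """Seeded random partition into train and test sample sets.

    The default test size is ``round(n * 17/96)`` so a 96-sample set yields
    the canonical 79/17 split. Source indices are recorded in both outputs.
    """
    n = samples.n
    if n_test is None:
        n_test = max(1, round(n * 17 / 96))
    if not 1 <= n_test < n:
        raise InvalidArgumentError(f"n_test must be in [1, {n - 1}], got {n_test}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    test_idx = np.sort(perm[:n_test])
    train_idx = np.sort(perm[n_test:])
    return samples.subset(train_idx, "train"), samples.subset(test_idx, "test")


# ---------------------------------------------------------------------------
# PLSR (NIPALS)
# ---------------------------------------------------------------------------


@dataclass
class PLSRModel:
    """Fitted PLS1 regression model in NIPALS factor form.

    ``coef``/``intercept`` give the collapsed affine predictor; the stored
    weights/loadings reproduce the same predictions factor by factor.
    """

    n_lv: int
    x_weights: np.ndarray  # B x A
    x_loadings: np.ndarray  # B x A
    y_loadings: np.ndarray  # A
    x_center: np.ndarray
    y_center: float
    coef: np.ndarray  # length B
    rmsecv_curve: np.ndarray | None = None
    preprocess: PreprocessSpec | None = None

    @property
    def intercept(self) -> float:
        return float(self.y_center - self.x_center @ self.coef)


def _nipals_path(
    X: np.ndarray, y: np.ndarray, max_lv: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, float]:
    """Run NIPALS PLS1 to ``max_lv`` components.

    Returns (W, P, q, x_center, y_center); columns may stop early if the
    residual is exhausted (W then has fewer than max_lv columns).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    x_center = X.mean(axis=0)
    y_center = float(y.mean())
    Xr = X - x_center
    yr = y - y_center
    scale = max(np.linalg.norm(Xr) * max(np.linalg.norm(yr), 1.0), 1.0)

    W, P, q = [], [], []
    for _ in range(max_lv):
        w = Xr.T @ yr
        nw = np.linalg.norm(w)
        if nw <= _WEIGHT_EPS * scale:
            break
        w = w / nw
        t = Xr @ w
        tt = float(t @ t)
        if tt <= (_WEIGHT_EPS * scale) ** 2:
            break
        p = Xr.T @ t / tt
        qa = float(yr @ t / tt)
        Xr = Xr - np.outer(t, p)
        yr = yr - qa * t
        W.append(w)
        P.append(p)
        q.append(qa)
    if not W:
        # zero-signal target: a 0-component model predicting the mean
        b = X.shape[1]
        return np.zeros((b, 0)), np.zeros((b, 0)), np.zeros(0), x_center, y_center
    return np.column_stack(W), np.column_stack(P), np.array(q), x_center, y_center


def _coef_from_path(W: np.ndarray, P: np.ndarray, q: np.ndarray, k: int) -> np.ndarray:
    """Regression vector of the k-component model: W_k (P_k^T W_k)^-1 q_k."""
    k = min(k, W.shape[1])
    if k == 0:
        return np.zeros(W.shape[0])
    return W[:, :k] @ np.linalg.solve(P[:, :k].T @ W[:, :k], q[:k])


def plsr_fit(X: np.ndarray, y: np.ndarray, n_lv: int) -> PLSRModel:
    """Fit a mean-centered NIPALS PLS1 model with ``n_lv`` latent variables."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ShapeError("X must be n x B with y of length n")
    n, b = X.shape
    if n < 2:
        raise InvalidArgumentError("need at least 2 training samples")
    if not 1 <= n_lv <= min(n - 1, b):
        raise InvalidArgumentError(
            f"n_lv must be in [1, {min(n - 1, b)}], got {n_lv}"
        )
    if np.ptp(y) == 0:
        raise DegenerateTargetError("target y has zero variance")
    W, P, q, x_center, y_center = _nipals_path(X, y, n_lv)
    return PLSRModel(
        n_lv=int(min(n_lv, W.shape[1])) or 1,
        x_weights=W,
        x_loadings=P,
        y_loadings=q,
        x_center=x_center,
        y_center=y_center,
        coef=_coef_from_path(W, P, q, n_lv),
    )


def plsr_predict(model: PLSRModel, X: np.ndarray) -> np.ndarray:
    """Predict via the collapsed regression vector."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.coef.shape[0]:
        raise ShapeError(
            f"X has {X.shape[1]} bands, model expects {model.coef.shape[0]}"
        )
    return (X - model.x_center) @ model.coef + model.y_center


def plsr_predict_factor_form(model: PLSRModel, X: np.ndarray) -> np.ndarray:
    """Predict by sequentially extracting scores (cross-check path)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Xr = X - model.x_center
    yhat = np.full(X.shape[0], model.y_center)
    k = min(model.n_lv, model.x_weights.shape[1])
    for a in range(k):
        t = Xr @ model.x_weights[:, a]
        Xr = Xr - np.outer(t, model.x_loadings[:, a])
        yhat = yhat + model.y_loadings[a] * t
    return yhat


def select_n_lv_loocv(
    X: np.ndarray,
    y: np.ndarray,
    max_lv: int = DEFAULT_MAX_LV,
    preprocess: PreprocessSpec | None = None,
) -> tuple[int, np.ndarray]:
    """Choose ``n_lv`` by leave-one-out cross-validation RMSECV.

    Each fold refits any train-statistic preprocessing (``preprocess`` is fit
    on the fold's n-1 samples before the held-out spectrum is transformed),
    then one NIPALS run per fold supplies predictions for every candidate
    component count. Returns ``(n_lv_best, rmsecv_curve)`` with the argmin
    tie broken toward the smaller model.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if n < 3:
        raise InvalidArgumentError("LOOCV needs at least 3 samples")
    cap = min(max_lv, n - 2, X.shape[1])
    preds = np.empty((n, cap))
    for i in range(n):
        tr = np.concatenate([np.arange(i), np.arange(i + 1, n)])
        Xtr, ytr = X[tr], y[tr]
        Xte = X[i : i + 1]
        if preprocess is not None:
            pipe = preprocess.copy()
            Xtr = pipe.fit_transform(Xtr)
            Xte = pipe.transform(Xte)
        W, P, q, x_center, y_center = _nipals_path(Xtr, ytr, cap)
        x0 = Xte[0] - x_center
        for k in range(1, cap + 1):
            coef = _coef_from_path(W, P, q, k)
            preds[i, k - 1] = x0 @ coef + y_center
    rmsecv = np.sqrt(np.mean((preds - y[:, None]) ** 2, axis=0))
    best = int(np.argmin(rmsecv)) + 1  # argmin returns the first (smallest) tie
    return best, rmsecv


# ---------------------------------------------------------------------------
# SVR (RBF kernel, libsvm behind a self-contained model)
# ---------------------------------------------------------------------------


@dataclass
class SVRModel:
    """Fitted epsilon-SVR with RBF kernel and stored scaling state.

    ``support_vectors`` live in the internally scaled feature space;
    ``dual_coef`` are the signed multipliers alpha_i - alpha_i^*;
    ``intercept`` is in scaled-target units (``bias`` converts back).
    """

    support_vectors: np.ndarray
    dual_coef: np.ndarray
    intercept: float
    c: float
    g: float
    epsilon: float
    x_center: np.ndarray
    x_scale: np.ndarray
    y_center: float
    y_scale: float
    n_iter: int = 0
    preprocess: PreprocessSpec | None = None

    @property
    def bias(self) -> float:
        """Model bias in original target units (mg/g)."""
        return self.y_center + self.y_scale * self.intercept

    @property
    def n_support(self) -> int:
        return int(self.dual_coef.size)


def _scale_fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # population sd (ddof=0): invariant under sample duplication
    center = X.mean(axis=0)
    scale = X.std(axis=0)
    scale = np.where(scale == 0, 1.0, scale)
    return center, scale


def _rbf(g: float, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.exp(-g * cdist(a, b, "sqeuclidean"))


def svr_fit(
    X: np.ndarray,
    y: np.ndarray,
    c: float,
    g: float,
    epsilon: float = DEFAULT_EPSILON,
    tol: float = 1e-6,
    max_iter: int = 1_000_000,
    strict: bool = True,
) -> SVRModel:
    """Solve the epsilon-insensitive dual on z-scored features and target.

    ``epsilon`` is the tube half-width on the unit-variance-scaled target.
    Raises :class:`ConvergenceError` if the iteration cap is reached and
    ``strict`` is set.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ShapeError("X row count does not match y")
    if X.shape[0] < 2:
        raise InvalidArgumentError("need at least 2 training samples")
    if c <= 0 or g <= 0 or epsilon < 0:
        raise InvalidArgumentError("need c > 0, g > 0, epsilon >= 0")

    x_center, x_scale = _scale_fit(X)
    Xs = (X - x_center) / x_scale
    y_center = float(y.mean())
    y_scale = float(y.std())
    if y_scale == 0:
        y_scale = 1.0
    ys = (y - y_center) / y_scale

    K = _rbf(g, Xs, Xs)
    svr = _SkSVR(kernel="precomputed", C=c, epsilon=epsilon, tol=tol, max_iter=max_iter)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        svr.fit(K, ys)
    n_iter = int(np.atleast_1d(svr.n_iter_)[0])
    if max_iter > 0 and n_iter >= max_iter and strict:
        raise ConvergenceError(
            f"SVR did not converge within {max_iter} iterations "
            f"(C={c}, g={g}, epsilon={epsilon}, tol={tol})"
        )
    return SVRModel(
        support_vectors=Xs[svr.support_],
        dual_coef=svr.dual_coef_.ravel().copy(),
        intercept=float(svr.intercept_[0]),
        c=float(c),
        g=float(g),
        epsilon=float(epsilon),
        x_center=x_center,
        x_scale=x_scale,
        y_center=y_center,
        y_scale=y_scale,
        n_iter=n_iter,
    )


def svr_predict(model: SVRModel, X: np.ndarray) -> np.ndarray:
    """yhat = sum_i alpha_i k(x, sv_i) + b, mapped back to mg/g."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.x_center.shape[0]:
        raise ShapeError(
            f"X has {X.shape[1]} bands, model expects {model.x_center.shape[0]}"
        )
    Xs = (X - model.x_center) / model.x_scale
    if model.n_support == 0:
        ys = np.full(X.shape[0], model.intercept)
    else:
        ys = _rbf(model.g, Xs, model.support_vectors) @ model.dual_coef + model.intercept
    return model.y_center + model.y_scale * ys


def grid_search_svr(
    X: np.ndarray,
    y: np.ndarray,
    c_grid: np.ndarray | None = None,
    g_grid: np.ndarray | None = None,
    k_folds: int = 5,
    seed: int = 0,
    epsilon: float = DEFAULT_EPSILON,
    preprocess: PreprocessSpec | None = None,
    tol: float = 1e-3,
    max_iter: int = 100_000,
):
    """Seeded k-fold CV RMSE over the (C, g) grid; smallest-RMSE pair wins.

    Ties break toward smaller C, then smaller g. Any train-statistic
    preprocessing is refit on each fold's training part. Returns
    ``(c_best, g_best, cv_table)`` where ``cv_table`` is a tidy DataFrame
    with one pooled-RMSE row per pair.

    Implementation note: per fold the scaled pairwise distances are computed
    once and reused across the grid; this is arithmetically identical to
    refitting :func:`svr_fit` per pair (same scaling, same kernel formula).
    """
    import pandas as pd

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    c_grid = DEFAULT_C_GRID if c_grid is None else np.asarray(c_grid, dtype=float)
    g_grid = DEFAULT_G_GRID if g_grid is None else np.asarray(g_grid, dtype=float)
    if c_grid.size == 0 or g_grid.size == 0:
        raise InvalidArgumentError("parameter grids must be nonempty")
    if not 2 <= k_folds <= n:
        raise InvalidArgumentError(f"k_folds must be in [2, {n}], got {k_folds}")

    preds = np.empty((c_grid.size, g_grid.size, n))
    kf = KFold(n_splits=k_folds, shuffle=True, random_state=seed)
    for tr, te in kf.split(X):
        Xtr, Xte = X[tr], X[te]
        if preprocess is not None:
            pipe = preprocess.copy()
            Xtr = pipe.fit_transform(Xtr)
            Xte = pipe.transform(Xte)
        x_center, x_scale = _scale_fit(Xtr)
        Xs_tr = (Xtr - x_center) / x_scale
        Xs_te = (Xte - x_center) / x_scale
        y_center = float(y[tr].mean())
        y_scale = float(y[tr].std())
        if y_scale == 0:
            y_scale = 1.0
        ys = (y[tr] - y_center) / y_scale
        d2_tr = cdist(Xs_tr, Xs_tr, "sqeuclidean")
        d2_te = cdist(Xs_te, Xs_tr, "sqeuclidean")
        for jg, g in enumerate(g_grid):
            K_tr = np.exp(-g * d2_tr)
            K_te = np.exp(-g * d2_te)
            for ic, c in enumerate(c_grid):
                svr = _SkSVR(
                    kernel="precomputed",
                    C=c,
                    epsilon=epsilon,
                    tol=tol,
                    max_iter=max_iter,
                )
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    svr.fit(K_tr, ys)
                if svr.support_.size == 0:
                    ys_hat = np.full(te.size, float(svr.intercept_[0]))
                else:
                    ys_hat = (
                        K_te[:, svr.support_] @ svr.dual_coef_.ravel()
                        + svr.intercept_[0]
                    )
                preds[ic, jg, te] = y_center + y_scale * ys_hat

    rmse_cv = np.sqrt(np.mean((preds - y[None, None, :]) ** 2, axis=2))
    cc, gg = np.meshgrid(c_grid, g_grid, indexing="ij")
    flat_rmse, flat_c, flat_g = rmse_cv.ravel(), cc.ravel(), gg.ravel()
    # primary key RMSE, then smaller C, then smaller g
    order = np.lexsort((flat_g, flat_c, flat_rmse))
    best = order[0]
    cv_table = pd.DataFrame({"c": flat_c, "g": flat_g, "rmse_cv": flat_rmse})
    return float(flat_c[best]), float(flat_g[best]), cv_table


# ---------------------------------------------------------------------------
# end-to-end per-pigment calibration
# ---------------------------------------------------------------------------


@dataclass
class CalibrationModel:
    """Self-contained predictor: fitted preprocessing + fitted regressor.

    ``predict`` accepts raw reflectance spectra on the training grid and
    returns pigment content in mg/g.
    """

    pigment: str
    preset: str
    model_type: str
    pipeline: PreprocessSpec
    model: PLSRModel | SVRModel
    grid: WavelengthGrid
    selection: dict = field(default_factory=dict)

    @property
    def hyperparams(self) -> dict:
        if self.model_type == "plsr":
            return {"n_lv": self.model.n_lv}
        return {"c": self.model.c, "g": self.model.g, "epsilon": self.model.epsilon}

    def predict(self, spectra: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(spectra, dtype=float))
        if X.shape[1] != self.grid.n_bands:
            raise ShapeError(
                f"spectra have {X.shape[1]} bands, model trained on "
                f"{self.grid.n_bands}"
            )
        Xt = self.pipeline.transform(X)
        if self.model_type == "plsr":
            return plsr_predict(self.model, Xt)
        return svr_predict(self.model, Xt)

    # -- text serialization -------------------------------------------------

    def to_json(self) -> str:
        if self.model_type == "plsr":
            m = self.model
            payload = {
                "n_lv": m.n_lv,
                "x_weights": m.x_weights.tolist(),
                "x_loadings": m.x_loadings.tolist(),
                "y_loadings": m.y_loadings.tolist(),
                "x_center": m.x_center.tolist(),
                "y_center": m.y_center,
                "coef": m.coef.tolist(),
                "rmsecv_curve": None
                if m.rmsecv_curve is None
                else m.rmsecv_curve.tolist(),
            }
        else:
            m = self.model
            payload = {
                "support_vectors": m.support_vectors.tolist(),
                "dual_coef": m.dual_coef.tolist(),
                "intercept": m.intercept,
                "c": m.c,
                "g": m.g,
                "epsilon": m.epsilon,
                "x_center": m.x_center.tolist(),
                "x_scale": m.x_scale.tolist(),
                "y_center": m.y_center,
                "y_scale": m.y_scale,
                "n_iter": m.n_iter,
            }
        return json.dumps(
            {
                "format": "phycospec-calibration-model",
                "version": 1,
                "pigment": self.pigment,
                "preset": self.preset,
                "model_type": self.model_type,
                "grid_centers": self.grid.centers.tolist(),
                "pipeline": self.pipeline.to_dict(),
                "model": payload,
                "selection": self.selection,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "CalibrationModel":
        d = json.loads(text)
        if d.get("format") != "phycospec-calibration-model":
            raise InvalidArgumentError("not a phycospec calibration model archive")
        p = d["model"]
        if d["model_type"] == "plsr":
            model = PLSRModel(
                n_lv=int(p["n_lv"]),
                x_weights=np.asarray(p["x_weights"]),
                x_loadings=np.asarray(p["x_loadings"]),
                y_loadings=np.asarray(p["y_loadings"]),
                x_center=np.asarray(p["x_center"]),
                y_center=float(p["y_center"]),
                coef=np.asarray(p["coef"]),
                rmsecv_curve=None
                if p["rmsecv_curve"] is None
                else np.asarray(p["rmsecv_curve"]),
            )
        else:
            model = SVRModel(
                support_vectors=np.asarray(p["support_vectors"]),
                dual_coef=np.asarray(p["dual_coef"]),
                intercept=float(p["intercept"]),
                c=float(p["c"]),
                g=float(p["g"]),
                epsilon=float(p["epsilon"]),
                x_center=np.asarray(p["x_center"]),
                x_scale=np.asarray(p["x_scale"]),
                y_center=float(p["y_center"]),
                y_scale=float(p["y_scale"]),
                n_iter=int(p["n_iter"]),
            )
        return cls(
            pigment=d["pigment"],
            preset=d["preset"],
            model_type=d["model_type"],
            pipeline=PreprocessSpec.from_dict(d["pipeline"]),
            model=model,
            grid=WavelengthGrid(np.asarray(d["grid_centers"])),
            selection=d.get("selection", {}),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "CalibrationModel":
        with open(path) as fh:
            return cls.from_json(fh.read())


def fit_pigment_model(
    train: SampleSet,
    pigment: str,
    preset: str = "sg_standardize",
    model_type: str = "plsr",
    max_lv: int = DEFAULT_MAX_LV,
    c_grid: np.ndarray | None = None,
    g_grid: np.ndarray | None = None,
    k_folds: int = 5,
    seed: int = 0,
    epsilon: float = DEFAULT_EPSILON,
) -> CalibrationModel:
    """Fit one pigment's calibration: preset preprocessing + model selection.

    PLSR selects ``n_lv`` by LOOCV (preprocessing refit per fold); SVR
    selects ``(C, g)`` by seeded k-fold grid search. The returned model
    carries its fitted pipeline and predicts from raw spectra.
    """
    if pigment not in PIGMENTS:
        raise InvalidArgumentError(f"unknown pigment {pigment!r}")
    if model_type not in ("plsr", "svr"):
        raise InvalidArgumentError(f"model_type must be plsr or svr, got {model_type!r}")

    spacing = train.grid.spacing
    spec = make_preset(preset, spacing=spacing)
    X_raw = train.spectra
    y = train.y(pigment)

    if model_type == "plsr":
        n_best, curve = select_n_lv_loocv(X_raw, y, max_lv=max_lv, preprocess=spec)
        pipe = make_preset(preset, spacing=spacing)
        Xt = pipe.fit_transform(X_raw)
        model = plsr_fit(Xt, y, n_best)
        model.rmsecv_curve = curve
        selection = {"method": "loocv", "max_lv": max_lv, "n_lv": n_best}
    else:
        c_best, g_best, cv_table = grid_search_svr(
            X_raw,
            y,
            c_grid=c_grid,
            g_grid=g_grid,
            k_folds=k_folds,
            seed=seed,
            epsilon=epsilon,
            preprocess=spec,
        )
        pipe = make_preset(preset, spacing=spacing)
        Xt = pipe.fit_transform(X_raw)
        # final fit at the selected pair; working tolerance matches selection
        model = svr_fit(
            Xt, y, c_best, g_best, epsilon=epsilon, tol=1e-3, strict=False
        )
        selection = {
            "method": f"{k_folds}-fold-cv",
            "c": c_best,
            "g": g_best,
            "cv_rmse_min": float(cv_table["rmse_cv"].min()),
        }

    return CalibrationModel(
        pigment=pigment,
        preset=preset,
        model_type=model_type,
        pipeline=pipe,
        model=model,
        grid=train.grid,
        selection=selection,
    )
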