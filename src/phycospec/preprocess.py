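"""Spectral preprocessing: Savitzky-Golay, standardization, SNV, MSC.

Five preset combinations are applied before calibration modeling:

========  =====================================================
preset    steps
========  =====================================================
sg_standardize  S-G smoothing (window 5, order 2) + per-band z-scoring
sg_snv          S-G smoothing + standard normal variate
sg_d1           S-G first derivative (window 5, order 2)
sg_d2           S-G second derivative (window 5, order 2)
msc             multiplicative scatter correction
========  =====================================================

Steps with learned statistics (standardize, MSC) are fit on the training
split only and applied unchanged everywhere else; stateless steps
(S-G, SNV) act identically on any matrix. Sample standard deviations use
the n-1 denominator throughout.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .errors import (
    DegenerateBandError,
    DegenerateFitError,
    DegenerateSpectrumError,
    InvalidArgumentError,
    ShapeError,
)

PRESET_NAMES = ("sg_standardize", "sg_snv", "sg_d1", "sg_d2", "msc")


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------


def savitzky_golay(
    spectra: np.ndarray,
    window: int = 5,
    polyorder: int = 2,
    deriv_order: int = 0,
    spacing: float = 1.0,
) -> np.ndarray:
    """Savitzky-Golay smoothing / differentiation along the band axis.

    Each output value is the ``deriv_order``-th derivative at the window
    center of the least-squares polynomial of degree ``polyorder`` fit to the
    window; derivatives are scaled per nm via ``spacing``. Edge bands are
    handled by polynomial extrapolation of the terminal windows, so the band
    count is preserved.
    """
    if window % 2 == 0 or window <= polyorder:
        raise InvalidArgumentError(
            f"window must be odd and > polyorder (got window={window}, "
            f"polyorder={polyorder})"
        )
    if not 0 <= deriv_order <= polyorder:
        raise InvalidArgumentError("need 0 <= deriv_order <= polyorder")
    spectra = np.asarray(spectra, dtype=float)
    if spectra.shape[-1] < window:
        raise InvalidArgumentError(
            f"need at least window={window} bands, got {spectra.shape[-1]}"
        )
    return savgol_filter(
        spectra,
        window_length=window,
        polyorder=polyorder,
        deriv=deriv_order,
        delta=spacing,
        axis=-1,
        mode="interp",
    )


def standardize_fit(train: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-band mean and sample standard deviation of the training matrix."""
    train = np.asarray(train, dtype=float)
    if train.ndim != 2 or train.shape[0] < 2:
        raise InvalidArgumentError("standardize_fit needs an n x B matrix, n >= 2")
    mean = train.mean(axis=0)
    sd = train.std(axis=0, ddof=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise DegenerateBandError(dead.tolist())
    return mean, sd


def standardize_apply(
    stats: tuple[np.ndarray, np.ndarray], spectra: np.ndarray
) -> np.ndarray:
    """(x - mean) / sd bandwise using training statistics."""
    mean, sd = stats
    spectra = np.asarray(spectra, dtype=float)
    if spectra.shape[-1] != mean.shape[0]:
        raise ShapeError(
            f"band count {spectra.shape[-1]} does not match fitted stats "
            f"({mean.shape[0]})"
        )
    return (spectra - mean) / sd


def snv(spectra: np.ndarray) -> np.ndarray:
    """Standard normal variate: each row centered and scaled to unit sd.

    Per-row, stateless; removes per-spectrum multiplicative and additive
    scatter (a*x + b maps to the same output as x for a > 0).
    """
    spectra = np.atleast_2d(np.asarray(spectra, dtype=float))
    mean = spectra.mean(axis=1, keepdims=True)
    sd = spectra.std(axis=1, ddof=1, keepdims=True)
    dead = np.flatnonzero(sd[:, 0] == 0)
    if dead.size:
        raise DegenerateSpectrumError(dead.tolist())
    return (spectra - mean) / sd


def msc_fit(train: np.ndarray) -> np.ndarray:
    """MSC reference spectrum: the bandwise mean of the training spectra."""
    train = np.asarray(train, dtype=float)
    if train.ndim != 2 or train.shape[0] < 2:
        raise InvalidArgumentError("msc_fit needs an n x B matrix, n >= 2")
    return train.mean(axis=0)


def msc_apply(reference: np.ndarray, spectra: np.ndarray) -> np.ndarray:
    """Regress each row on the reference (x ~ a + b*ref); return (x - a)/b."""
    reference = np.asarray(reference, dtype=float)
    spectra = np.atleast_2d(np.asarray(spectra, dtype=float))
    if spectra.shape[-1] != reference.shape[0]:
        raise ShapeError("band count does not match MSC reference")
    ref_c = reference - reference.mean()
    denom = float(ref_c @ ref_c)
    if denom == 0:
        raise DegenerateFitError([], "MSC reference spectrum is constant")
    b = (spectra - spectra.mean(axis=1, keepdims=True)) @ ref_c / denom
    a = spectra.mean(axis=1) - b * reference.mean()
    bad = np.flatnonzero(np.abs(b) < 1e-8)
    if bad.size:
        raise DegenerateFitError(bad.tolist())
    return (spectra - a[:, None]) / b[:, None]


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


@dataclass
class _Step:
    """One pipeline step. ``state`` holds fitted statistics (or None)."""

    kind: str  # savitzky_golay | standardize | snv | msc
    params: dict = field(default_factory=dict)
    state: object = None

    def to_dict(self) -> dict:
        d = {"kind": self.kind, "params": dict(self.params)}
        if self.state is not None:
            if self.kind == "standardize":
                mean, sd = self.state
                d["state"] = {"mean": mean.tolist(), "sd": sd.tolist()}
            elif self.kind == "msc":
                d["state"] = {"reference": np.asarray(self.state).tolist()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "_Step":
        state = None
        raw = d.get("state")
        if raw is not None:
            if d["kind"] == "standardize":
                state = (np.asarray(raw["mean"]), np.asarray(raw["sd"]))
            elif d["kind"] == "msc":
                state = np.asarray(raw["reference"])
        return cls(kind=d["kind"], params=dict(d.get("params", {})), state=state)


_STATEFUL = {"standardize", "msc"}
_VALID_KINDS = {"savitzky_golay", "standardize", "snv", "msc"}


@dataclass
class PreprocessSpec:
    """An ordered list of preprocessing steps with optional fitted state.

    Use :func:`make_preset` for the named combinations. ``fit_transform``
    learns the train-only statistics and returns the transformed training
    matrix; ``transform`` then applies the frozen pipeline to any matrix
    without mutating stored state.
    """

    name: str
    steps: list[_Step]
    spacing: float = 1.0

    def __post_init__(self):
        for step in self.steps:
            if step.kind not in _VALID_KINDS:
                raise InvalidArgumentError(f"unknown step kind {step.kind!r}")
            if step.kind == "savitzky_golay":
                w = step.params.get("window", 5)
                p = step.params.get("polyorder", 2)
                d = step.params.get("deriv_order", 0)
                if w % 2 == 0 or w <= p or d > p:
                    raise InvalidArgumentError(
                        f"invalid S-G parameters window={w} polyorder={p} deriv={d}"
                    )

    @property
    def fitted(self) -> bool:
        return all(s.state is not None for s in self.steps if s.kind in _STATEFUL)

    def _apply_step(self, step: _Step, x: np.ndarray) -> np.ndarray:
        if step.kind == "savitzky_golay":
            return savitzky_golay(x, spacing=self.spacing, **step.params)
        if step.kind == "snv":
            return snv(x)
        if step.kind == "standardize":
            return standardize_apply(step.state, x)
        return msc_apply(step.state, x)

    def fit_transform(self, train: np.ndarray) -> np.ndarray:
        x = np.asarray(train, dtype=float)
        for i, step in enumerate(self.steps):
            try:
                if step.kind == "standardize":
                    step.state = standardize_fit(x)
                elif step.kind == "msc":
                    step.state = msc_fit(x)
                x = self._apply_step(step, x)
            except Exception as exc:
                exc.add_note(f"raised by pipeline step {i} ({step.kind})")
                raise
        return x

    def transform(self, spectra: np.ndarray) -> np.ndarray:
        for step in self.steps:
            if step.kind in _STATEFUL and step.state is None:
                raise InvalidArgumentError(
                    f"pipeline {self.name!r} not fitted; call fit_transform first"
                )
        x = np.atleast_2d(np.asarray(spectra, dtype=float))
        for i, step in enumerate(self.steps):
            try:
                x = self._apply_step(step, x)
            except Exception as exc:
                exc.add_note(f"raised by pipeline step {i} ({step.kind})")
                raise
        return x

    def copy(self) -> "PreprocessSpec":
        return copy.deepcopy(self)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "spacing": self.spacing,
            "steps": [s.to_dict() for s in self.steps],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessSpec":
        return cls(
            name=d["name"],
            spacing=float(d.get("spacing", 1.0)),
            steps=[_Step.from_dict(s) for s in d["steps"]],
        )


def _sg(deriv: int = 0) -> _Step:
    return _Step("savitzky_golay", {"window": 5, "polyorder": 2, "deriv_order": deriv})


def make_preset(name: str, spacing: float = 1.0) -> PreprocessSpec:
    """Fresh (unfitted) pipeline for one of the five named combinations."""
    if name == "sg_standardize":
        steps = [_sg(0), _Step("standardize")]
    elif name == "sg_snv":
        steps = [_sg(0), _Step("snv")]
    elif name == "sg_d1":
        steps = [_sg(1)]
    elif name == "sg_d2":
        steps = [_sg(2)]
    elif name == "msc":
        steps = [_Step("msc")]
    else:
        raise InvalidArgumentError(
            f"unknown preset {name!r}; choose from {PRESET_NAMES}"
        )
    return PreprocessSpec(name=name, steps=steps, spacing=spacing)


def apply_pipeline(
    spec: PreprocessSpec,
    train: np.ndarray,
    others: list[np.ndarray] | None = None,
) -> tuple[np.ndarray, list[np.ndarray], PreprocessSpec]:
    """Fit a pipeline on the training matrix and apply it everywhere.

    Returns ``(train_transformed, others_transformed, fitted_spec)``; the
    input ``spec`` is not mutated.
    """
    fitted = spec.copy()
    train_t = fitted.fit_transform(train)
    others_t = [fitted.transform(x) for x in (others or [])]
    return train_t, others_t, fitted
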