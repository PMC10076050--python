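"""Pixel-level pigment prediction maps and their rendering.

A fitted calibration model is applied to every masked pixel of a calibrated
cube: each pixel's spectrum passes through the model's stored preprocessing
(stateless steps act per pixel; learned statistics are reused from training)
and the predictor. Raw predictions are kept as-is for statistics; negative
values are clipped to zero only in the display copy, mirroring the
nonnegative blue-to-red color scale of pigment distribution figures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from matplotlib import colormaps
from matplotlib import image as mpimage

from .calibration import CalibrationModel
from .datatypes import ROIMask, SpectralCube
from .errors import EmptyROIError, IncompatibleGridError, InvalidArgumentError, ShapeError


@dataclass
class PredictionMap:
    """H x W concentration map (mg/g), defined only on masked pixels."""

    values: np.ndarray  # NaN outside the mask, raw (unclipped) inside
    mask: ROIMask
    pigment: str
    model_id: str
    clip_count: int

    def __post_init__(self):
        if self.values.shape != self.mask.shape:
            raise ShapeError("map and mask shapes differ")

    def masked_values(self) -> np.ndarray:
        return self.values[self.mask.mask]

    def display_values(self) -> np.ndarray:
        """Copy with negatives clipped to 0 (display only)."""
        out = self.values.copy()
        m = self.mask.mask
        out[m] = np.maximum(out[m], 0.0)
        return out


def predict_map(
    cube: SpectralCube, mask: ROIMask, model: CalibrationModel
) -> PredictionMap:
    """Predict pigment content for every masked pixel of a calibrated cube."""
    if not cube.calibrated:
        raise InvalidArgumentError("predict_map requires a calibrated cube")
    if not np.array_equal(cube.grid.centers, model.grid.centers):
        raise IncompatibleGridError(
            "cube wavelength grid does not match the model's training grid"
        )
    if mask.shape != cube.values.shape[:2]:
        raise ShapeError("mask shape does not match cube")
    if mask.n_pixels == 0:
        raise EmptyROIError("prediction mask is empty")

    spectra = np.asarray(cube.values, dtype=float)[mask.mask]
    preds = model.predict(spectra)
    values = np.full(mask.shape, np.nan)
    values[mask.mask] = preds
    return PredictionMap(
        values=values,
        mask=mask,
        pigment=model.pigment,
        model_id=f"{model.pigment}:{model.preset}:{model.model_type}",
        clip_count=int((preds < 0).sum()),
    )


@dataclass
class MapSummary:
    """Summary statistics of a prediction map over its mask."""

    mean: float
    sd: float
    min: float
    max: float
    profile_positions: np.ndarray  # bin centers along the principal axis (px)
    profile: np.ndarray  # mean concentration per occupied bin


def _principal_axis(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and unit major-axis vector of the mask (second moments).

    Sign is fixed so the largest-magnitude component is positive, making the
    axial direction deterministic.
    """
    coords = np.argwhere(mask).astype(float)
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    cov = centered.T @ centered / max(len(coords) - 1, 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    axis = eigvecs[:, np.argmax(eigvals)]
    if axis[np.argmax(np.abs(axis))] < 0:
        axis = -axis
    return centroid, axis


def map_statistics(pmap: PredictionMap, n_bins: int = 50) -> MapSummary:
    """Masked summary statistics plus the axial concentration profile.

    The profile bins masked pixels by their projection onto the mask's
    principal axis and averages the (unclipped) predictions per bin; empty
    bins are dropped.
    """
    vals = pmap.masked_values()
    if vals.size == 0:
        raise EmptyROIError("map has no masked pixels")
    centroid, axis = _principal_axis(pmap.mask.mask)
    coords = np.argwhere(pmap.mask.mask).astype(float)
    t = (coords - centroid) @ axis
    edges = np.linspace(t.min(), t.max() + 1e-9, n_bins + 1)
    which = np.digitize(t, edges) - 1
    positions, means = [], []
    for b in range(n_bins):
        sel = which == b
        if sel.any():
            positions.append(0.5 * (edges[b] + edges[b + 1]))
            means.append(float(vals[sel].mean()))
    return MapSummary(
        mean=float(vals.mean()),
        sd=float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
        min=float(vals.min()),
        max=float(vals.max()),
        profile_positions=np.asarray(positions),
        profile=np.asarray(means),
    )


def render_map(
    pmap: PredictionMap,
    colormap: str = "jet",
    out_path=None,
    scale_limits: tuple[float, float] | None = None,
    background_gray: float = 0.85,
) -> np.ndarray:
    """Render the map as an RGBA raster with a blue-to-red scale.

    Color limits default to the 1st/99th percentiles of the masked values;
    the background is a neutral gray. When ``out_path`` is given, a PNG is
    written along with a ``<out_path>.json`` sidecar holding the color-scale
    metadata so renders are reproducible. Returns the RGBA array.
    """
    disp = pmap.display_values()
    masked = disp[pmap.mask.mask]
    if scale_limits is None:
        lo, hi = np.percentile(masked, [1, 99])
    else:
        lo, hi = map(float, scale_limits)
    if hi <= lo:
        hi = lo + 1e-12
    norm = np.clip((disp - lo) / (hi - lo), 0.0, 1.0)
    cmap = colormaps[colormap]
    rgba = cmap(norm)
    rgba[~pmap.mask.mask] = (background_gray, background_gray, background_gray, 1.0)
    if out_path is not None:
        mpimage.imsave(out_path, rgba)
        meta = {
            "pigment": pmap.pigment,
            "model_id": pmap.model_id,
            "colormap": colormap,
            "scale_lo": float(lo),
            "scale_hi": float(hi),
            "clip_count": pmap.clip_count,
            "n_pixels": pmap.mask.n_pixels,
        }
        with open(f"{out_path}.json", "w") as fh:
            json.dump(meta, fh, indent=2)
    return rgba


def save_map(pmap: PredictionMap, path) -> None:
    """Export the raw map as delimited text (NaN outside the mask) plus a
    JSON sidecar with provenance."""
    np.savetxt(path, pmap.values, delimiter=",")
    meta = {
        "pigment": pmap.pigment,
        "model_id": pmap.model_id,
        "clip_count": pmap.clip_count,
        "n_pixels": pmap.mask.n_pixels,
    }
    with open(f"{path}.json", "w") as fh:
        json.dump(meta, fh, indent=2)
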