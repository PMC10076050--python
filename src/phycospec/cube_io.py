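"""ENVI-style cube I/O, white/dark reflectance calibration, ROI extraction.

The supported ENVI dialect is the minimal faithful subset produced by
Specim-style line scanners: a text header (``samples``, ``lines``, ``bands``,
``data type``, ``interleave``, ``byte order``, ``wavelength``) next to a raw
binary file; data types unsigned 16-bit int (code 12) and 32-bit float
(code 4); interleaves BSQ, BIL, BIP. Unknown header fields are ignored with
a logged warning. In memory the band axis is always last.
"""

from __future__ import annotations

import logging

import numpy as np

from .datatypes import ROIMask, SpectralCube, Spectrum, WavelengthGrid
from .errors import (
    CorruptionError,
    DegenerateReferenceError,
    EmptyROIError,
    FormatError,
    InvalidArgumentError,
    ShapeError,
)

logger = logging.getLogger(__name__)

#: ENVI data-type code -> numpy dtype (little-endian assumed; byte order 0)
_DTYPE_CODES = {4: np.dtype("<f4"), 12: np.dtype("<u2")}
_CODE_FOR_KIND = {"f": 4, "u": 12, "i": 12}

_MANDATORY_FIELDS = (
    "samples",
    "lines",
    "bands",
    "data type",
    "interleave",
    "byte order",
    "wavelength",
)

_KNOWN_FIELDS = set(_MANDATORY_FIELDS) | {"calibrated", "description", "header offset"}


# ---------------------------------------------------------------------------
# header parsing / writing
# ---------------------------------------------------------------------------


def _parse_header(text: str) -> dict:
    """Parse ``key = value`` lines, including multi-line ``{ ... }`` blocks."""
    fields: dict[str, str] = {}
    lines = iter(text.splitlines())
    first = next(lines, "")
    if first.strip() != "ENVI":
        raise FormatError("not an ENVI header: missing 'ENVI' magic line")
    for line in lines:
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        key = key.strip().lower()
        value = value.strip()
        if value.startswith("{") and "}" not in value:
            parts = [value]
            for cont in lines:
                parts.append(cont.strip())
                if "}" in cont:
                    break
            value = " ".join(parts)
        fields[key] = value
        if key not in _KNOWN_FIELDS:
            logger.warning("ignoring unknown ENVI header field %r", key)
    return fields


def read_envi_cube(header_path, data_path) -> SpectralCube:
    """Read an ENVI header/binary pair into a band-last :class:`SpectralCube`.

    Raises :class:`FormatError` naming any missing mandatory field and
    :class:`CorruptionError` if the binary size disagrees with the header.
    """
    with open(header_path) as fh:
        fields = _parse_header(fh.read())
    for name in _MANDATORY_FIELDS:
        if name not in fields:
            raise FormatError(f"ENVI header missing mandatory field '{name}'")

    samples = int(fields["samples"])
    lines_n = int(fields["lines"])
    bands = int(fields["bands"])
    code = int(fields["data type"])
    interleave = fields["interleave"].lower()
    byte_order = int(fields["byte order"])
    if code not in _DTYPE_CODES:
        raise FormatError(f"unsupported ENVI data type code {code}; expected 4 or 12")
    if interleave not in ("bsq", "bil", "bip"):
        raise FormatError(f"unsupported interleave {interleave!r}")
    if byte_order != 0:
        raise FormatError("only byte order 0 (little-endian) is supported")

    wl_text = fields["wavelength"].strip().lstrip("{").rstrip("}")
    centers = np.array([float(tok) for tok in wl_text.split(",") if tok.strip()])
    if centers.size != bands:
        raise CorruptionError(
            f"header declares {bands} bands but lists {centers.size} wavelengths"
        )

    dtype = _DTYPE_CODES[code]
    raw = np.fromfile(data_path, dtype=dtype)
    expected = samples * lines_n * bands
    if raw.size != expected:
        raise CorruptionError(
            f"binary holds {raw.size} values but header implies {expected} "
            f"({lines_n} lines x {samples} samples x {bands} bands)"
        )

    if interleave == "bsq":
        values = raw.reshape(bands, lines_n, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        values = raw.reshape(lines_n, bands, samples).transpose(0, 2, 1)
    else:  # bip
        values = raw.reshape(lines_n, samples, bands)

    return SpectralCube(
        values=np.ascontiguousarray(values),
        grid=WavelengthGrid(centers),
        calibrated=bool(int(fields.get("calibrated", "0"))),
        band_interleave=interleave,
    )


def write_envi_cube(cube: SpectralCube, header_path, data_path) -> None:
    """Write a cube as an ENVI header/binary pair.

    Integer cubes are stored as unsigned 16-bit, anything else as 32-bit
    float. Wavelengths are serialized with full round-trip precision so the
    grid survives write -> read exactly.
    """
    kind = np.asarray(cube.values).dtype.kind
    code = _CODE_FOR_KIND.get(kind, 4)
    dtype = _DTYPE_CODES[code]
    data = np.ascontiguousarray(cube.values, dtype=dtype)
    h, w, b = data.shape

    interleave = cube.band_interleave
    if interleave == "bsq":
        ordered = data.transpose(2, 0, 1)
    elif interleave == "bil":
        ordered = data.transpose(0, 2, 1)
    else:
        ordered = data

    wl = ", ".join(repr(float(v)) for v in cube.grid.centers)
    header = (
        "ENVI\n"
        f"samples = {w}\n"
        f"lines = {h}\n"
        f"bands = {b}\n"
        f"data type = {code}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        f"calibrated = {int(cube.calibrated)}\n"
        f"wavelength = {{ {wl} }}\n"
    )
    with open(header_path, "w") as fh:
        fh.write(header)
    with open(data_path, "wb") as fh:
        ordered.tofile(fh)


# ---------------------------------------------------------------------------
# radiometric calibration
# ---------------------------------------------------------------------------


def _reference_array(ref, cube_shape, grid) -> np.ndarray:
    """Normalize a Spectrum / cube / array reference to a broadcastable array."""
    if isinstance(ref, Spectrum):
        if ref.grid.n_bands != cube_shape[2]:
            raise ShapeError("reference spectrum band count mismatch")
        return ref.values[None, None, :]
    if isinstance(ref, SpectralCube):
        if ref.values.shape != cube_shape:
            raise ShapeError("reference cube shape mismatch")
        return np.asarray(ref.values, dtype=float)
    arr = np.asarray(ref, dtype=float)
    if arr.ndim == 1:
        if arr.size != cube_shape[2]:
            raise ShapeError("reference vector band count mismatch")
        return arr[None, None, :]
    if arr.shape != cube_shape:
        raise ShapeError("reference array shape mismatch")
    return arr


def calibrate_reflectance(
    raw: SpectralCube,
    white,
    dark=None,
    panel_factor: float = 0.99,
    clip_max: float = 1.5,
) -> SpectralCube:
    """White/dark radiometric calibration of a raw cube.

    reflectance = panel_factor * (raw - dark) / (white - dark), clipped to
    [0, clip_max]. ``panel_factor`` is the reflectivity of the white
    reference panel (0.99 for a 99%-reflectance panel). The number of
    clipped values is reported in the result's ``meta['n_clipped']``.
    """
    shape = raw.values.shape
    white_a = _reference_array(white, shape, raw.grid)
    dark_a = (
        np.zeros_like(white_a)
        if dark is None
        else _reference_array(dark, shape, raw.grid)
    )
    denom = white_a - dark_a
    zero = denom == 0
    if zero.any():
        bad_bands = sorted(set(np.argwhere(zero)[:, -1].tolist()))
        raise DegenerateReferenceError(
            f"white - dark is zero at bands {bad_bands}"
        )
    refl = panel_factor * (np.asarray(raw.values, dtype=float) - dark_a) / denom
    n_clipped = int(((refl < 0) | (refl > clip_max)).sum())
    refl = np.clip(refl, 0.0, clip_max)
    return SpectralCube(
        values=refl,
        grid=raw.grid,
        calibrated=True,
        band_interleave=raw.band_interleave,
        meta={**raw.meta, "n_clipped": n_clipped, "panel_factor": panel_factor},
    )


# ---------------------------------------------------------------------------
# ROI selection and extraction
# ---------------------------------------------------------------------------

#: wavelength windows used by the default foreground rule (nm)
_VIS_WINDOW = (400.0, 680.0)
_NIR_WINDOW = (720.0, 1000.0)


def auto_roi(
    cube: SpectralCube,
    shadow_quantile: float = 0.02,
    highlight_quantile: float = 0.98,
    nir_threshold: float = 0.15,
    nir_vis_ratio: float = 1.3,
) -> ROIMask:
    """Deterministic thallus mask: red-edge contrast rule + brightness trim.

    Foreground pixels must have mean NIR reflectance above ``nir_threshold``
    and an NIR/Vis contrast above ``nir_vis_ratio`` (photosynthetic tissue is
    dark in the visible and bright in the NIR; a flat background is not).
    Pixels whose broadband brightness falls below the ``shadow_quantile`` or
    above the ``highlight_quantile`` of the foreground brightness
    distribution are then removed, emulating manual exclusion of shadows and
    specular highlights. Quantiles (0, 1) disable the trim.
    """
    if not cube.calibrated:
        raise InvalidArgumentError("auto_roi requires a calibrated cube")
    if not 0.0 <= shadow_quantile <= highlight_quantile <= 1.0:
        raise InvalidArgumentError("need 0 <= shadow_q <= highlight_q <= 1")

    vis_sel = cube.grid.band_slice(*_VIS_WINDOW)
    nir_sel = cube.grid.band_slice(*_NIR_WINDOW)
    if not vis_sel.any() or not nir_sel.any():
        raise InvalidArgumentError("grid does not cover both Vis and NIR windows")

    values = np.asarray(cube.values, dtype=float)
    vis_mean = values[:, :, vis_sel].mean(axis=2)
    nir_mean = values[:, :, nir_sel].mean(axis=2)
    fg = (nir_mean > nir_threshold) & (
        nir_mean > nir_vis_ratio * np.maximum(vis_mean, 1e-12)
    )
    if not fg.any():
        raise EmptyROIError("foreground rule selected no pixels")

    brightness = values.mean(axis=2)
    lo, hi = np.quantile(brightness[fg], [shadow_quantile, highlight_quantile])
    keep = fg & (brightness >= lo) & (brightness <= hi)
    if not keep.any():
        raise EmptyROIError("all foreground pixels trimmed as shadow/highlight")
    return ROIMask(keep)


def mean_spectrum(cube: SpectralCube, mask: ROIMask) -> Spectrum:
    """Bandwise arithmetic mean over masked pixels."""
    if mask.shape != cube.values.shape[:2]:
        raise ShapeError("mask shape does not match cube")
    if mask.n_pixels == 0:
        raise EmptyROIError("cannot average over an empty mask")
    return Spectrum(
        np.asarray(cube.values, dtype=float)[mask.mask].mean(axis=0), cube.grid
    )


# ---------------------------------------------------------------------------
# mask serialization (plain text, one row per line, 0/1 characters)
# ---------------------------------------------------------------------------


def write_mask(mask: ROIMask, path) -> None:
    with open(path, "w") as fh:
        for row in mask.mask:
            fh.write("".join("1" if v else "0" for v in row) + "\n")


def read_mask(path) -> ROIMask:
    with open(path) as fh:
        rows = [line.strip() for line in fh if line.strip()]
    if not rows:
        raise FormatError("empty mask file")
    width = len(rows[0])
    if any(len(r) != width for r in rows) or any(set(r) - {"0", "1"} for r in rows):
        raise FormatError("mask file must be rectangular rows of 0/1 characters")
    return ROIMask(np.array([[c == "1" for c in r] for r in rows]))
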