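"""Shared in-memory containers for spectra, cubes, masks and sample sets.

These are deliberately thin dataclasses around numpy arrays / pandas frames;
all numerical work lives in the operation modules. Conventions used
throughout the package:

* wavelength axis is always the *last* array axis (band-last layout),
* spatial indexing is row-major, 0-based ``(row, col)``,
* reflectance is a dimensionless fraction, pigment content is mg/g fresh
  weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError, ShapeError

#: canonical pigment order used for every 4-vector in the package
PIGMENTS: tuple[str, ...] = ("pe", "pc", "apc", "chla")


@dataclass(frozen=True)
class WavelengthGrid:
    """Ordered band-center wavelengths (nm) defining the spectral axis."""

    centers: np.ndarray

    def __post_init__(self):
        centers = np.asarray(self.centers, dtype=float)
        object.__setattr__(self, "centers", centers)
        if centers.ndim != 1 or centers.size < 2:
            raise InvalidArgumentError("grid needs at least 2 band centers")
        if not np.all(np.isfinite(centers)):
            raise InvalidArgumentError("grid centers must be finite")
        if not np.all(np.diff(centers) > 0):
            raise InvalidArgumentError("grid centers must be strictly increasing")

    @property
    def n_bands(self) -> int:
        return int(self.centers.size)

    @property
    def lo(self) -> float:
        return float(self.centers[0])

    @property
    def hi(self) -> float:
        return float(self.centers[-1])

    @property
    def spacing(self) -> float:
        """Mean band spacing in nm (exact for evenly spaced grids)."""
        return float((self.hi - self.lo) / (self.n_bands - 1))

    def index_of(self, wavelength: float) -> int:
        """Index of the band center nearest to ``wavelength``."""
        return int(np.argmin(np.abs(self.centers - wavelength)))

    def band_slice(self, lo: float, hi: float) -> np.ndarray:
        """Boolean selector for bands with ``lo <= center <= hi``."""
        return (self.centers >= lo) & (self.centers <= hi)

    def __len__(self) -> int:
        return self.n_bands

    def __eq__(self, other) -> bool:
        return isinstance(other, WavelengthGrid) and np.array_equal(
            self.centers, other.centers
        )

    def __hash__(self):
        return hash(self.centers.tobytes())


@dataclass
class Spectrum:
    """A single reflectance spectrum aligned to a :class:`WavelengthGrid`."""

    values: np.ndarray
    grid: WavelengthGrid

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size != self.grid.n_bands:
            raise ShapeError(
                f"spectrum length {self.values.size} != grid length {self.grid.n_bands}"
            )


@dataclass
class SpectralCube:
    """H x W x B hyperspectral array on a wavelength grid.

    ``values`` is always stored band-last in memory regardless of the file
    interleave it came from; ``band_interleave`` only records the preferred
    on-disk layout. ``calibrated`` distinguishes raw sensor counts from
    white/dark-referenced reflectance.
    """

    values: np.ndarray
    grid: WavelengthGrid
    calibrated: bool = False
    band_interleave: str = "bip"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ShapeError("cube must be a 3-d H x W x B array")
        if self.values.shape[2] != self.grid.n_bands:
            raise ShapeError(
                f"cube has {self.values.shape[2]} bands, grid has {self.grid.n_bands}"
            )
        if self.band_interleave not in ("bsq", "bil", "bip"):
            raise InvalidArgumentError(
                f"unknown interleave {self.band_interleave!r}; expected bsq/bil/bip"
            )
        if self.calibrated and not np.all(np.isfinite(self.values)):
            raise InvalidArgumentError("calibrated cube must hold finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass
class ROIMask:
    """Boolean H x W foreground map."""

    mask: np.ndarray

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ShapeError("mask must be 2-d")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


@dataclass(frozen=True)
class PigmentPanel:
    """Reference pigment contents of one sample, mg/g fresh weight."""

    pe: float
    pc: float
    apc: float
    chla: float

    def __post_init__(self):
        for name in PIGMENTS:
            v = float(getattr(self, name))
            object.__setattr__(self, name, v)
            if not np.isfinite(v):
                raise InvalidArgumentError(f"{name} must be finite, got {v}")
            if v < 0:
                raise InvalidArgumentError(f"{name} must be >= 0, got {v}")

    def as_array(self) -> np.ndarray:
        return np.array([self.pe, self.pc, self.apc, self.chla], dtype=float)

    @classmethod
    def from_array(cls, values: Sequence[float]) -> "PigmentPanel":
        values = np.asarray(values, dtype=float)
        if values.shape != (4,):
            raise ShapeError("panel array must have exactly 4 entries")
        return cls(*values)

    def scaled(self, factor: float) -> "PigmentPanel":
        return PigmentPanel.from_array(self.as_array() * float(factor))


@dataclass
class SampleSet:
    """Per-sample mean spectra paired with reference pigment panels.

    ``panels`` is a DataFrame with the four pigment columns of
    :data:`PIGMENTS`, one row per sample, aligned with ``spectra`` rows.
    """

    spectra: np.ndarray
    panels: pd.DataFrame
    ids: list[str]
    grid: WavelengthGrid
    split_tag: str | None = None
    source_indices: np.ndarray | None = None

    def __post_init__(self):
        self.spectra = np.asarray(self.spectra, dtype=float)
        if self.spectra.ndim != 2:
            raise ShapeError("spectra must be a 2-d n x B matrix")
        if self.spectra.shape[1] != self.grid.n_bands:
            raise ShapeError("spectra band count does not match grid")
        n = self.spectra.shape[0]
        if len(self.panels) != n or len(self.ids) != n:
            raise ShapeError("spectra, panels and ids must have equal row counts")
        missing = [p for p in PIGMENTS if p not in self.panels.columns]
        if missing:
            raise InvalidArgumentError(f"panels missing pigment columns {missing}")

    @property
    def n(self) -> int:
        return self.spectra.shape[0]

    def y(self, pigment: str) -> np.ndarray:
        """Reference concentration vector for one pigment (mg/g)."""
        if pigment not in PIGMENTS:
            raise InvalidArgumentError(f"unknown pigment {pigment!r}")
        return self.panels[pigment].to_numpy(dtype=float)

    def panel(self, i: int) -> PigmentPanel:
        return PigmentPanel.from_array(
            self.panels.iloc[i][list(PIGMENTS)].to_numpy(dtype=float)
        )

    def subset(self, idx: np.ndarray, split_tag: str | None = None) -> "SampleSet":
        idx = np.asarray(idx, dtype=int)
        return SampleSet(
            spectra=self.spectra[idx],
            panels=self.panels.iloc[idx].reset_index(drop=True),
            ids=[self.ids[i] for i in idx],
            grid=self.grid,
            split_tag=split_tag,
            source_indices=idx.copy(),
        )

    # -- delimited-table serialization -------------------------------------

    def to_csv(self, path) -> None:
        """One row per sample: id, the 4 pigments, then reflectance columns
        headed by their wavelength (full float precision)."""
        wl_cols = pd.DataFrame(
            self.spectra, columns=[repr(float(w)) for w in self.grid.centers]
        )
        frame = pd.concat(
            [
                pd.DataFrame({"id": self.ids}),
                self.panels[list(PIGMENTS)].reset_index(drop=True),
                wl_cols,
            ],
            axis=1,
        )
        frame.to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path, split_tag: str | None = None) -> "SampleSet":
        frame = pd.read_csv(path, float_precision="round_trip")
        meta_cols = ["id", *PIGMENTS]
        wl_cols = [c for c in frame.columns if c not in meta_cols]
        grid = WavelengthGrid(np.array([float(c) for c in wl_cols]))
        return cls(
            spectra=frame[wl_cols].to_numpy(dtype=float),
            panels=frame[list(PIGMENTS)].copy(),
            ids=[str(v) for v in frame["id"]],
            grid=grid,
            split_tag=split_tag,
        )
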