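"""Synthetic Vis-NIR reflectance and wet-chemistry data generator.

Red-macroalga thalli show a characteristic 400-1000 nm reflectance signature:
pigment absorption wells in the visible (PE near 500/570 nm, PC near 620 nm,
APC near 650 nm, chlorophyll-a near 440/660 nm), a steep red-edge rise to a
high near-infrared plateau, and a shallow O-H water dip near 970 nm. This
module generates spectra, whole cubes with a holdfast-to-tip concentration
gradient, and spectrophotometric absorbance readings with exactly that
structure, so the calibration pipeline can be exercised end to end on data
whose ground truth is known.

The optical model is a single-layer Beer-Lambert attenuation of a smooth
baseline:

    R(lambda) = plateau(lambda) * exp(-sum_p c_p * k_p(lambda) - k_w(lambda))

with Gaussian absorption kernels ``k_p`` per pigment, pigment contents
``c_p`` in mg/g fresh weight, and a logistic red-edge plateau. Measurement
noise is applied per spectrum as ``(1 + m) * R + b + eps`` (multiplicative
gain, baseline offset, independent band noise).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from .datatypes import (
    PIGMENTS,
    PigmentPanel,
    ROIMask,
    SampleSet,
    SpectralCube,
    Spectrum,
    WavelengthGrid,
)
from .errors import InvalidArgumentError, InvalidModelError, ShapeError

# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AbsorptionBand:
    """One Gaussian absorption kernel.

    ``strength`` is the specific absorption at the band center per unit
    concentration (mg/g); ``width`` is the Gaussian standard deviation in nm.
    """

    center: float
    width: float
    strength: float

    def __post_init__(self):
        if not (self.width > 0 and self.strength > 0):
            raise InvalidArgumentError("band width and strength must be > 0")

    def kernel(self, wavelengths: np.ndarray) -> np.ndarray:
        z = (np.asarray(wavelengths, dtype=float) - self.center) / self.width
        return self.strength * np.exp(-0.5 * z * z)


@dataclass(frozen=True)
class NoiseSpec:
    """Per-spectrum corruption model: (1+m)*R + b + eps.

    m ~ N(0, multiplicative_sd), b ~ N(0, baseline_sd),
    eps ~ iid N(0, additive_sd) per band. All in reflectance units
    (multiplicative_sd is a fraction). ``seed`` makes draws reproducible.
    """

    additive_sd: float = 0.005
    multiplicative_sd: float = 0.03
    baseline_sd: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if min(self.additive_sd, self.multiplicative_sd, self.baseline_sd) < 0:
            raise InvalidArgumentError("noise standard deviations must be >= 0")

    @classmethod
    def zero(cls, seed: int = 0) -> "NoiseSpec":
        return cls(0.0, 0.0, 0.0, seed)


@dataclass(frozen=True)
class WetChemCoefficients:
    """Opaque linear pigment-equation coefficients.

    ``phyco_matrix`` maps absorbances (A498, A614, A651) to extract
    concentrations (PE, PC, APC) in mg/mL; ``chla_vector`` maps (A646, A663)
    to the Chla extract concentration. Tissue content (mg/g fresh weight) is
    extract concentration x extract volume / fresh weight.
    """

    phyco_matrix: np.ndarray
    chla_vector: np.ndarray
    extract_volume_phyco: float
    extract_volume_chl: float
    fresh_weight: float
    a646_over_a663: float = 0.35

    def __post_init__(self):
        m = np.asarray(self.phyco_matrix, dtype=float)
        v = np.asarray(self.chla_vector, dtype=float)
        object.__setattr__(self, "phyco_matrix", m)
        object.__setattr__(self, "chla_vector", v)
        if m.shape != (3, 3):
            raise ShapeError("phyco_matrix must be 3x3")
        if v.shape != (2,):
            raise ShapeError("chla_vector must have 2 entries")
        if abs(np.linalg.det(m)) < 1e-12:
            raise InvalidModelError("phyco_matrix is singular")
        if min(self.extract_volume_phyco, self.extract_volume_chl, self.fresh_weight) <= 0:
            raise InvalidArgumentError("volumes and fresh weight must be > 0")


@dataclass(frozen=True)
class AbsorbanceReadings:
    """The five spectrophotometer readings of one wet-chemistry assay."""

    a498: float
    a614: float
    a651: float
    a646: float
    a663: float

    def phyco(self) -> np.ndarray:
        return np.array([self.a498, self.a614, self.a651])

    def chl(self) -> np.ndarray:
        return np.array([self.a646, self.a663])


@dataclass(frozen=True)
class ConcentrationReadout:
    """Pigment contents recovered from absorbances, mg/g fresh weight.

    Unlike :class:`PigmentPanel` this may carry (flagged) negative values:
    noisy absorbances can invert to slightly negative concentrations, and the
    inversion reports rather than hides them. Negatives above -1e-6 are
    clamped to zero; anything lower passes through with its pigment named in
    ``negative_pigments``.
    """

    pe: float
    pc: float
    apc: float
    chla: float
    negative_pigments: tuple[str, ...] = ()

    def as_array(self) -> np.ndarray:
        return np.array([self.pe, self.pc, self.apc, self.chla], dtype=float)

    def to_panel(self) -> PigmentPanel:
        """Clamp any negatives to zero and return a valid panel."""
        return PigmentPanel.from_array(np.maximum(self.as_array(), 0.0))


# ---------------------------------------------------------------------------
# defaults: the simulated study conditions
# ---------------------------------------------------------------------------

#: Gaussian absorption bands per pigment. Centers follow the thallus
#: absorption features (PE 500/570, PC 620, APC 650, Chla 440/660 nm);
#: widths are a common 12 nm; strengths are set so mid-range contents
#: produce ~0.3-0.7 visible reflectance. APC is deliberately weak and
#: overlaps the Chla 660 nm band, making it the hardest target.
DEFAULT_BANDS: dict[str, tuple[AbsorptionBand, ...]] = {
    "pe": (AbsorptionBand(500.0, 12.0, 0.08), AbsorptionBand(570.0, 12.0, 0.08)),
    "pc": (AbsorptionBand(620.0, 12.0, 0.15),),
    "apc": (AbsorptionBand(650.0, 12.0, 0.08),),
    "chla": (AbsorptionBand(440.0, 12.0, 0.30), AbsorptionBand(660.0, 12.0, 0.25)),
}

#: O-H stretching overtone dip on the NIR plateau.
DEFAULT_WATER_BAND = AbsorptionBand(970.0, 25.0, 0.12)

#: lab-culture concentration ranges (mg/g fresh weight) spanned by the
#: reference assays; the calibration span of the synthetic sample sets.
LAB_RANGES: dict[str, tuple[float, float]] = {
    "pe": (1.840, 13.450),
    "pc": (0.960, 5.270),
    "apc": (0.430, 2.350),
    "chla": (0.290, 2.230),
}

#: narrower field-collected ranges, used for external-validation sets.
FIELD_RANGES: dict[str, tuple[float, float]] = {
    "pe": (0.939, 6.229),
    "pc": (0.589, 4.650),
    "apc": (0.294, 1.838),
    "chla": (0.299, 0.845),
}

#: red-edge plateau parameters: visible-range baseline level, NIR plateau
#: level, logistic transition center and width (nm).
DEFAULT_VIS_LEVEL = 0.55
DEFAULT_NIR_PLATEAU = 0.85
RED_EDGE_CENTER = 705.0
RED_EDGE_WIDTH = 15.0

#: flat bright background (Teflon-sheet-like) behind the thallus in cubes.
DEFAULT_BACKGROUND_REFLECTANCE = 0.90


def load_wet_chem_coefficients(path=None) -> WetChemCoefficients:
    """Load pigment-equation coefficients from YAML (package default config
    if ``path`` is None)."""
    if path is None:
        text = (
            resources.files("phycospec").joinpath("data/wet_chem.yaml").read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    return WetChemCoefficients(
        phyco_matrix=np.asarray(raw["phyco_matrix"], dtype=float),
        chla_vector=np.asarray(raw["chla_vector"], dtype=float),
        extract_volume_phyco=float(raw["extract_volume_phyco"]),
        extract_volume_chl=float(raw["extract_volume_chl"]),
        fresh_weight=float(raw["fresh_weight"]),
        a646_over_a663=float(raw.get("a646_over_a663", 0.35)),
    )


# ---------------------------------------------------------------------------
# spectral forward model
# ---------------------------------------------------------------------------


def make_wavelength_grid(
    n_bands: int = 204, lo: float = 400.0, hi: float = 1000.0
) -> WavelengthGrid:
    """Evenly spaced band centers spanning [lo, hi] inclusive.

    The default matches a 400-1000 nm Vis-NIR line scanner with 204 bands
    (spacing ~2.956 nm).
    """
    if int(n_bands) != n_bands or n_bands < 2:
        raise InvalidArgumentError(f"n_bands must be an integer >= 2, got {n_bands}")
    if not lo < hi:
        raise InvalidArgumentError(f"need lo < hi, got [{lo}, {hi}]")
    return WavelengthGrid(np.linspace(float(lo), float(hi), int(n_bands)))


def _plateau(
    wavelengths: np.ndarray,
    nir_plateau: float,
    vis_level: float = DEFAULT_VIS_LEVEL,
) -> np.ndarray:
    """Smooth baseline: visible level rising logistically across the red edge."""
    s = expit((wavelengths - RED_EDGE_CENTER) / RED_EDGE_WIDTH)
    return vis_level + (nir_plateau - vis_level) * s


def _pigment_kernels(
    grid: WavelengthGrid, bands: dict[str, tuple[AbsorptionBand, ...]]
) -> np.ndarray:
    """Stack of per-unit-concentration absorption kernels, shape (4, B)."""
    out = np.zeros((len(PIGMENTS), grid.n_bands))
    for i, p in enumerate(PIGMENTS):
        for band in bands.get(p, ()):
            if not (grid.lo <= band.center <= grid.hi):
                raise InvalidArgumentError(
                    f"band center {band.center} nm outside grid "
                    f"[{grid.lo}, {grid.hi}] nm"
                )
            out[i] += band.kernel(grid.centers)
    return out


def _reflectance_matrix(
    concentrations: np.ndarray,
    grid: WavelengthGrid,
    bands: dict[str, tuple[AbsorptionBand, ...]],
    nir_plateau: float,
    water_band: AbsorptionBand,
    vis_level: float = DEFAULT_VIS_LEVEL,
) -> np.ndarray:
    """Noiseless reflectance for an (n, 4) concentration matrix -> (n, B)."""
    concentrations = np.atleast_2d(np.asarray(concentrations, dtype=float))
    if np.any(concentrations < 0):
        raise InvalidArgumentError("concentrations must be >= 0")
    kernels = _pigment_kernels(grid, bands)
    # elementwise accumulation (not a matmul) so batch and single-spectrum
    # evaluation are bit-identical
    optical_depth = np.broadcast_to(
        water_band.kernel(grid.centers), (concentrations.shape[0], grid.n_bands)
    ).copy()
    for i in range(len(PIGMENTS)):
        optical_depth += concentrations[:, i : i + 1] * kernels[i]
    return _plateau(grid.centers, nir_plateau, vis_level) * np.exp(-optical_depth)


def pigment_reflectance(
    panel: PigmentPanel,
    grid: WavelengthGrid,
    bands: dict[str, tuple[AbsorptionBand, ...]] | None = None,
    nir_plateau: float = DEFAULT_NIR_PLATEAU,
    water_band: AbsorptionBand | None = None,
    vis_level: float = DEFAULT_VIS_LEVEL,
) -> Spectrum:
    """Noiseless Beer-Lambert reflectance spectrum of one pigment panel.

    R(lambda) = plateau(lambda) * exp(-sum_p c_p k_p(lambda) - k_w(lambda));
    all values lie in (0, 1] and reflectance is strictly decreasing in each
    concentration wherever that pigment absorbs.
    """
    bands = DEFAULT_BANDS if bands is None else bands
    water_band = DEFAULT_WATER_BAND if water_band is None else water_band
    values = _reflectance_matrix(
        panel.as_array(), grid, bands, nir_plateau, water_band, vis_level
    )[0]
    return Spectrum(values, grid)


# ---------------------------------------------------------------------------
# sample sets and cubes
# ---------------------------------------------------------------------------


def _corrupt(
    spectra: np.ndarray, noise: NoiseSpec, rng: np.random.Generator
) -> np.ndarray:
    """(1+m)*R + b + eps, with one (m, b) per row and iid eps per band."""
    n, n_bands = spectra.shape
    m = rng.normal(0.0, noise.multiplicative_sd, size=(n, 1))
    b = rng.normal(0.0, noise.baseline_sd, size=(n, 1))
    eps = rng.normal(0.0, noise.additive_sd, size=(n, n_bands))
    return (1.0 + m) * spectra + b + eps


def simulate_sample_set(
    n: int = 96,
    ranges: dict[str, tuple[float, float]] | None = None,
    noise: NoiseSpec | None = None,
    grid: WavelengthGrid | None = None,
    bands: dict[str, tuple[AbsorptionBand, ...]] | None = None,
    nir_plateau: float = DEFAULT_NIR_PLATEAU,
    water_band: AbsorptionBand | None = None,
    id_prefix: str = "S",
) -> SampleSet:
    """Generate ``n`` samples with uniform concentrations and noisy spectra.

    Concentrations are drawn uniformly within the per-pigment ranges
    (defaults to the lab-culture calibration span), spectra from the
    Beer-Lambert forward model corrupted by the noise model. Identical
    ``noise.seed`` gives bit-identical output.
    """
    if n < 4:
        raise InvalidArgumentError(f"need n >= 4 samples, got {n}")
    ranges = LAB_RANGES if ranges is None else ranges
    noise = NoiseSpec() if noise is None else noise
    grid = make_wavelength_grid() if grid is None else grid
    bands = DEFAULT_BANDS if bands is None else bands
    water_band = DEFAULT_WATER_BAND if water_band is None else water_band

    for p in PIGMENTS:
        lo, hi = ranges[p]
        if lo < 0 or not lo < hi:
            raise InvalidArgumentError(f"invalid range for {p}: ({lo}, {hi})")

    rng = np.random.default_rng(noise.seed)
    conc = np.column_stack(
        [rng.uniform(ranges[p][0], ranges[p][1], size=n) for p in PIGMENTS]
    )
    clean = _reflectance_matrix(conc, grid, bands, nir_plateau, water_band)
    spectra = _corrupt(clean, noise, rng)
    panels = pd.DataFrame(conc, columns=list(PIGMENTS))
    ids = [f"{id_prefix}{i + 1:03d}" for i in range(n)]
    return SampleSet(spectra=spectra, panels=panels, ids=ids, grid=grid)


def thallus_mask(shape: tuple[int, int], axis: int = 0) -> np.ndarray:
    """Axis-aligned elongated ellipse standing in for a thallus blade.

    The long semi-axis (0.45 x extent) lies along ``axis`` (the
    holdfast-to-tip direction), the short one is 0.28 x extent.
    """
    h, w = shape
    rows, cols = np.mgrid[0:h, 0:w]
    cr, cc = (h - 1) / 2.0, (w - 1) / 2.0
    if axis == 0:
        a, b = 0.45 * h, 0.28 * w
    else:
        a, b = 0.28 * h, 0.45 * w
    return ((rows - cr) / a) ** 2 + ((cols - cc) / b) ** 2 <= 1.0


def simulate_cube(
    shape: tuple[int, int] = (512, 512),
    panel_base: PigmentPanel | None = None,
    gradient_axis: int = 0,
    gradient_factor: float = 2.0,
    noise: NoiseSpec | None = None,
    grid: WavelengthGrid | None = None,
    bands: dict[str, tuple[AbsorptionBand, ...]] | None = None,
    nir_plateau: float = DEFAULT_NIR_PLATEAU,
    water_band: AbsorptionBand | None = None,
    background_reflectance: float = DEFAULT_BACKGROUND_REFLECTANCE,
) -> tuple[SpectralCube, np.ndarray, ROIMask]:
    """Simulate a calibrated reflectance cube of one thallus.

    Inside an elliptical foreground mask, per-pixel concentrations
    interpolate linearly from ``panel_base`` at the holdfast end (low index
    along ``gradient_axis``) to ``gradient_factor * panel_base`` at the tip.
    Background pixels carry a flat bright reference spectrum. Returns
    ``(cube, concentration_map, mask)`` where ``concentration_map`` is an
    H x W x 4 ground-truth array (zero outside the mask).
    """
    h, w = shape
    if h < 2 or w < 2:
        raise InvalidArgumentError(f"degenerate cube shape {shape}")
    if gradient_factor < 1.0:
        raise InvalidArgumentError("gradient_factor must be >= 1")
    if gradient_axis not in (0, 1):
        raise InvalidArgumentError("gradient_axis must be 0 (rows) or 1 (cols)")
    if panel_base is None:
        # mid-range lab panel
        panel_base = PigmentPanel.from_array(
            [0.5 * (lo + hi) for lo, hi in (LAB_RANGES[p] for p in PIGMENTS)]
        )
    noise = NoiseSpec() if noise is None else noise
    grid = make_wavelength_grid() if grid is None else grid
    bands = DEFAULT_BANDS if bands is None else bands
    water_band = DEFAULT_WATER_BAND if water_band is None else water_band

    fg = thallus_mask((h, w), axis=gradient_axis)
    if not fg.any():
        raise InvalidArgumentError("foreground mask is empty for this shape")

    # normalized holdfast->tip position within the mask's own extent
    coords = np.argwhere(fg)
    pos = coords[:, gradient_axis].astype(float)
    lo_p, hi_p = pos.min(), pos.max()
    t = (pos - lo_p) / max(hi_p - lo_p, 1.0)
    factors = 1.0 + (gradient_factor - 1.0) * t

    conc_map = np.zeros((h, w, 4))
    conc_map[fg] = factors[:, None] * panel_base.as_array()[None, :]

    rng = np.random.default_rng(noise.seed)
    clean_fg = _reflectance_matrix(
        conc_map[fg], grid, bands, nir_plateau, water_band
    )
    values = np.full((h, w, grid.n_bands), float(background_reflectance))
    values[fg] = clean_fg
    flat = _corrupt(values.reshape(h * w, grid.n_bands), noise, rng)
    cube = SpectralCube(
        values=flat.reshape(h, w, grid.n_bands),
        grid=grid,
        calibrated=True,
        meta={"synthetic": True, "gradient_factor": float(gradient_factor)},
    )
    return cube, conc_map, ROIMask(fg)


# ---------------------------------------------------------------------------
# wet-chemistry emulation
# ---------------------------------------------------------------------------


def simulate_wet_chem(
    panel: PigmentPanel,
    coeffs: WetChemCoefficients | None = None,
    absorbance_noise_sd: float = 0.0,
    seed: int = 0,
) -> AbsorbanceReadings:
    """Invert the pigment equations: tissue contents -> absorbance readings.

    Tissue mg/g is converted to extract mg/mL through the fresh weight and
    extract volumes, the phycobiliprotein matrix is inverted for
    (A498, A614, A651), and the Chla absorbances are placed on the fixed
    A646/A663 ratio of a pure extract. Seeded Gaussian noise (AU) is added
    last. With zero noise, :func:`absorbance_to_concentration` recovers the
    panel to 1e-9 relative error.
    """
    coeffs = load_wet_chem_coefficients() if coeffs is None else coeffs
    if absorbance_noise_sd < 0:
        raise InvalidArgumentError("absorbance_noise_sd must be >= 0")

    fw = coeffs.fresh_weight
    ext_phyco = panel.as_array()[:3] * fw / coeffs.extract_volume_phyco
    a_phyco = np.linalg.solve(coeffs.phyco_matrix, ext_phyco)

    ext_chla = panel.chla * fw / coeffs.extract_volume_chl
    r = coeffs.a646_over_a663
    denom = coeffs.chla_vector[0] * r + coeffs.chla_vector[1]
    if abs(denom) < 1e-12:
        raise InvalidModelError(
            "chla_vector is orthogonal to the assumed A646/A663 extract shape"
        )
    a663 = ext_chla / denom
    a646 = r * a663

    readings = np.array([a_phyco[0], a_phyco[1], a_phyco[2], a646, a663])
    if absorbance_noise_sd > 0:
        rng = np.random.default_rng(seed)
        readings = readings + rng.normal(0.0, absorbance_noise_sd, size=5)
    return AbsorbanceReadings(*readings)


def absorbance_to_concentration(
    readings: AbsorbanceReadings, coeffs: WetChemCoefficients | None = None
) -> ConcentrationReadout:
    """Apply the pigment equations and scale to mg/g fresh weight.

    Tiny negative results (> -1e-6 mg/g) are clamped to zero; larger
    negatives pass through flagged in ``negative_pigments``.
    """
    coeffs = load_wet_chem_coefficients() if coeffs is None else coeffs
    ext_phyco = coeffs.phyco_matrix @ readings.phyco()
    ext_chla = float(coeffs.chla_vector @ readings.chl())

    fw = coeffs.fresh_weight
    tissue = np.empty(4)
    tissue[:3] = ext_phyco * coeffs.extract_volume_phyco / fw
    tissue[3] = ext_chla * coeffs.extract_volume_chl / fw

    tiny = (tissue < 0) & (tissue > -1e-6)
    tissue[tiny] = 0.0
    flagged = tuple(p for p, v in zip(PIGMENTS, tissue) if v < 0)
    return ConcentrationReadout(*tissue, negative_pigments=flagged)
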