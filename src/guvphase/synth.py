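"""Seeded synthetic-data generators for every assay modality.

Each generator returns the data object plus a :class:`GroundTruth` record
sufficient to predict the ideal (noise-free) output of its matched
analysis stage, so every downstream stage can be tested by parameter
recovery. Identical ``(cfg.seed, parameters)`` give bit-identical
outputs.

Noise model: additive Gaussian with sd ``cfg.noise_sd`` (in the data's
own intensity units), clipped at 0. Generators whose natural scale
differs from camera counts (FRAP traces, spectra, strain series,
diffusion profiles) accept a ``noise_sd`` override.

The defaults emulate the study conditions of the assays they stand in
for: 0.1 µm pixels on a 256×256 field, ring-shaped GUV membranes with
protein coats, two-emission-window ratio images encoding a configured
lipid order φ, fields of non-overlapping disk condensates, exponential
FRAP recovery sampled at 11 Hz, lipid C=O + amide-I spectra on a
1400–1794 cm⁻¹ grid at 2 cm⁻¹ steps (liquid C=O at 1730 cm⁻¹, gel at
1738 cm⁻¹ — the reported 8 cm⁻¹ shift above the liquid position — both
~20 cm⁻¹ wide), linear strain–pressure series over 100–1000 Pa, and
lateral advection–diffusion spreading profiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np

from .errors import GeometryError, PackingError, ParameterError
from .imaging import ImageChannel
from .kinetics import FRAPTrace, logistic4
from .mechanics import DeformationSeries, PRESSURE_RANGE_PA
from .sizing import (
    ChannelGeometry,
    Conditions,
    DiffusionProfileSet,
    RH_GRID_NM,
    simulate_profiles,
)
from .spectra import AMIDE_SUBBANDS_CM1, Spectrum

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "Band",
    "make_guv_image",
    "make_pk_image",
    "make_condensate_field",
    "make_frap_trace",
    "make_spectrum",
    "make_amide_spectrum",
    "make_deformation_series",
    "make_diffusion_profiles",
    "make_dose_response",
    "lipid_band_preset",
    "amide_band_preset",
    "K_REF_PA",
    "E_REL_PRESETS",
    "CO_LIQUID_CM1",
    "CO_GEL_SHIFT_CM1",
    "CO_WIDTH_CM1",
    "SUV_RH_NM",
]

#: Liquid-phase lipid C=O band centre and width; the gel preset sits
#: CO_GEL_SHIFT_CM1 above the liquid position (the reported shift — the
#: absolute gel position is not printed).
CO_LIQUID_CM1 = 1730.0
CO_GEL_SHIFT_CM1 = 8.0
CO_WIDTH_CM1 = 20.0

#: Reference compliance constant for the deformation law
#: strain = P / (K_REF_PA · E_rel); gives naked-GUV strains of 0.02–0.2
#: over the 100–1000 Pa assay range.
K_REF_PA = 5000.0

#: Relative-stiffness presets. The magnitudes are package inventions
#: constrained by the printed fold-change bounds (>2-fold for the
#: FL coat, >3-fold with ALG2, CALC near naked), not measured values.
E_REL_PRESETS = {"naked": 1.0, "fl": 2.5, "fl_alg2": 3.5, "fl_calc": 1.3}

#: Measured vesicle (SUV) hydrodynamic radius used as the sizing
#: recovery setpoint (nm).
SUV_RH_NM = 18.65


@dataclass
class SynthConfig:
    """Shared generator configuration.

    seed fixed ⇒ bit-identical output; ``noise_sd`` is the additive
    Gaussian sd in the data's own intensity units (clipped at 0) and
    ``background_level`` the off-structure intensity of image modalities.
    """

    seed: int
    pixel_size_um: float = 0.1
    shape: tuple[int, int] = (256, 256)
    noise_sd: float = 2.0
    background_level: float = 10.0

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ParameterError("pixel_size_um must be > 0")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if len(self.shape) != 2 or min(self.shape) < 4:
            raise ParameterError("shape must be (rows, cols) of at least 4")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class GroundTruth:
    """Sidecar truth record; keys are documented per generator."""

    generator: str
    data: dict

    def __getitem__(self, key: str):
        return self.data[key]

    def get(self, key: str, default=None):
        return self.data.get(key, default)


class Band(NamedTuple):
    """One spectral band: centre (cm⁻¹), FWHM (cm⁻¹), peak amplitude."""

    centre_cm1: float
    fwhm_cm1: float
    amplitude: float
    shape: str = "lorentzian"  # or "gaussian"


def _add_noise(rng: np.random.Generator, data: np.ndarray, sd: float) -> np.ndarray:
    if sd == 0:
        return data
    return np.clip(data + rng.normal(0.0, sd, size=data.shape), 0.0, None)


def _ring_mask(shape: tuple[int, int], centre: tuple[float, float],
               radius_px: float, width_px: float) -> np.ndarray:
    rows, cols = np.indices(shape)
    rr = np.hypot(rows - centre[0], cols - centre[1])
    return np.abs(rr - radius_px) <= width_px / 2.0


def _place_rings(cfg: SynthConfig, rng: np.random.Generator, n: int,
                 radius_px: float, width_px: float) -> list[tuple[float, float]]:
    margin = radius_px + width_px / 2.0 + 1.0
    rows, cols = cfg.shape
    if 2 * margin >= min(rows, cols):
        raise GeometryError("ring does not fit inside the field")
    centres: list[tuple[float, float]] = []
    for _ in range(n):
        for _attempt in range(2000):
            c = (rng.uniform(margin, rows - margin), rng.uniform(margin, cols - margin))
            if all(np.hypot(c[0] - o[0], c[1] - o[1]) > 2 * margin for o in centres):
                centres.append(c)
                break
        else:
            raise PackingError(f"could not place {n} non-overlapping GUVs")
    return centres


def make_guv_image(
    cfg: SynthConfig,
    ring_radius_um: float = 5.0,
    ring_width_um: float = 0.8,
    coat_amplitude: float = 100.0,
    n_guvs: int = 1,
    membrane_amplitude: float = 100.0,
) -> tuple[ImageChannel, ImageChannel, GroundTruth]:
    """Render annular GUV membranes with a protein coat.

    The membrane channel shows rings of ``membrane_amplitude`` over the
    background; the protein channel carries ``coat_amplitude`` on the same
    ring pixels (linear in the coat, so doubling the amplitude doubles
    every downstream recruitment measure).

    GroundTruth keys: ``centres_px``, ``ring_radius_um``,
    ``ring_width_um``, ``coat_amplitude``, ``membrane_amplitude``,
    ``ring_area_um2``, ``n_ring_pixels``.
    """
    if n_guvs < 1:
        raise ParameterError("n_guvs must be >= 1")
    if ring_radius_um <= 0 or ring_width_um <= 0:
        raise ParameterError("ring geometry must be positive")
    rng = cfg.rng()
    radius_px = ring_radius_um / cfg.pixel_size_um
    width_px = max(ring_width_um / cfg.pixel_size_um, 1.0)
    centres = _place_rings(cfg, rng, n_guvs, radius_px, width_px)
    ring = np.zeros(cfg.shape, dtype=bool)
    for c in centres:
        ring |= _ring_mask(cfg.shape, c, radius_px, width_px)
    membrane = np.full(cfg.shape, cfg.background_level, dtype=float)
    membrane[ring] += membrane_amplitude
    protein = np.full(cfg.shape, cfg.background_level, dtype=float)
    protein[ring] += coat_amplitude
    membrane = _add_noise(rng, membrane, cfg.noise_sd)
    protein = _add_noise(rng, protein, cfg.noise_sd)
    truth = GroundTruth("guv_image", {
        "centres_px": [tuple(map(float, c)) for c in centres],
        "ring_radius_um": ring_radius_um,
        "ring_width_um": ring_width_um,
        "coat_amplitude": coat_amplitude,
        "membrane_amplitude": membrane_amplitude,
        "n_ring_pixels": int(ring.sum()),
        "ring_area_um2": float(ring.sum()) * cfg.pixel_size_um**2,
    })
    return (
        ImageChannel(membrane, cfg.pixel_size_um, "membrane"),
        ImageChannel(protein, cfg.pixel_size_um, "protein"),
        truth,
    )


def make_pk_image(
    cfg: SynthConfig,
    true_phi: float,
    ring_radius_um: float = 5.0,
    ring_width_um: float = 0.8,
    red_amplitude: float = 100.0,
    n_guvs: int = 1,
) -> tuple[ImageChannel, ImageChannel, ImageChannel, GroundTruth]:
    """Two-emission-window solvatochromic-dye image pair plus a membrane
    marker channel.

    On-membrane pixels carry ``red_amplitude`` in the red window and
    ``true_phi × red_amplitude`` in the blue/green window, so the
    expected per-pixel ratio on the membrane is exactly ``true_phi``;
    off-membrane pixels sit at the background level.

    GroundTruth keys: ``true_phi``, ``centres_px``, ``ring_radius_um``,
    ``ring_width_um``, ``red_amplitude``, ``n_ring_pixels``.
    """
    if true_phi <= 0:
        raise ParameterError("true_phi must be positive")
    rng = cfg.rng()
    radius_px = ring_radius_um / cfg.pixel_size_um
    width_px = max(ring_width_um / cfg.pixel_size_um, 1.0)
    centres = _place_rings(cfg, rng, n_guvs, radius_px, width_px)
    ring = np.zeros(cfg.shape, dtype=bool)
    for c in centres:
        ring |= _ring_mask(cfg.shape, c, radius_px, width_px)
    red = np.full(cfg.shape, cfg.background_level, dtype=float)
    blue = np.full(cfg.shape, cfg.background_level, dtype=float)
    marker = np.full(cfg.shape, cfg.background_level, dtype=float)
    red[ring] = red_amplitude
    blue[ring] = true_phi * red_amplitude
    marker[ring] = red_amplitude
    blue = _add_noise(rng, blue, cfg.noise_sd)
    red = _add_noise(rng, red, cfg.noise_sd)
    marker = _add_noise(rng, marker, cfg.noise_sd)
    truth = GroundTruth("pk_image", {
        "true_phi": true_phi,
        "centres_px": [tuple(map(float, c)) for c in centres],
        "ring_radius_um": ring_radius_um,
        "ring_width_um": ring_width_um,
        "red_amplitude": red_amplitude,
        "n_ring_pixels": int(ring.sum()),
    })
    return (
        ImageChannel(blue, cfg.pixel_size_um, "blue_green"),
        ImageChannel(red, cfg.pixel_size_um, "red"),
        ImageChannel(marker, cfg.pixel_size_um, "marker"),
        truth,
    )


def _disk_pixels(shape: tuple[int, int], centre: tuple[float, float],
                 n_px: int) -> tuple[np.ndarray, float]:
    """Select exactly ``n_px`` pixels closest to ``centre`` (a disk whose
    rasterised area matches the request to within one pixel)."""
    rows, cols = np.indices(shape)
    d2 = (rows - centre[0]) ** 2 + (cols - centre[1]) ** 2
    flat = np.sort(d2.ravel())
    r2 = 0.5 * (flat[n_px - 1] + flat[n_px]) if n_px < flat.size else flat[-1]
    return d2 <= r2, float(np.sqrt(r2))


def make_condensate_field(
    cfg: SynthConfig,
    n: int,
    area_um2_mean: float = 0.6,
    area_um2_sd: float = 0.0,
    amplitude: float = 100.0,
) -> tuple[ImageChannel, GroundTruth]:
    """Field of ``n`` non-overlapping disk-shaped condensates.

    Disk radii are chosen so the rasterised pixel count matches the drawn
    area to within one pixel. Placement is reject-and-retry with a 3-pixel
    clearance (so 8-connected components never merge); exhausting the
    retry budget raises :class:`PackingError`.

    GroundTruth keys: ``centres_px``, ``areas_um2`` (rasterised),
    ``requested_areas_um2``, ``field_area_um2``, ``amplitude``.
    """
    if n < 0:
        raise ParameterError("n must be >= 0")
    if area_um2_mean <= 0 or area_um2_sd < 0:
        raise ParameterError("areas must be positive")
    rng = cfg.rng()
    px_area = cfg.pixel_size_um**2
    img = np.full(cfg.shape, cfg.background_level, dtype=float)
    centres: list[tuple[float, float]] = []
    radii_px: list[float] = []
    areas: list[float] = []
    requested: list[float] = []
    occupied = np.zeros(cfg.shape, dtype=bool)
    rows, cols = cfg.shape
    for _ in range(n):
        area = max(float(rng.normal(area_um2_mean, area_um2_sd)), 4 * px_area) \
            if area_um2_sd > 0 else area_um2_mean
        n_px = max(int(round(area / px_area)), 4)
        r_px = np.sqrt(n_px / np.pi)
        margin = r_px + 2.0
        placed = False
        for _attempt in range(2000):
            c = (rng.uniform(margin, rows - margin), rng.uniform(margin, cols - margin))
            if all(np.hypot(c[0] - o[0], c[1] - o[1]) > r_px + ro + 3.0
                   for o, ro in zip(centres, radii_px)):
                disk, r_sel = _disk_pixels(cfg.shape, c, n_px)
                img[disk] += amplitude
                occupied |= disk
                centres.append(c)
                radii_px.append(r_sel)
                areas.append(float(disk.sum()) * px_area)
                requested.append(area)
                placed = True
                break
        if not placed:
            raise PackingError(f"could not place {n} non-overlapping disks")
    img = _add_noise(rng, img, cfg.noise_sd)
    truth = GroundTruth("condensate_field", {
        "centres_px": [tuple(map(float, c)) for c in centres],
        "areas_um2": areas,
        "requested_areas_um2": requested,
        "field_area_um2": rows * cols * px_area,
        "amplitude": amplitude,
    })
    return ImageChannel(img, cfg.pixel_size_um, "condensates"), truth


def make_frap_trace(
    cfg: SynthConfig,
    mobile_fraction: float = 0.8,
    tau_s: float = 3.0,
    bleach_depth: float = 0.8,
    dt_s: float = 1.0 / 11.0,
    n_frames: int = 200,
    n_prebleach: int = 11,
    noise_sd: Optional[float] = None,
) -> tuple[FRAPTrace, GroundTruth]:
    """Exponential FRAP recovery trace sampled at ``1/dt_s`` Hz (default
    11 Hz, ~1 s of pre-bleach frames).

    Pre-bleach plateau at 1; post-bleach
    F(t) = (1 − bleach_depth) + bleach_depth·M·(1 − e^(−t/τ)) + noise.

    GroundTruth keys: ``true_mobile_fraction``, ``true_tau_s``,
    ``bleach_depth``, ``dt_s``.
    """
    if not 0 <= mobile_fraction <= 1:
        raise ParameterError("mobile_fraction must be within [0, 1]")
    if tau_s <= 0 or dt_s <= 0:
        raise ParameterError("tau_s and dt_s must be positive")
    if not 0 < bleach_depth <= 1:
        raise ParameterError("bleach_depth must be in (0, 1]")
    if n_frames < n_prebleach + 5:
        raise ParameterError("n_frames too small to contain the bleach")
    rng = cfg.rng()
    sd = cfg.noise_sd if noise_sd is None else noise_sd
    times = np.arange(n_frames) * dt_s
    f = np.ones(n_frames)
    post_t = times[n_prebleach:] - times[n_prebleach]
    f[n_prebleach:] = (1.0 - bleach_depth) + bleach_depth * mobile_fraction * (
        1.0 - np.exp(-post_t / tau_s))
    f = _add_noise(rng, f, sd)
    truth = GroundTruth("frap_trace", {
        "true_mobile_fraction": mobile_fraction,
        "true_tau_s": tau_s,
        "bleach_depth": bleach_depth,
        "dt_s": dt_s,
    })
    return FRAPTrace(times_s=times, intensities=f, bleach_index=n_prebleach), truth


def lipid_band_preset(phase: str, include_protein: bool = False) -> list[Band]:
    """Band list for a lipid membrane spectrum.

    ``liquid``: C=O at 1730 cm⁻¹; ``gel``: C=O shifted up by 8 cm⁻¹
    (1738 cm⁻¹); both 20 cm⁻¹ wide, plus a CH₂ scissoring band in the
    1450–1475 cm⁻¹ region. ``include_protein`` adds amide-I bands.
    """
    if phase not in ("liquid", "gel"):
        raise ParameterError("phase must be 'liquid' or 'gel'")
    centre = CO_LIQUID_CM1 + (CO_GEL_SHIFT_CM1 if phase == "gel" else 0.0)
    bands = [
        Band(centre, CO_WIDTH_CM1, 1.0, "lorentzian"),
        Band(1462.0, 18.0, 0.5, "lorentzian"),
    ]
    if include_protein:
        bands += amide_band_preset(0.10)[0]
    return bands


def amide_band_preset(
    intermolecular_beta_fraction: float = 0.10,
) -> tuple[list[Band], dict[str, float]]:
    """Amide-I band set with a configurable true intermolecular β-sheet
    area fraction; the remaining structure classes share the rest in a
    fixed proportion (β-sheet 15 : coil 30 : α-helix 30 : turns 15).

    Returns the band list (Gaussian bands centred inside the default
    sub-band windows) and the true area-fraction dict.
    """
    f = intermolecular_beta_fraction
    if not 0 <= f < 1:
        raise ParameterError("fraction must be within [0, 1)")
    rest = {"beta_sheet": 0.15, "random_coil": 0.30, "alpha_helix": 0.30, "turns": 0.15}
    scale = (1.0 - f) / sum(rest.values())
    fractions = {"intermolecular_beta": f}
    fractions.update({k: v * scale for k, v in rest.items()})
    centres = {"intermolecular_beta": 1620.0, "beta_sheet": 1637.0,
               "random_coil": 1648.5, "alpha_helix": 1657.0, "turns": 1674.0}
    widths = {"intermolecular_beta": 14.0, "beta_sheet": 12.0,
              "random_coil": 7.0, "alpha_helix": 9.0, "turns": 16.0}
    bands = []
    for name, frac in fractions.items():
        sigma = widths[name] / 2.354820045
        amp = frac / (sigma * np.sqrt(2.0 * np.pi))  # unit total area
        bands.append(Band(centres[name], widths[name], amp, "gaussian"))
    return bands, fractions


def _render_bands(grid: np.ndarray, bands: Sequence[Band]) -> np.ndarray:
    y = np.zeros_like(grid)
    for band in bands:
        if band.shape == "lorentzian":
            half = band.fwhm_cm1 / 2.0
            y += band.amplitude * half**2 / ((grid - band.centre_cm1) ** 2 + half**2)
        elif band.shape == "gaussian":
            sigma = band.fwhm_cm1 / 2.354820045
            y += band.amplitude * np.exp(-0.5 * ((grid - band.centre_cm1) / sigma) ** 2)
        else:
            raise ParameterError(f"unknown band shape {band.shape!r}")
    return y


def make_spectrum(
    cfg: SynthConfig,
    phase: Optional[str] = None,
    bands: Optional[Sequence[Band]] = None,
    include_protein: bool = False,
    grid_cm1: tuple[float, float, float] = (1400.0, 1794.0, 2.0),
    instrument: str = "afmir",
    noise_sd: Optional[float] = None,
) -> tuple[Spectrum, GroundTruth]:
    """Synthesize an IR spectrum as a sum of Lorentzian/Gaussian bands.

    Either a ``phase`` preset (``liquid``/``gel``, optionally with amide-I
    protein bands) or an explicit ``bands`` list must be given. The grid
    is uniform ascending (default 1400–1794 cm⁻¹ at 2 cm⁻¹ steps, the
    nanospectroscopy sampling).

    GroundTruth keys: ``true_peak_cm1`` (C=O centre, when a lipid C=O
    band is present), ``true_width_cm1``, ``phase``, ``bands``.
    """
    if (phase is None) == (bands is None):
        raise ParameterError("give exactly one of phase= or bands=")
    lo, hi, step = grid_cm1
    if step > 2.0 or step <= 0:
        raise ParameterError("grid step must be positive and <= 2 cm^-1")
    if lo > 1400.0 or hi < 1794.0:
        raise ParameterError("grid must cover at least 1400-1794 cm^-1")
    grid = np.arange(lo, hi + step / 2, step)
    if bands is None:
        bands = lipid_band_preset(phase, include_protein)
    bands = [Band(*b) for b in bands]
    for band in bands:
        if not lo <= band.centre_cm1 <= hi:
            raise ParameterError(f"band at {band.centre_cm1} cm^-1 outside the grid")
    y = _render_bands(grid, bands)
    rng = cfg.rng()
    sd = cfg.noise_sd if noise_sd is None else noise_sd
    y = _add_noise(rng, y, sd)
    co = [b for b in bands if 1700.0 <= b.centre_cm1 <= 1760.0]
    truth = GroundTruth("spectrum", {
        "phase": phase,
        "bands": [tuple(b) for b in bands],
        "true_peak_cm1": co[0].centre_cm1 if co else None,
        "true_width_cm1": co[0].fwhm_cm1 if co else None,
    })
    return Spectrum(grid, y, instrument=instrument), truth


def make_amide_spectrum(
    cfg: SynthConfig,
    intermolecular_beta_fraction: float = 0.10,
    instrument: str = "ftir",
    noise_sd: Optional[float] = None,
) -> tuple[Spectrum, GroundTruth]:
    """Amide-I-only spectrum with a known true intermolecular β-sheet
    fraction (dispersed preset ≈ 0.10; a condensed preset raises it).

    GroundTruth keys: ``true_fractions`` (per sub-band).
    """
    bands, fractions = amide_band_preset(intermolecular_beta_fraction)
    spec, truth = make_spectrum(cfg, bands=bands, instrument=instrument,
                                noise_sd=noise_sd)
    truth.data["true_fractions"] = fractions
    truth.data["generator"] = "amide_spectrum"
    return spec, truth


def make_deformation_series(
    cfg: SynthConfig,
    e_rel: float = 1.0,
    pressures_Pa: Optional[Sequence[float]] = None,
    direction: str = "forth",
    condition: str = "",
    noise_sd: Optional[float] = None,
) -> tuple[DeformationSeries, GroundTruth]:
    """Linear-elastic strain–pressure series:
    strain = P / (K_REF_PA · E_rel) + noise, over the 100–1000 Pa range.

    GroundTruth keys: ``true_E_rel``, ``k_ref_Pa``, ``true_slope``.
    """
    if e_rel <= 0:
        raise ParameterError("e_rel must be positive")
    if pressures_Pa is None:
        pressures_Pa = np.linspace(*PRESSURE_RANGE_PA, 10)
    pressures = np.asarray(pressures_Pa, dtype=float)
    if np.any(pressures < PRESSURE_RANGE_PA[0]) or np.any(pressures > PRESSURE_RANGE_PA[1]):
        raise ParameterError("pressures must lie within 100-1000 Pa")
    rng = cfg.rng()
    sd = cfg.noise_sd if noise_sd is None else noise_sd
    strain = pressures / (K_REF_PA * e_rel)
    strain = _add_noise(rng, strain, sd)
    truth = GroundTruth("deformation_series", {
        "true_E_rel": e_rel,
        "k_ref_Pa": K_REF_PA,
        "true_slope": 1.0 / (K_REF_PA * e_rel),
    })
    return DeformationSeries(pressures, strain, direction=direction,
                             condition=condition), truth


def make_diffusion_profiles(
    cfg: SynthConfig,
    rh_nm: float = SUV_RH_NM,
    geometry: Optional[ChannelGeometry] = None,
    conditions: Optional[Conditions] = None,
    noise_sd: Optional[float] = None,
) -> tuple[DiffusionProfileSet, GroundTruth]:
    """Noisy lateral spreading profiles for a species of radius ``rh_nm``
    (must be within the 0.1–50 nm sizing grid).

    GroundTruth keys: ``true_Rh_nm``.
    """
    if not RH_GRID_NM[0] <= rh_nm <= RH_GRID_NM[1]:
        raise ParameterError(f"rh_nm must be within {RH_GRID_NM} nm")
    ideal = simulate_profiles(rh_nm, geometry, conditions)
    rng = cfg.rng()
    sd = cfg.noise_sd if noise_sd is None else noise_sd
    noisy = _add_noise(rng, ideal.profiles.copy(), sd)
    out = DiffusionProfileSet(x_um=ideal.x_um, profiles=noisy,
                              geometry=ideal.geometry, conditions=ideal.conditions)
    return out, GroundTruth("diffusion_profiles", {"true_Rh_nm": rh_nm})


def make_dose_response(
    cfg: SynthConfig,
    preset: Optional[str] = None,
    ec50_uM: float = 2.0,
    hill: float = 1.5,
    bottom: float = 0.0,
    top: float = 1.0,
    concentrations_uM: Optional[Sequence[float]] = None,
    noise_sd: Optional[float] = None,
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Logistic binding data over a log-spaced dose range up to ~30 µM.

    Presets: ``"ard"`` — lipid-site binding that plateaus well inside the
    tested range (EC50 2 µM, Hill 1.5); ``"fl"`` — collective binding
    still rising at the top dose (EC50 15 µM, Hill 1).

    GroundTruth keys: ``true_ec50_uM``, ``true_hill``, ``bottom``,
    ``top``, ``preset``.
    """
    if preset == "ard":
        ec50_uM, hill = 2.0, 1.5
    elif preset == "fl":
        ec50_uM, hill = 15.0, 1.0
    elif preset is not None:
        raise ParameterError("preset must be 'ard' or 'fl'")
    if ec50_uM <= 0:
        raise ParameterError("ec50 must be positive")
    conc = np.asarray(concentrations_uM, dtype=float) if concentrations_uM is not None \
        else np.geomspace(0.05, 30.0, 10)
    if np.any(conc <= 0):
        raise ParameterError("concentrations must be positive")
    resp = logistic4(conc, bottom, top, np.log10(ec50_uM), hill)
    rng = cfg.rng()
    sd = cfg.noise_sd if noise_sd is None else noise_sd
    resp = _add_noise(rng, resp, sd)
    truth = GroundTruth("dose_response", {
        "true_ec50_uM": ec50_uM, "true_hill": hill,
        "bottom": bottom, "top": top, "preset": preset,
    })
    return conc, resp, truth
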