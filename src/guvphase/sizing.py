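"""Microfluidic diffusional sizing: forward model and R_H fitting.

A sample stream is co-flowed with buffer down a laminar-flow channel and
imaged at four positions of increasing path length. Lateral diffusion
broadens the stream; the broadening at each position, compared against a
forward model evaluated over a grid of hydrodynamic radii, yields the
average R_H of the diffusing species via the Stokes–Einstein relation
D = k_B·T / (6π·η·R_H).

The forward model treats transport with a plug-flow residence-time
approximation: the residence time at observation position i is
t_i = path_length_i × cross-section / volumetric flow, and lateral
diffusion across the channel width obeys the 1-D diffusion equation with
no-flux walls, solved by a cosine eigenfunction expansion from a top-hat
initial condition over the sample-stream fraction of the width.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize

from .errors import ParameterError, UnidentifiableError

__all__ = [
    "BOLTZMANN_J_K",
    "ChannelGeometry",
    "Conditions",
    "DiffusionProfileSet",
    "SizingResult",
    "stokes_einstein_d",
    "stokes_einstein_rh",
    "simulate_profiles",
    "fit_rh",
    "RH_GRID_NM",
]

BOLTZMANN_J_K = 1.380649e-23

#: Radius grid bounds for the fit (nm).
RH_GRID_NM = (0.1, 50.0)


@dataclass
class ChannelGeometry:
    """Sizing-chip geometry. Defaults are a typical four-window design;
    the observation positions are path lengths along the channel from the
    co-flow junction."""

    width_um: float = 300.0
    height_um: float = 25.0
    observation_path_lengths_um: tuple[float, ...] = (5300.0, 19900.0, 57300.0, 81800.0)
    sample_stream_fraction: float = 0.25

    def __post_init__(self) -> None:
        if self.width_um <= 0 or self.height_um <= 0:
            raise ParameterError("channel dimensions must be positive")
        if not 25.0 <= self.height_um <= 50.0:
            raise ParameterError("channel height must be within 25-50 um")
        lengths = tuple(float(v) for v in self.observation_path_lengths_um)
        if len(lengths) != 4 or np.any(np.diff(lengths) <= 0):
            raise ParameterError("need 4 strictly increasing path lengths")
        self.observation_path_lengths_um = lengths
        if not 0 < self.sample_stream_fraction < 1:
            raise ParameterError("sample_stream_fraction must be in (0, 1)")


@dataclass
class Conditions:
    temperature_K: float = 298.15
    viscosity_Pa_s: float = 8.9e-4
    flow_uL_h: float = 60.0

    def __post_init__(self) -> None:
        if min(self.temperature_K, self.viscosity_Pa_s, self.flow_uL_h) <= 0:
            raise ParameterError("conditions must be positive")
        if not 20.0 <= self.flow_uL_h <= 150.0:
            raise ParameterError("flow must be within 20-150 uL/h")


@dataclass
class DiffusionProfileSet:
    """Normalised lateral intensity profiles at the four observation
    positions, on a common coordinate grid across the channel width.
    Each profile conserves the initial mass (within 1e-3 relative)."""

    x_um: np.ndarray
    profiles: np.ndarray  # shape (4, n_x)
    geometry: ChannelGeometry
    conditions: Conditions

    def __post_init__(self) -> None:
        self.x_um = np.asarray(self.x_um, dtype=float)
        self.profiles = np.asarray(self.profiles, dtype=float)
        if self.profiles.ndim != 2 or self.profiles.shape[0] != 4:
            raise ParameterError("profiles must have shape (4, n_x)")
        if self.profiles.shape[1] != len(self.x_um):
            raise ParameterError("profile length does not match the grid")


@dataclass
class SizingResult:
    rh_nm: float
    diffusion_coefficient_m2_s: float
    residual: float
    rh_grid_nm: np.ndarray


def stokes_einstein_d(rh_nm: float, conditions: Conditions) -> float:
    """Diffusion coefficient (m²/s) from R_H via D = k_BT/(6πηR_H)."""
    if rh_nm <= 0:
        raise ParameterError("rh_nm must be positive")
    return BOLTZMANN_J_K * conditions.temperature_K / (
        6.0 * np.pi * conditions.viscosity_Pa_s * rh_nm * 1e-9)


def stokes_einstein_rh(d_m2_s: float, conditions: Conditions) -> float:
    """Hydrodynamic radius (nm) from a diffusion coefficient; exact
    inverse of :func:`stokes_einstein_d`."""
    if d_m2_s <= 0:
        raise ParameterError("diffusion coefficient must be positive")
    return BOLTZMANN_J_K * conditions.temperature_K / (
        6.0 * np.pi * conditions.viscosity_Pa_s * d_m2_s) * 1e9


def residence_times_s(geometry: ChannelGeometry, conditions: Conditions) -> np.ndarray:
    """Plug-flow residence time at each observation position:
    t_i = L_i × (width × height) / Q."""
    area_m2 = geometry.width_um * 1e-6 * geometry.height_um * 1e-6
    q_m3_s = conditions.flow_uL_h * 1e-9 / 3600.0
    lengths_m = np.asarray(geometry.observation_path_lengths_um) * 1e-6
    return lengths_m * area_m2 / q_m3_s


def _cosine_profile(x_um: np.ndarray, width_um: float, frac: float,
                    d_m2_s: float, t_s: float, n_modes: int = 4000) -> np.ndarray:
    """Concentration profile of a top-hat over [0, frac·W] after time t,
    no-flux walls, by cosine eigenfunction expansion. t = 0 returns the
    exact top-hat (the truncated series would Gibbs-oscillate)."""
    w_m = width_um * 1e-6
    x_m = x_um * 1e-6
    if t_s == 0:
        return (x_um <= frac * width_um + 1e-12).astype(float)
    n = np.arange(1, n_modes + 1)
    lam = n * np.pi / w_m
    decay = np.exp(-d_m2_s * lam**2 * t_s)
    # drop modes that no longer contribute
    keep = decay > 1e-18
    n, lam, decay = n[keep], lam[keep], decay[keep]
    coeff = (2.0 / (n * np.pi)) * np.sin(n * np.pi * frac) * decay
    return frac + coeff @ np.cos(np.outer(lam, x_m))


def simulate_profiles(
    rh_nm: float,
    geometry: Optional[ChannelGeometry] = None,
    conditions: Optional[Conditions] = None,
    n_x: int = 256,
) -> DiffusionProfileSet:
    """Simulate the four lateral diffusion profiles for a species of
    hydrodynamic radius ``rh_nm`` (must lie within the 0.1–50 nm grid)."""
    geometry = geometry or ChannelGeometry()
    conditions = conditions or Conditions()
    if not RH_GRID_NM[0] <= rh_nm <= RH_GRID_NM[1]:
        raise ParameterError(f"rh_nm must be within {RH_GRID_NM} nm")
    d = stokes_einstein_d(rh_nm, conditions)
    times = residence_times_s(geometry, conditions)
    x_um = (np.arange(n_x) + 0.5) * geometry.width_um / n_x
    profiles = np.stack([
        _cosine_profile(x_um, geometry.width_um, geometry.sample_stream_fraction, d, t)
        for t in times
    ])
    return DiffusionProfileSet(x_um=x_um, profiles=profiles,
                               geometry=geometry, conditions=conditions)


def _misfit(observed: DiffusionProfileSet, rh_nm: float) -> float:
    """Summed squared mismatch across the 4 positions, with a free linear
    amplitude per profile (nuisance scale from background/exposure)."""
    model = simulate_profiles(rh_nm, observed.geometry, observed.conditions,
                              n_x=len(observed.x_um))
    total = 0.0
    for obs, mod in zip(observed.profiles, model.profiles):
        denom = float(mod @ mod)
        alpha = float(obs @ mod) / denom if denom > 0 else 0.0
        resid = obs - alpha * mod
        total += float(resid @ resid)
    return total


def fit_rh(observed: DiffusionProfileSet, grid_n: int = 200) -> SizingResult:
    """Fit R_H by grid search over a log-spaced 0.1–50 nm radius grid
    followed by golden-section refinement between the best grid
    neighbours (absolute tolerance 0.01 nm).

    Raises :class:`UnidentifiableError` for flat observed profiles.
    """
    spreads = observed.profiles.std(axis=1)
    scale = np.abs(observed.profiles).max()
    if scale == 0 or np.all(spreads < 1e-9 * max(scale, 1.0)):
        raise UnidentifiableError("flat observed profiles carry no sizing signal")
    grid = np.geomspace(RH_GRID_NM[0], RH_GRID_NM[1], grid_n)
    losses = np.array([_misfit(observed, r) for r in grid])
    best = int(np.argmin(losses))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, grid_n - 1)]
    func = lambda r: _misfit(observed, float(r))  # noqa: E731
    rh, residual = float(grid[best]), float(losses[best])
    if 0 < best < grid_n - 1:
        # golden-section refinement between the best grid neighbours
        xmin = float(optimize.golden(func, brack=(lo, grid[best], hi),
                                     tol=0.01 / grid[best]))
        xmin = float(np.clip(xmin, lo, hi))
        if func(xmin) <= residual:
            rh, residual = xmin, func(xmin)
    elif hi > lo:
        res = optimize.minimize_scalar(func, bounds=(lo, hi), method="bounded",
                                       options={"xatol": 0.01})
        rh, residual = float(res.x), float(res.fun)
    return SizingResult(
        rh_nm=rh,
        diffusion_coefficient_m2_s=stokes_einstein_d(rh, observed.conditions),
        residual=residual,
        rh_grid_nm=grid,
    )
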