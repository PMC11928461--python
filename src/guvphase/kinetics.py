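"""FRAP recovery and log-dose binding-response fitting.

FRAP traces are normalised to F(t) = (I(t) − I_bleach)/(I_pre − I_bleach)
with I_pre the pre-bleach mean and I_bleach the first post-bleach frame,
then fitted with a single-exponential recovery
F(t) = M·(1 − exp(−t/τ)) on the post-bleach frames, giving the mobile
fraction M and time constant τ. Percent recovery at a fixed time (e.g.
5 s or 15 s post-bleach) is the comparison readout across conditions.

Binding of a protein to GUV membranes as a function of concentration is
fitted with a 4-parameter logistic in log₁₀(concentration); a saturation
call distinguishes simple lipid-site binding (plateaus within the tested
range) from collective condensation-driven binding (still rising at the
highest dose).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize

from .errors import FitFailureError, NoBleachError, ParameterError

__all__ = [
    "FRAPTrace",
    "RecoveryFit",
    "DoseResponse",
    "normalize_trace",
    "fit_recovery",
    "percent_recovery_at",
    "fit_dose_response",
    "logistic4",
]


@dataclass
class FRAPTrace:
    """A FRAP time series: intensities sampled at ``times_s`` with the
    first post-bleach frame at index ``bleach_index``."""

    times_s: np.ndarray
    intensities: np.ndarray
    bleach_index: int

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times_s.shape != self.intensities.shape:
            raise ParameterError("times and intensities lengths differ")
        if not (0 < self.bleach_index < len(self.times_s)):
            raise ParameterError("bleach_index must be inside the trace")
        if np.any(np.diff(self.times_s) <= 0):
            raise ParameterError("times must be strictly ascending")


@dataclass
class RecoveryFit:
    """Single-exponential FRAP recovery fit: F(t) = M(1 − e^(−t/τ))."""

    mobile_fraction: float
    tau_s: float
    plateau: float
    rss: float


@dataclass
class DoseResponse:
    """4-parameter logistic fit of response vs log₁₀(concentration)."""

    concentrations_uM: np.ndarray
    responses: np.ndarray
    bottom: float
    top: float
    ec50_uM: float
    hill: float
    saturated: bool
    saturation_conc_uM: Optional[float] = None
    degenerate: bool = False


def normalize_trace(trace: FRAPTrace) -> FRAPTrace:
    """Normalise a raw FRAP trace to the [bleach → pre-bleach] scale.

    F(t) = (I(t) − I_bleach)/(I_pre − I_bleach) where I_pre is the mean of
    the pre-bleach frames and I_bleach the first post-bleach frame, so
    F(bleach) = 0 and full recovery corresponds to F = 1. The convention is
    invariant to affine rescaling of the raw intensities.

    Raises :class:`NoBleachError` when I_pre = I_bleach (flat trace).
    """
    if trace.bleach_index < 3:
        raise ParameterError("need at least 3 pre-bleach frames")
    i_pre = float(trace.intensities[: trace.bleach_index].mean())
    i_bleach = float(trace.intensities[trace.bleach_index])
    if i_pre == i_bleach:
        raise NoBleachError("no intensity drop at the bleach frame")
    norm = (trace.intensities - i_bleach) / (i_pre - i_bleach)
    return FRAPTrace(times_s=trace.times_s.copy(), intensities=norm,
                     bleach_index=trace.bleach_index)


def _recovery_model(t: np.ndarray, m: float, tau: float) -> np.ndarray:
    return m * (1.0 - np.exp(-t / tau))


def fit_recovery(norm: FRAPTrace) -> RecoveryFit:
    """Least-squares fit of F(t) = M(1 − e^(−t/τ)) to the post-bleach
    frames of a normalised trace, with t re-zeroed at the bleach frame.

    M is constrained to [0, 1] and τ > 0. Raises :class:`FitFailureError`
    with residual diagnostics on non-convergence.
    """
    post_t = norm.times_s[norm.bleach_index:] - norm.times_s[norm.bleach_index]
    post_f = norm.intensities[norm.bleach_index:]
    if len(post_t) < 5:
        raise ParameterError("need at least 5 post-bleach frames")
    span = max(post_t[-1], 1e-9)
    m0 = float(np.clip(post_f[-1], 1e-3, 1.0))
    tau0 = span / 3.0
    try:
        popt, _ = optimize.curve_fit(
            _recovery_model, post_t, post_f, p0=(m0, tau0),
            bounds=([0.0, 1e-12], [1.0, np.inf]), maxfev=20000,
        )
    except RuntimeError as exc:  # pragma: no cover - scipy failure path
        rss = float(np.sum(post_f**2))
        raise FitFailureError(f"recovery fit failed (rss against zero model = {rss:.3g})") from exc
    m, tau = float(popt[0]), float(popt[1])
    resid = post_f - _recovery_model(post_t, m, tau)
    return RecoveryFit(mobile_fraction=m, tau_s=tau, plateau=m, rss=float(resid @ resid))


def percent_recovery_at(fit: RecoveryFit, t_s: float) -> float:
    """Percent fluorescence recovery at ``t_s`` seconds post-bleach:
    100·M·(1 − e^(−t/τ)). Strictly increasing in t and bounded by 100·M."""
    if t_s < 0:
        raise ParameterError("t_s must be non-negative")
    return 100.0 * fit.mobile_fraction * (1.0 - math.exp(-t_s / fit.tau_s))


def logistic4(conc: np.ndarray, bottom: float, top: float,
              log_ec50: float, hill: float) -> np.ndarray:
    """4-parameter logistic response at concentration ``conc`` (same units
    as 10**log_ec50)."""
    logc = np.log10(conc)
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((log_ec50 - logc) * hill))


def fit_dose_response(
    concentrations_uM: Sequence[float],
    responses: Sequence[float],
    saturation_band: float = 0.05,
    top_ci_fraction: float = 0.20,
) -> DoseResponse:
    """Fit a 4-parameter logistic to binding data in log₁₀(dose).

    Saturation is called when (a) the fitted curve at the highest tested
    concentration lies within ``saturation_band`` (default 5%) of the
    fitted plateau ``top`` and (b) the 95% confidence half-width of ``top``
    is below ``top_ci_fraction`` of its value — i.e. the plateau is both
    reached and well determined inside the tested range.
    ``saturation_conc_uM`` is the smallest tested concentration whose
    fitted response is within the band of ``top``.

    A degenerate fit (e.g. constant response) is returned flagged
    ``degenerate=True`` with ``saturated=False`` rather than raised.
    """
    conc = np.asarray(concentrations_uM, dtype=float)
    resp = np.asarray(responses, dtype=float)
    if conc.shape != resp.shape:
        raise ParameterError("concentration and response lengths differ")
    if len(np.unique(conc)) < 5:
        raise ParameterError("need at least 5 distinct concentrations")
    if np.any(conc <= 0):
        raise ParameterError("concentrations must be positive")

    span = float(resp.max() - resp.min())
    if span == 0:
        return DoseResponse(conc, resp, bottom=float(resp[0]), top=float(resp[0]),
                            ec50_uM=float(np.median(conc)), hill=1.0,
                            saturated=False, degenerate=True)
    p0 = (float(resp.min()), float(resp.max()), float(np.log10(np.median(conc))), 1.0)
    try:
        popt, pcov = optimize.curve_fit(
            logistic4, conc, resp, p0=p0, maxfev=50000,
            bounds=([-np.inf, -np.inf, np.log10(conc.min()) - 3, 0.05],
                    [np.inf, np.inf, np.log10(conc.max()) + 3, 20.0]),
        )
    except RuntimeError:
        return DoseResponse(conc, resp, bottom=p0[0], top=p0[1],
                            ec50_uM=10.0 ** p0[2], hill=p0[3],
                            saturated=False, degenerate=True)
    bottom, top, log_ec50, hill = (float(v) for v in popt)
    top_se = float(np.sqrt(max(pcov[1, 1], 0.0))) if np.all(np.isfinite(pcov)) else np.inf
    top_halfwidth = 1.96 * top_se

    cmax = float(conc.max())
    resp_at_max = float(logistic4(np.array([cmax]), bottom, top, log_ec50, hill)[0])
    amplitude = abs(top - bottom)
    reached = amplitude > 0 and abs(top - resp_at_max) <= saturation_band * amplitude
    well_determined = math.isfinite(top_halfwidth) and top != 0 and \
        top_halfwidth < top_ci_fraction * abs(top)
    saturated = bool(reached and well_determined)

    saturation_conc = None
    if saturated:
        fitted = logistic4(conc, bottom, top, log_ec50, hill)
        within = np.abs(top - fitted) <= saturation_band * amplitude
        if within.any():
            saturation_conc = float(conc[within].min())
    return DoseResponse(conc, resp, bottom=bottom, top=top, ec50_uM=10.0 ** log_ec50,
                        hill=hill, saturated=saturated, saturation_conc_uM=saturation_conc)
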