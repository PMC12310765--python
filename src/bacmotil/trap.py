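"""Optical-trap calibration and low-Reynolds-number force budget.

A trapped bacterium behaves as an overdamped harmonic oscillator, so its
position fluctuations obey Boltzmann statistics,

    P(ζ) = N·exp(−κ ζ² / 2 k_B T),     ζ ∈ {x, y},

and the stiffness follows from equipartition, κ = k_B T/σ².  Axial (x) and
transverse (y) axes are calibrated separately.  The normalized trapping
efficiency κ̃ (pN/µm/W) is the slope of κ versus laser power.  The swimming
force budget models the cell as a rigid prolate spheroid with Stokes drag
γ0 = 4πηb/[ln(2b/a) − 1/2] and propulsion force F = γ0·v, balanced against
the optical restoring force F = κ·Δx.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .synth import KT_ROOM

__all__ = [
    "KT_ROOM", "ETA_WATER",
    "PositionDistribution", "StiffnessEstimate", "EfficiencySeries",
    "EfficiencyFit", "ChainMember",
    "estimate_stiffness", "position_distribution", "normalized_efficiency",
    "stiffness_at_power", "chain_stiffness_profile",
    "stokes_drag", "propulsion_force", "trap_displacement",
]

#: dynamic viscosity of water near room temperature, Pa·s
ETA_WATER = 1.0e-3


@dataclass
class PositionDistribution:
    """Normalized position histogram of one axis of a trapped cell."""

    axis: str
    samples: np.ndarray          # µm, mean-removed
    sigma: float                 # µm
    bin_centers: np.ndarray
    density: np.ndarray


@dataclass
class StiffnessEstimate:
    kappa: float                 # pN/µm
    sigma: float                 # µm
    kT: float                    # J
    method: str                  # 'variance' | 'histogram_fit'
    axis: str | None = None


@dataclass
class EfficiencySeries:
    powers_mw: np.ndarray        # laser power, mW
    kappas: np.ndarray           # pN/µm
    axis: str = "x"


@dataclass
class EfficiencyFit:
    kappa_tilde: float           # pN/µm/W, through-origin slope
    saturated: bool
    plateau_kappa: float | None  # pN/µm, mean of saturated points
    used_powers_mw: np.ndarray


@dataclass
class ChainMember:
    """Position samples of one bacterium in an optically bound chain."""

    axial_position: float        # µm along the beam
    x_samples: np.ndarray        # µm
    y_samples: np.ndarray        # µm
    chained: bool = True         # False for the isolated/loose-end cell


def _kappa_from_sigma(sigma_um: float, kT: float) -> float:
    # κ = kT/σ²; J/µm² → pN/µm carries a factor 1e18
    return kT * 1e18 / sigma_um ** 2


def position_distribution(samples, axis: str = "x",
                          bins="fd") -> PositionDistribution:
    """Mean-removed position histogram (Freedman–Diaconis bins, density-normalized)."""
    samples = np.asarray(samples, dtype=float)
    samples = samples - samples.mean()
    density, edges = np.histogram(samples, bins=bins, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return PositionDistribution(axis=axis, samples=samples,
                                sigma=float(samples.std(ddof=1)),
                                bin_centers=centers, density=density)


def estimate_stiffness(samples, kT: float = KT_ROOM,
                       method: str = "variance",
                       axis: str | None = None) -> StiffnessEstimate:
    """Trap stiffness of one axis from position samples (µm).

    ``variance``: κ = kT/σ² with σ the sample standard deviation.
    ``histogram_fit``: least-squares Gaussian fit of the normalized position
    histogram, then κ from the fitted width.  Samples are detrended (mean
    removed) first; κ is returned in pN/µm.
    """
    samples = np.asarray(samples, dtype=float)
    samples = samples - samples.mean()
    if np.allclose(samples, 0.0):
        raise ValueError("zero position variance: stiffness undefined")
    if method == "variance":
        sigma = float(samples.std(ddof=1))
    elif method == "histogram_fit":
        dist = position_distribution(samples, axis=axis or "x")

        def gauss(z, amp, sig):
            return amp * np.exp(-z ** 2 / (2 * sig ** 2))

        p0 = [dist.density.max(), max(dist.sigma, 1e-9)]
        popt, _ = curve_fit(gauss, dist.bin_centers, dist.density, p0=p0,
                            bounds=([0, 1e-12], [np.inf, np.inf]), maxfev=10000)
        sigma = float(popt[1])
    else:
        raise ValueError(f"unknown method {method!r}")
    return StiffnessEstimate(kappa=_kappa_from_sigma(sigma, kT), sigma=sigma,
                             kT=kT, method=method, axis=axis)


def normalized_efficiency(series: EfficiencySeries,
                          power_cutoff_mw: float | None = None,
                          saturation_tol: float = 0.2) -> EfficiencyFit:
    """Normalized trapping efficiency κ̃: slope of κ versus power through the origin.

    Points above ``power_cutoff_mw``, or detected as a saturation plateau
    (upper points falling ``saturation_tol`` below the low-power linear
    trend), are flagged and excluded from the regression; the mean κ of the
    flagged points is reported as the plateau value.
    """
    p_mw = np.asarray(series.powers_mw, dtype=float)
    k = np.asarray(series.kappas, dtype=float)
    if len(np.unique(p_mw)) < 2:
        raise ValueError("need at least two distinct powers for a regression")
    order = np.argsort(p_mw)
    p_mw, k = p_mw[order], k[order]

    excluded = np.zeros(len(p_mw), dtype=bool)
    if power_cutoff_mw is not None:
        excluded |= p_mw > power_cutoff_mw
    else:
        # plateau heuristic: slope from the lower half predicts the rest
        half = max(2, len(p_mw) // 2)
        p_lo, k_lo = p_mw[:half], k[:half]
        slope_lo = float((p_lo * k_lo).sum() / (p_lo * p_lo).sum())
        pred = slope_lo * p_mw
        excluded |= (pred - k) > saturation_tol * np.maximum(pred, 1e-300)
    if excluded.all():
        excluded = np.zeros(len(p_mw), dtype=bool)

    p_fit = p_mw[~excluded] * 1e-3       # mW → W
    k_fit = k[~excluded]
    slope = float((p_fit * k_fit).sum() / (p_fit * p_fit).sum())
    saturated = bool(excluded.any())
    plateau = float(k[excluded].mean()) if saturated else None
    return EfficiencyFit(kappa_tilde=slope, saturated=saturated,
                         plateau_kappa=plateau, used_powers_mw=p_mw[~excluded])


def stiffness_at_power(kappa_tilde: float, power_mw: float) -> float:
    """κ (pN/µm) predicted at a laser power (mW) from κ̃ (pN/µm/W)."""
    return kappa_tilde * power_mw * 1e-3


def chain_stiffness_profile(members: list[ChainMember],
                            kT: float = KT_ROOM,
                            method: str = "variance") -> list[dict]:
    """Effective stiffness κ̂ along an optically bound bacteria chain.

    Applies the equipartition estimator per member and axis; for chained
    members the harmonic approximation is only indicative (mechanical contact
    violates it), which the ``harmonic_valid`` flag records.
    """
    out = []
    for m in sorted(members, key=lambda m: m.axial_position):
        ex = estimate_stiffness(m.x_samples, kT=kT, method=method, axis="x")
        ey = estimate_stiffness(m.y_samples, kT=kT, method=method, axis="y")
        out.append({
            "axial_position": m.axial_position,
            "kappa_x": ex.kappa, "sigma_x": ex.sigma,
            "kappa_y": ey.kappa, "sigma_y": ey.sigma,
            "harmonic_valid": not m.chained,
        })
    return out


# --------------------------------------------------------------------------
# Stokes-drag force budget
# --------------------------------------------------------------------------

def stokes_drag(a: float, b: float, eta: float = ETA_WATER) -> float:
    """Stokes drag γ0 (Ns/m) of a prolate spheroid moving along its long axis.

    γ0 = 4πη·b / [ln(2b/a) − 1/2] with minor/major semi-axes a < b in µm and
    dynamic viscosity η in Pa·s.
    """
    if not (0 < a < b):
        raise ValueError("require 0 < a < b (minor < major semi-axis)")
    if eta <= 0:
        raise ValueError("viscosity must be positive")
    denom = np.log(2 * b / a) - 0.5
    if denom <= 0:
        raise ValueError("ln(2b/a) must exceed 1/2 for this drag formula")
    return float(4 * np.pi * eta * (b * 1e-6) / denom)


def propulsion_force(v: float, gamma0: float) -> float:
    """Flagellar propulsion force F = γ0·v in pN, for v in µm/s and γ0 in Ns/m."""
    if v < 0:
        raise ValueError("speed must be >= 0")
    return float(gamma0 * v * 1e-6 * 1e12)


def trap_displacement(force_pn: float, kappa: float) -> float:
    """Position shift Δx = F/κ (µm) of a trapped cell under a force (pN)."""
    if kappa <= 0:
        raise ValueError("stiffness must be positive")
    return float(force_pn / kappa)
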