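"""Trajectory statistics and motility classification.

Implements the feature chain used to separate motile from passive bacteria:

* time-averaged mean square displacement and its power-law fit
  ``MSD(τ) = 2dK·τ^α`` (d = 2), giving the scaling exponent α and the
  generalized diffusion coefficient K (reported unitless by convention);
* windowed mean speed vectors ``v_j = (r_{j+n} − r_j)/(n Δt)``;
* the speed autocorrelation ``C(ξ)`` on the rescaled lag ξ = k/n, compared
  with the closed-form fractional-Brownian-motion prediction
  ``C^FBM(ξ) = {(ξ+1)^αc + |ξ−1|^αc − 2ξ^αc}/2``;
* reversal detection and a rule-based classifier into
  floating / running / rwr (run–wrap–reverse) / trapped.

Motile trajectories are identified by C(ξ=1) ≡ C₁ > 0.45 together with
α_c > 1.52; these thresholds separate the motile and passive populations in
the C₁–α_c plane.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .trajectory import Trajectory

__all__ = [
    "MSDCurve", "MSDFit", "SpeedSeries", "AutocorrCurve", "AutocorrFit",
    "MotilityClass", "Thresholds",
    "msd", "fit_msd_power_law", "mean_speed_series", "speed_autocorrelation",
    "fbm_autocorrelation", "fit_fbm_autocorr", "detect_reversals",
    "compute_features", "decide_label", "classify", "fit_double_gaussian",
]


@dataclass
class MSDCurve:
    tau: np.ndarray      # s
    msd: np.ndarray      # µm²


@dataclass
class MSDFit:
    K: float             # generalized diffusion coefficient (unitless report)
    alpha: float         # scaling exponent
    d: int = 2
    fit_range: tuple[int, int] | None = None


@dataclass
class SpeedSeries:
    n: int               # window length in frames
    delta_t: float       # s, = n·Δt
    v: np.ndarray        # (N−n, 2) velocity vectors, µm/s

    @property
    def speed(self) -> np.ndarray:
        return np.linalg.norm(self.v, axis=1)


@dataclass
class AutocorrCurve:
    xi: np.ndarray       # dimensionless lag k/n
    C: np.ndarray


@dataclass
class AutocorrFit:
    alpha_c: float
    C1: float            # measured C at ξ = 1
    C1_fitted: float     # model curve evaluated at ξ = 1


@dataclass
class Thresholds:
    """Classifier thresholds; defaults are the population-separating values."""

    c1: float = 0.45
    alpha_c: float = 1.52
    K: float = 10.0                      # auxiliary fast/slow separator
    require_both: bool = True            # motile needs BOTH c1 and alpha_c
    floating_speed: float = 20.0         # µm/s, gates reversal detection
    confinement_radius: float = 0.5      # µm, trapped-segment RMS bound
    confinement_window: float = 1.0      # s


@dataclass
class MotilityClass:
    label: str                           # floating|running|rwr|trapped|unclassified
    features: dict = field(default_factory=dict)


# --------------------------------------------------------------------------
# MSD
# --------------------------------------------------------------------------

def msd(traj: Trajectory, max_lag: int | None = None,
        time_averaged: bool = True) -> MSDCurve:
    """Mean square displacement versus lag time.

    By default the time-averaged MSD (mean over all start points) is
    computed; ``time_averaged=False`` gives the single-origin displacement
    ``|r_{1+k} − r_1|²``.
    """
    n = len(traj)
    if max_lag is None:
        max_lag = max(1, n // 4)
    if max_lag >= n:
        raise ValueError("max_lag must be smaller than the trajectory length")
    r = traj.positions
    out = np.empty(max_lag + 1)
    out[0] = 0.0
    for k in range(1, max_lag + 1):
        d = r[k:] - r[:-k]
        sq = (d ** 2).sum(axis=1)
        out[k] = sq.mean() if time_averaged else sq[0]
    tau = np.arange(max_lag + 1) * traj.dt
    return MSDCurve(tau=tau, msd=out)


def fit_msd_power_law(curve: MSDCurve, fit_range: tuple[int, int] | None = None,
                      d: int = 2) -> MSDFit:
    """Fit ``MSD = 2dK·τ^α`` by a least-squares line in log–log coordinates."""
    n = len(curve.tau)
    lo, hi = fit_range if fit_range is not None else (1, n - 1)
    tau = curve.tau[lo:hi + 1]
    val = curve.msd[lo:hi + 1]
    good = val > 0
    if good.sum() < val.size:
        warnings.warn("nonpositive MSD values excluded from the power-law fit",
                      stacklevel=2)
    tau, val = tau[good], val[good]
    if len(tau) < 3:
        raise ValueError("need at least 3 positive MSD points to fit")
    slope, intercept = np.polyfit(np.log(tau), np.log(val), 1)
    K = float(np.exp(intercept) / (2 * d))
    return MSDFit(K=K, alpha=float(slope), d=d, fit_range=(lo, hi))


# --------------------------------------------------------------------------
# speed and autocorrelation
# --------------------------------------------------------------------------

def mean_speed_series(traj: Trajectory, n: int = 25) -> SpeedSeries:
    """Sliding-window mean velocity vectors over n frames (δt = n·Δt)."""
    if n >= len(traj):
        raise ValueError("window n must be smaller than the trajectory length")
    r = traj.positions
    delta_t = n * traj.dt
    v = (r[n:] - r[:-n]) / delta_t
    return SpeedSeries(n=n, delta_t=delta_t, v=v)


def speed_autocorrelation(speeds: SpeedSeries, max_k: int | None = None) -> AutocorrCurve:
    """Normalized speed autocorrelation on the rescaled lag ξ = k/n.

    For each lag k both the numerator Σ v_{j+k}·v_j and the denominator
    Σ v_j² run over the same range j = 1 … N−n−k, so C(0) = 1 exactly.  With
    the default ``max_k = n`` the ξ ∈ [0, 1] interval holds n+1 points.
    """
    v = speeds.v
    m = len(v)
    if max_k is None:
        max_k = speeds.n
    if max_k > m - 1:
        raise ValueError("max_k too large for the speed series")
    C = np.empty(max_k + 1)
    for k in range(max_k + 1):
        head = v[: m - k]
        num = float((v[k:] * head).sum())
        den = float((head * head).sum())
        if den == 0.0:
            raise ValueError("all-zero speeds: autocorrelation undefined")
        C[k] = num / den
    xi = np.arange(max_k + 1) / speeds.n
    return AutocorrCurve(xi=xi, C=C)


def fbm_autocorrelation(xi, alpha_c: float):
    """Closed-form FBM speed autocorrelation C^FBM(ξ)."""
    xi = np.asarray(xi, dtype=float)
    if np.any(xi < 0):
        raise ValueError("xi must be >= 0")
    if not 0 < alpha_c <= 2:
        raise ValueError("alpha_c must lie in (0, 2]")
    out = 0.5 * ((xi + 1) ** alpha_c + np.abs(xi - 1) ** alpha_c - 2 * xi ** alpha_c)
    return float(out) if out.ndim == 0 else out


def fit_fbm_autocorr(curve: AutocorrCurve) -> AutocorrFit:
    """Fit α_c of the FBM autocorrelation over ξ ∈ (0, 1].

    ``C1`` is the *measured* value at ξ = 1 (the model curve evaluated there
    is also reported as ``C1_fitted``).
    """
    sel = (curve.xi > 0) & (curve.xi <= 1 + 1e-12)
    xi, c = curve.xi[sel], curve.C[sel]
    if len(xi) < 3:
        raise ValueError("need at least 3 points in xi ∈ (0, 1] to fit alpha_c")
    res = least_squares(lambda p: fbm_autocorrelation(xi, p[0]) - c,
                        x0=[1.0], bounds=([1e-6], [2.0]))
    alpha_c = float(res.x[0])
    i1 = int(np.argmin(np.abs(curve.xi - 1.0)))
    if not np.isclose(curve.xi[i1], 1.0, atol=1e-9):
        raise ValueError("curve must contain the point ξ = 1 to report C1")
    return AutocorrFit(alpha_c=alpha_c, C1=float(curve.C[i1]),
                       C1_fitted=float(fbm_autocorrelation(1.0, alpha_c)))


# --------------------------------------------------------------------------
# reversals and classification
# --------------------------------------------------------------------------

def detect_reversals(traj: Trajectory, window: int | None = None,
                     guard: int | None = None, angle_deg: float = 120.0,
                     min_speed: float = 20.0) -> list[float]:
    """Detect abrupt run–wrap–reverse direction changes.

    At each candidate instant the mean headings over a ``window`` of frames
    before and after (separated by a ``guard`` that skips the wrap/pause phase
    of the reversal, default 0.1 s) are compared; an event is flagged when the
    angle between them exceeds ``angle_deg`` while both sides move faster
    than ``min_speed`` µm/s.  Nearby flags are merged into one event; event
    times are returned.
    """
    fps = traj.fps
    w = window if window is not None else max(2, int(round(0.05 * fps)))
    g = guard if guard is not None else max(1, int(round(0.1 * fps)))
    r = traj.positions
    n = len(traj)
    if n < 2 * (w + g) + 1:
        return []
    idx = np.arange(w + g, n - w - g)
    vb = r[idx - g] - r[idx - g - w]
    va = r[idx + g + w] - r[idx + g]
    dt_w = w * traj.dt
    sb = np.linalg.norm(vb, axis=1) / dt_w
    sa = np.linalg.norm(va, axis=1) / dt_w
    dot = (vb * va).sum(axis=1)
    norm = np.linalg.norm(vb, axis=1) * np.linalg.norm(va, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ang = np.degrees(np.arccos(np.clip(dot / np.where(norm > 0, norm, np.inf),
                                           -1.0, 1.0)))
    flag = (ang > angle_deg) & (sb > min_speed) & (sa > min_speed)
    events: list[float] = []
    i = 0
    while i < len(idx):
        if flag[i]:
            j = i
            while j + 1 < len(idx) and flag[j + 1]:
                j += 1
            peak = i + int(np.argmax(ang[i:j + 1]))
            events.append(float(traj.t[idx[peak]]))
            i = j + 1 + w          # suppress re-triggering within one window
        else:
            i += 1
    return events


def _window_rms(traj: Trajectory, window_s: float) -> np.ndarray:
    """RMS 2D deviation from the window centroid, over sliding windows."""
    w = max(2, int(round(window_s * traj.fps)))
    r = traj.positions
    n = len(traj)
    if n <= w:
        w = n
    step = max(1, w // 4)
    out = []
    for start in range(0, n - w + 1, step):
        seg = r[start:start + w]
        dev = seg - seg.mean(axis=0)
        out.append(float(np.sqrt((dev ** 2).sum(axis=1).mean())))
    return np.asarray(out)


def _is_trapped(traj: Trajectory, radius: float, window_s: float) -> bool:
    """Detect a harmonically confined (trapped) trajectory or segment.

    Two routes: (a) the whole record is anchored — its RMS spread about the
    global centroid stays below twice the confinement radius, which a freely
    diffusing cell exceeds by slow wandering; (b) a partial trap — some
    window is confined below ``radius`` while other segments show clear
    motion (RMS above 4×radius), the before/after contrast of a swimmer
    getting caught.
    """
    r = traj.positions
    dev = r - r.mean(axis=0)
    full_rms = float(np.sqrt((dev ** 2).sum(axis=1).mean()))
    if full_rms < 2.0 * radius:
        return True
    win = _window_rms(traj, window_s)
    return bool((win < radius).any() and (win > 4.0 * radius).any())


def compute_features(traj: Trajectory, n_speed: int = 25, n_acf: int = 7,
                     thresholds: Thresholds | None = None) -> dict:
    """All classification features of one trajectory."""
    th = thresholds or Thresholds()
    feats: dict = {}
    curve = msd(traj)
    try:
        fit = fit_msd_power_law(curve)
        feats["K"], feats["alpha"] = fit.K, fit.alpha
    except ValueError:
        feats["K"] = feats["alpha"] = np.nan
    try:
        sp = mean_speed_series(traj, n_speed)
        feats["median_speed"] = float(np.median(sp.speed))
    except ValueError:
        feats["median_speed"] = np.nan
    try:
        acf = speed_autocorrelation(mean_speed_series(traj, n_acf))
        af = fit_fbm_autocorr(acf)
        feats["alpha_c"], feats["C1"] = af.alpha_c, af.C1
    except ValueError:
        feats["alpha_c"] = feats["C1"] = np.nan
    if np.isfinite(feats["median_speed"]) and feats["median_speed"] > th.floating_speed:
        feats["n_reversals"] = len(detect_reversals(traj, min_speed=th.floating_speed))
    else:
        feats["n_reversals"] = 0
    return feats


def decide_label(c1: float, alpha_c: float, n_reversals: int = 0,
                 trapped: bool = False,
                 thresholds: Thresholds | None = None) -> str:
    """Label from the classification features alone.

    Trapped wins outright; a trajectory is motile when C₁ and α_c both
    exceed their thresholds (``require_both=False`` relaxes this to either);
    motile with reversals is rwr, without is running; the rest float.
    """
    th = thresholds or Thresholds()
    if trapped:
        return "trapped"
    if not (np.isfinite(c1) and np.isfinite(alpha_c)):
        return "unclassified"
    if th.require_both:
        motile = c1 > th.c1 and alpha_c > th.alpha_c
    else:
        motile = c1 > th.c1 or alpha_c > th.alpha_c
    if motile:
        return "rwr" if n_reversals > 0 else "running"
    return "floating"


def classify(traj: Trajectory, thresholds: Thresholds | None = None,
             n_speed: int = 25, n_acf: int = 7) -> MotilityClass:
    """Rule-based classification into floating / running / rwr / trapped.

    Decision order: (1) trapped if the record is anchored or shows a
    confined-vs-moving contrast; (2) motile if C₁ and α_c exceed their
    thresholds; (3) motile with detected reversals → rwr, otherwise running;
    (4) everything else floats.
    """
    th = thresholds or Thresholds()
    feats = compute_features(traj, n_speed=n_speed, n_acf=n_acf, thresholds=th)
    trapped = _is_trapped(traj, th.confinement_radius, th.confinement_window)
    label = decide_label(feats.get("C1", np.nan), feats.get("alpha_c", np.nan),
                         feats.get("n_reversals", 0), trapped, th)
    return MotilityClass(label, feats)


# --------------------------------------------------------------------------
# population utility
# --------------------------------------------------------------------------

def fit_double_gaussian(values: np.ndarray, bins: int = 40):
    """Fit a two-component Gaussian mixture to a 1D feature distribution.

    Utility for population histograms of speed, α, K, α_c or C₁; returns
    ``(weights, means, sigmas)`` of the two components.
    """
    from scipy.optimize import curve_fit

    values = np.asarray(values, dtype=float)
    counts, edges = np.histogram(values, bins=bins, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])

    def model(x, w1, m1, s1, w2, m2, s2):
        g1 = w1 * np.exp(-(x - m1) ** 2 / (2 * s1 ** 2)) / (s1 * np.sqrt(2 * np.pi))
        g2 = w2 * np.exp(-(x - m2) ** 2 / (2 * s2 ** 2)) / (s2 * np.sqrt(2 * np.pi))
        return g1 + g2

    lo_q, hi_q = np.quantile(values, [0.25, 0.75])
    s0 = max(values.std() / 2, 1e-6)
    p0 = [0.5, lo_q, s0, 0.5, hi_q, s0]
    popt, _ = curve_fit(model, centers, counts, p0=p0,
                        bounds=([0, -np.inf, 1e-9, 0, -np.inf, 1e-9],
                                [1, np.inf, np.inf, 1, np.inf, np.inf]),
                        maxfev=20000)
    w = np.array([popt[0], popt[3]])
    m = np.array([popt[1], popt[4]])
    s = np.array([popt[2], popt[5]])
    order = np.argsort(m)
    return w[order], m[order], s[order]
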