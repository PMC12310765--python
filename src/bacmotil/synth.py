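"""Synthetic trajectories and video stacks for swimming, floating and trapped bacteria.

Four trajectory classes are generated, mirroring what dark-field video
microscopy of *Pseudomonas aeruginosa* shows at 200--1000 fps:

* ``floating`` -- passive (sub-)diffusive motion of non-motile cells, modelled
  as two independent fractional Brownian motions with Hurst coefficient ``H``;
* ``running`` -- ballistic swimming at 20--100 µm/s with the body wobbling at
  tens of Hz around the mean heading;
* ``rwr`` -- running interrupted by abrupt near-180° reversals
  (run--wrap--reverse);
* ``trapped`` -- overdamped harmonic confinement in an optical trap
  (Ornstein--Uhlenbeck process with stiffness κ).

Trajectories can be rendered into noisy grayscale frame stacks (elliptical
Gaussian spots, optional twin-lobe dividing cells) so the tracking stage can
be exercised without experimental data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .trajectory import Trajectory

__all__ = [
    "FBMParams",
    "SwimmerParams",
    "TrapParams",
    "SceneParams",
    "SpotAppearance",
    "TwinAppearance",
    "fgn_autocovariance",
    "gen_fbm_trajectory",
    "gen_fbm_ensemble",
    "gen_run_trajectory",
    "gen_trapped_trajectory",
    "gen_class_set",
    "render_video",
    "write_stack",
    "write_truth",
]

#: thermal energy at room temperature (T ≈ 293 K), joules
KT_ROOM = 4.05e-21

#: prolate-spheroid drag of a 1×2 µm bacterium in water, Ns/m
GAMMA0_BACTERIUM = 1.42e-8


# --------------------------------------------------------------------------
# parameter containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FBMParams:
    """Fractional Brownian motion parameters for a floating cell.

    ``diffusion_scale`` is the generalized diffusion coefficient K per axis in
    µm²/s^(2H): the one-axis MSD obeys ``2·K·τ^(2H)``.
    """

    hurst: float
    diffusion_scale: float = 1.0
    n_steps: int = 1000
    dt: float = 1.0 / 500.0

    def __post_init__(self) -> None:
        if not 0.0 < self.hurst < 1.0:
            raise ValueError(f"hurst must lie in (0, 1), got {self.hurst}")
        if self.diffusion_scale <= 0:
            raise ValueError("diffusion_scale must be positive")
        if self.n_steps < 2:
            raise ValueError("n_steps must be >= 2")
        if self.dt <= 0:
            raise ValueError("dt must be positive")


@dataclass(frozen=True)
class SwimmerParams:
    """Run / run--wrap--reverse swimmer parameters.

    ``wobble_freq``/``wobble_amp`` describe the sinusoidal oscillation of the
    body orientation caused by flagellar rotation (typically 30--40 Hz, a few
    degrees to tens of degrees); ``rot_diffusion`` adds slow rotational
    diffusion of the mean heading; ``reversal_rate`` > 0 switches on
    exponentially distributed run times terminated by ~180° heading flips
    after a pause of ``reversal_pause`` seconds.
    """

    speed: float = 55.0            # µm/s
    wobble_freq: float = 35.0      # Hz
    wobble_amp: float = 15.0       # degrees
    rot_diffusion: float = 0.1     # rad²/s
    reversal_rate: float = 0.0     # 1/s (0 → pure runner)
    reversal_pause: float = 0.1    # s
    reversal_angle_sd: float = 15.0  # degrees of scatter around 180°

    def __post_init__(self) -> None:
        if self.speed < 0:
            raise ValueError("speed must be >= 0")
        if self.wobble_freq < 0:
            raise ValueError("wobble_freq must be >= 0")
        if self.reversal_rate < 0:
            raise ValueError("reversal_rate must be >= 0")
        if self.rot_diffusion < 0:
            raise ValueError("rot_diffusion must be >= 0")


@dataclass(frozen=True)
class TrapParams:
    """Overdamped harmonic (optical-trap) confinement parameters."""

    kappa_x: float = 0.8           # pN/µm
    kappa_y: float = 0.8           # pN/µm
    gamma0: float = GAMMA0_BACTERIUM  # Ns/m
    kT: float = KT_ROOM            # J
    center: tuple[float, float] = (0.0, 0.0)  # µm

    def __post_init__(self) -> None:
        if self.kappa_x <= 0 or self.kappa_y <= 0:
            raise ValueError("trap stiffness must be positive")
        if self.gamma0 <= 0:
            raise ValueError("gamma0 must be positive")
        if self.kT < 0:
            raise ValueError("kT must be >= 0")


@dataclass(frozen=True)
class SceneParams:
    """Imaging geometry and camera noise for rendered stacks."""

    frame_shape: tuple[int, int] = (256, 256)  # (rows, cols) px
    pixel_scale: float = 0.26      # µm/px
    fps: float = 500.0
    background: float = 100.0      # counts
    noise_sigma: float = 5.0       # counts
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if self.pixel_scale <= 0:
            raise ValueError("pixel_scale must be positive")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")


@dataclass(frozen=True)
class SpotAppearance:
    """Elliptical-Gaussian image of one bacterium (pixel units)."""

    amplitude: float = 2000.0
    sigma_long: float = 2.2        # px
    sigma_short: float = 1.2       # px


@dataclass(frozen=True)
class TwinAppearance:
    """Two merged circular lobes of a dividing cell (pixel units)."""

    amplitude: float = 2000.0
    sigma: float = 1.4             # px, per lobe
    separation: float = 1.5        # µm between lobe centers


# --------------------------------------------------------------------------
# fractional Brownian motion
# --------------------------------------------------------------------------

def fgn_autocovariance(hurst: float, n: int) -> np.ndarray:
    """Autocovariance γ(0..n-1) of unit-variance fractional Gaussian noise.

    γ(k) = ½ (|k+1|^{2H} − 2|k|^{2H} + |k−1|^{2H})
    """
    k = np.arange(n, dtype=float)
    h2 = 2.0 * hurst
    return 0.5 * (np.abs(k + 1) ** h2 - 2 * np.abs(k) ** h2 + np.abs(k - 1) ** h2)


@lru_cache(maxsize=16)
def _fgn_cholesky(hurst: float, n: int) -> np.ndarray:
    """Lower Cholesky factor of the unit-variance fGn covariance matrix."""
    gamma = fgn_autocovariance(hurst, n)
    cov = gamma[np.abs(np.subtract.outer(np.arange(n), np.arange(n)))]
    return np.linalg.cholesky(cov)


@lru_cache(maxsize=16)
def _fgn_circulant_sqrt(hurst: float, n: int) -> np.ndarray:
    """Square roots of circulant-embedding eigenvalues for Davies–Harte synthesis."""
    gamma = fgn_autocovariance(hurst, n + 1)
    first_row = np.concatenate([gamma, gamma[-2:0:-1]])
    eig = np.fft.fft(first_row).real
    if eig.min() < -1e-8:
        raise RuntimeError("circulant embedding not nonnegative definite")
    return np.sqrt(np.clip(eig, 0.0, None))


def _fgn_samples(hurst: float, n: int, n_series: int, rng: np.random.Generator) -> np.ndarray:
    """(n_series, n) unit-variance fGn samples; exact for any H."""
    if n <= 4096:
        chol = _fgn_cholesky(hurst, n)
        z = rng.standard_normal((n, n_series))
        return (chol @ z).T
    # Davies–Harte circulant embedding for long series
    sq = _fgn_circulant_sqrt(hurst, n)
    m = len(sq)
    z = rng.standard_normal((n_series, m)) + 1j * rng.standard_normal((n_series, m))
    w = np.fft.fft(sq * z, axis=1) / np.sqrt(2 * m)
    return w[:, :n].real * np.sqrt(2.0)


def gen_fbm_trajectory(params: FBMParams, seed: int) -> Trajectory:
    """One 2D fractional Brownian motion path starting at the origin.

    Increments along each axis are fractional Gaussian noise with the exact
    autocovariance implied by the Hurst coefficient; axes are independent.
    Deterministic given ``(params, seed)``.
    """
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(2.0 * params.diffusion_scale * params.dt ** (2 * params.hurst))
    incr = sigma * _fgn_samples(params.hurst, params.n_steps - 1, 2, rng)
    x = np.concatenate([[0.0], np.cumsum(incr[0])])
    y = np.concatenate([[0.0], np.cumsum(incr[1])])
    t = np.arange(params.n_steps) * params.dt
    return Trajectory(t, x, y, meta={"class": "floating", "hurst": params.hurst,
                                     "K": params.diffusion_scale, "seed": seed})


def gen_fbm_ensemble(params: FBMParams, n_traj: int, seed: int) -> np.ndarray:
    """(n_traj, n_steps, 2) array of FBM paths, vectorized for ensemble statistics."""
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(2.0 * params.diffusion_scale * params.dt ** (2 * params.hurst))
    incr = sigma * _fgn_samples(params.hurst, params.n_steps - 1, 2 * n_traj, rng)
    incr = incr.reshape(n_traj, 2, params.n_steps - 1)
    paths = np.zeros((n_traj, params.n_steps, 2))
    paths[:, 1:, 0] = np.cumsum(incr[:, 0, :], axis=1)
    paths[:, 1:, 1] = np.cumsum(incr[:, 1, :], axis=1)
    return paths


# --------------------------------------------------------------------------
# active swimmers
# --------------------------------------------------------------------------

def gen_run_trajectory(params: SwimmerParams, n_steps: int, dt: float,
                       seed: int) -> Trajectory:
    """Swimmer trajectory with wobbling heading and optional reversals.

    The instantaneous heading is ``φ(t) = φ_rw(t) + A sin(2π f t + φ0)`` where
    ``φ_rw`` performs rotational diffusion; positions integrate the wobbling
    heading at constant speed, which produces the characteristic wobbling
    track.  With ``reversal_rate > 0``, run segments of exponentially
    distributed duration end in a pause of ``reversal_pause`` seconds followed
    by a heading flip of 180° ± ``reversal_angle_sd``.

    Returns a :class:`Trajectory` whose ``beta`` is the axial body orientation
    in degrees and whose ``meta`` carries the programmed reversal times.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    rng = np.random.default_rng(seed)
    t = np.arange(n_steps) * dt

    phi0 = rng.uniform(0, 2 * np.pi)
    wobble_phase = rng.uniform(0, 2 * np.pi)
    # rotational diffusion of the mean heading
    phi = phi0 + np.concatenate(
        [[0.0], np.cumsum(np.sqrt(2 * params.rot_diffusion * dt)
                          * rng.standard_normal(n_steps - 1))])

    # reversal schedule: alternating run / pause segments
    speed_mask = np.ones(n_steps)
    reversal_times: list[float] = []
    if params.reversal_rate > 0:
        t_ev = rng.exponential(1.0 / params.reversal_rate)
        while t_ev < t[-1]:
            reversal_times.append(t_ev)
            i0 = int(np.searchsorted(t, t_ev))
            i1 = int(np.searchsorted(t, t_ev + params.reversal_pause))
            speed_mask[i0:i1] = 0.0
            flip = np.pi + np.deg2rad(rng.normal(0.0, params.reversal_angle_sd))
            phi[i1:] += flip if rng.random() < 0.5 else -flip
            t_ev += params.reversal_pause + rng.exponential(1.0 / params.reversal_rate)

    heading = phi + np.deg2rad(params.wobble_amp) * np.sin(
        2 * np.pi * params.wobble_freq * t + wobble_phase)

    vx = params.speed * speed_mask * np.cos(heading)
    vy = params.speed * speed_mask * np.sin(heading)
    x = np.concatenate([[0.0], np.cumsum(vx[:-1] * dt)])
    y = np.concatenate([[0.0], np.cumsum(vy[:-1] * dt)])

    beta = _axial_degrees(heading)
    label = "rwr" if params.reversal_rate > 0 else "running"
    return Trajectory(t, x, y, beta=beta,
                      meta={"class": label, "seed": seed,
                            "reversal_times": reversal_times,
                            "speed": params.speed,
                            "wobble_freq": params.wobble_freq})


def _axial_degrees(heading_rad: np.ndarray) -> np.ndarray:
    """Map a heading angle to the axial orientation convention (−90, 90] deg."""
    beta = np.rad2deg(heading_rad) % 180.0
    beta = np.where(beta > 90.0, beta - 180.0, beta)
    return beta


# --------------------------------------------------------------------------
# optically trapped cells
# --------------------------------------------------------------------------

def gen_trapped_trajectory(params: TrapParams, n_steps: int, dt: float,
                           seed: int) -> Trajectory:
    """Ornstein–Uhlenbeck motion in a harmonic optical trap.

    Uses the exact discretization per axis,

        x⁺ = c·x + σ_st·√(1 − c²)·ζ,   c = exp(−κ dt/γ0),

    with stationary standard deviation ``σ_st = √(kT/κ)`` (equipartition), so
    samples have the correct stationary variance and autocorrelation at any
    ``dt``.  Initial positions are drawn from the stationary distribution.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    rng = np.random.default_rng(seed)
    t = np.arange(n_steps) * dt
    out = []
    for kappa_pn_um in (params.kappa_x, params.kappa_y):
        kappa_si = kappa_pn_um * 1e-6          # pN/µm → N/m
        c = np.exp(-kappa_si * dt / params.gamma0)
        sigma_um = np.sqrt(params.kT / kappa_si) * 1e6  # m → µm
        zeta = rng.standard_normal(n_steps)
        pos = np.empty(n_steps)
        pos[0] = sigma_um * zeta[0]
        s = sigma_um * np.sqrt(1 - c * c)
        for i in range(1, n_steps):
            pos[i] = c * pos[i - 1] + s * zeta[i]
        out.append(pos)
    x = out[0] + params.center[0]
    y = out[1] + params.center[1]
    return Trajectory(t, x, y, meta={"class": "trapped", "seed": seed,
                                     "kappa_x": params.kappa_x,
                                     "kappa_y": params.kappa_y})


# --------------------------------------------------------------------------
# video rendering
# --------------------------------------------------------------------------

def _add_gaussian_spot(frame: np.ndarray, x: float, y: float, amplitude: float,
                       sigma_a: float, sigma_b: float, beta_deg: float) -> None:
    """Add one elliptical Gaussian centred at (x, y) px, long axis along β."""
    h, w = frame.shape
    half = int(np.ceil(4 * max(sigma_a, sigma_b))) + 1
    i0, i1 = max(0, int(x) - half), min(w, int(x) + half + 1)
    j0, j1 = max(0, int(y) - half), min(h, int(y) + half + 1)
    if i0 >= i1 or j0 >= j1:
        return
    xs = np.arange(i0, i1) - x
    ys = np.arange(j0, j1) - y
    dx, dy = np.meshgrid(xs, ys)
    b = np.deg2rad(beta_deg)
    u = dx * np.cos(b) + dy * np.sin(b)
    v = -dx * np.sin(b) + dy * np.cos(b)
    frame[j0:j1, i0:i1] += amplitude * np.exp(
        -(u ** 2 / (2 * sigma_a ** 2) + v ** 2 / (2 * sigma_b ** 2)))


def render_video(trajectories: list[Trajectory],
                 spot_params: list[SpotAppearance | TwinAppearance],
                 scene: SceneParams, seed: int = 0) -> np.ndarray:
    """Render trajectories into a noisy grayscale frame stack.

    Each frame is ``background + Σ spots + N(0, noise_sigma)``, clipped to the
    bit depth.  Spots are elliptical Gaussians oriented by the trajectory's
    ``beta`` (or circular if absent); a :class:`TwinAppearance` renders two
    circular lobes at the given separation, emulating a dividing cell.
    Positions are converted µm → px with ``scene.pixel_scale``; spots leaving
    the frame raise a warning and are clipped.

    Returns ``(n_frames, rows, cols)`` array with the scene's integer dtype.
    """
    if len(trajectories) != len(spot_params):
        raise ValueError("one SpotAppearance/TwinAppearance per trajectory required")
    n_frames = min(len(tr) for tr in trajectories)
    h, w = scene.frame_shape
    rng = np.random.default_rng(seed)
    maxval = 2 ** scene.bit_depth - 1
    dtype = np.uint8 if scene.bit_depth == 8 else np.uint16

    stack = np.empty((n_frames, h, w), dtype=dtype)
    warned = False
    for k in range(n_frames):
        frame = np.full((h, w), float(scene.background))
        for tr, ap in zip(trajectories, spot_params):
            xp = tr.x[k] / scene.pixel_scale
            yp = tr.y[k] / scene.pixel_scale
            if not (0 <= xp < w and 0 <= yp < h) and not warned:
                warnings.warn("trajectory leaves the frame; spot clipped", stacklevel=2)
                warned = True
            beta = tr.beta[k] if tr.beta is not None else 0.0
            if isinstance(ap, TwinAppearance):
                half_d = 0.5 * ap.separation / scene.pixel_scale
                b = np.deg2rad(beta)
                for sgn in (-1.0, 1.0):
                    _add_gaussian_spot(frame,
                                       xp + sgn * half_d * np.cos(b),
                                       yp + sgn * half_d * np.sin(b),
                                       ap.amplitude, ap.sigma, ap.sigma, 0.0)
            else:
                _add_gaussian_spot(frame, xp, yp, ap.amplitude,
                                   ap.sigma_long, ap.sigma_short, beta)
        if scene.noise_sigma > 0:
            frame += rng.normal(0.0, scene.noise_sigma, size=frame.shape)
        stack[k] = np.clip(np.rint(frame), 0, maxval).astype(dtype)
    return stack


def gen_class_set(n_per_class: int, seed: int, n_steps: int = 3000,
                  dt: float = 1.0 / 500.0) -> list[Trajectory]:
    """Generate a labelled benchmark set covering the four trajectory classes.

    Per-trajectory parameters are drawn from the observed ranges: floating
    cells are FBM with H in [0.3, 0.5] and K near 1 µm²/s^2H; runners swim at
    20–100 µm/s wobbling at 30–40 Hz; run–wrap–reverse swimmers add ~0.7/s
    reversals with a 0.15 s pause; trapped cells are harmonically confined
    with κ log-uniform in [0.01, 1] pN/µm.  Record length defaults to 3000
    frames at 500 fps, as in typical videos.  The truth label is in each
    trajectory's ``meta['class']``.
    """
    rng = np.random.default_rng(seed)
    out: list[Trajectory] = []
    hurst_grid = np.array([0.30, 0.35, 0.40, 0.45, 0.50])
    for i in range(n_per_class):
        sub = int(rng.integers(0, 2 ** 31 - 1))
        out.append(gen_fbm_trajectory(FBMParams(
            hurst=float(rng.choice(hurst_grid)),
            diffusion_scale=float(np.exp(rng.uniform(np.log(0.5), np.log(3.0)))),
            n_steps=n_steps, dt=dt), seed=sub))
    for label, rev_rate in (("running", 0.0), ("rwr", 0.7)):
        for i in range(n_per_class):
            sub = int(rng.integers(0, 2 ** 31 - 1))
            out.append(gen_run_trajectory(SwimmerParams(
                speed=float(rng.uniform(20.0, 100.0)),
                wobble_freq=float(rng.uniform(30.0, 40.0)),
                wobble_amp=float(rng.uniform(10.0, 20.0)),
                rot_diffusion=0.1,
                reversal_rate=rev_rate,
                reversal_pause=0.15), n_steps, dt, seed=sub))
    for i in range(n_per_class):
        sub = int(rng.integers(0, 2 ** 31 - 1))
        kappa = float(np.exp(rng.uniform(np.log(0.01), np.log(1.0))))
        out.append(gen_trapped_trajectory(
            TrapParams(kappa_x=kappa, kappa_y=kappa), n_steps, dt, seed=sub))
    return out


def write_stack(stack: np.ndarray, path: str) -> None:
    """Write a frame stack as a multi-page grayscale TIFF."""
    import tifffile

    tifffile.imwrite(path, stack, photometric="minisblack")


def write_truth(trajectories: list[Trajectory], path: str,
                pixel_scale: float | None = None) -> None:
    """Write ground-truth positions (frame, id, x_um, y_um, beta_deg, class) as CSV."""
    import pandas as pd

    rows = []
    for tid, tr in enumerate(trajectories):
        label = tr.meta.get("class", "unknown")
        for k in range(len(tr)):
            rows.append({
                "frame": k, "id": tid,
                "x_um": tr.x[k], "y_um": tr.y[k],
                "beta_deg": tr.beta[k] if tr.beta is not None else np.nan,
                "class": label,
            })
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6g")
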