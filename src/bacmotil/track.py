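"""Sub-pixel spot localization and trajectory linking for bacteria videos.

Pipeline per frame: rough detection of bright spots by determinant-of-Hessian
blob detection, then sub-pixel refinement by nonlinear least-squares fitting
of an elliptical Gaussian (or a twin-lobe model for dividing cells) in a
cropped region.  Detections in successive frames are linked by greedy
nearest-neighbour association gated at three times the spot size; only tracks
spanning at least ``min_track_len`` frames (default 200) are kept.

Coordinate convention: pixel centers at integer coordinates, origin at the
top-left, x rightward, y downward; the orientation β of the long axis is
measured from the +x axis and normalized to (−90, 90] degrees.
"""

from __future__ import annotations

import glob as _glob
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from skimage.feature import blob_doh

from .trajectory import Trajectory

__all__ = [
    "Spot", "TwinSpot", "Track", "FitError",
    "detect_blobs", "fit_gaussian_ellipse", "fit_twin_spot", "choose_spot_model",
    "link_tracks", "track_to_trajectory", "process_stack", "read_stack",
    "tracks_to_dataframe",
]


class FitError(RuntimeError):
    """Raised when a spot fit does not converge to a physical solution."""


@dataclass
class Spot:
    """One fitted elliptical-Gaussian bacterium image (pixel units)."""

    x: float
    y: float
    sigma_long: float
    sigma_short: float
    beta: float          # degrees, (−90, 90]
    amplitude: float
    background: float
    frame: int = -1

    @property
    def size(self) -> float:
        """Spot size used for the linking gate: full width 2σ_long."""
        return 2.0 * self.sigma_long


@dataclass
class TwinSpot:
    """Two circular Gaussian lobes at separation d (a dividing cell)."""

    cx: float
    cy: float
    d: float
    theta: float         # degrees, (−90, 90]
    sigma: float
    amplitude: float
    background: float
    frame: int = -1
    degenerate: bool = False


@dataclass
class Track:
    """A linked sequence of spots over consecutive frames."""

    id: int
    frames: list[int] = field(default_factory=list)
    spots: list[Spot] = field(default_factory=list)
    fps: float | None = None
    pixel_scale: float | None = None

    def __len__(self) -> int:
        return len(self.frames)


# --------------------------------------------------------------------------
# detection
# --------------------------------------------------------------------------

def detect_blobs(frame: np.ndarray, min_sigma: float = 1.0, max_sigma: float = 6.0,
                 threshold: float = 0.01) -> list[tuple[float, float, float]]:
    """Rough bright-spot detection by determinant-of-Hessian scale-space maxima.

    Only bright in-focus cells are detected; dark out-of-plane cells do not
    produce DoH maxima at positive threshold.  Returns ``(x, y, sigma)``
    triples in pixel units.
    """
    img = np.asarray(frame, dtype=float)
    span = img.max() - img.min()
    if span <= 0:
        return []
    img = (img - img.min()) / span
    blobs = blob_doh(img, min_sigma=min_sigma, max_sigma=max_sigma,
                     threshold=threshold)
    return [(float(bx), float(by), float(bs)) for by, bx, bs in blobs]


# --------------------------------------------------------------------------
# sub-pixel fitting
# --------------------------------------------------------------------------

def _extract_roi(frame: np.ndarray, roi_center: tuple[float, float],
                 roi_halfwidth: int):
    h, w = frame.shape
    cx, cy = int(round(roi_center[0])), int(round(roi_center[1]))
    if (cx - roi_halfwidth < 0 or cx + roi_halfwidth >= w
            or cy - roi_halfwidth < 0 or cy + roi_halfwidth >= h):
        raise ValueError("ROI extends outside the frame")
    roi = np.asarray(frame[cy - roi_halfwidth: cy + roi_halfwidth + 1,
                           cx - roi_halfwidth: cx + roi_halfwidth + 1], dtype=float)
    xs = np.arange(cx - roi_halfwidth, cx + roi_halfwidth + 1, dtype=float)
    ys = np.arange(cy - roi_halfwidth, cy + roi_halfwidth + 1, dtype=float)
    return roi, *np.meshgrid(xs, ys)


def _ellipse_model(p, gx, gy):
    bg, amp, x0, y0, sa, sb, beta = p
    dx, dy = gx - x0, gy - y0
    u = dx * np.cos(beta) + dy * np.sin(beta)
    v = -dx * np.sin(beta) + dy * np.cos(beta)
    return bg + amp * np.exp(-(u ** 2 / (2 * sa ** 2) + v ** 2 / (2 * sb ** 2)))


def fit_gaussian_ellipse(frame: np.ndarray, roi_center: tuple[float, float],
                         roi_halfwidth: int = 8,
                         init_sigma: float | None = None) -> Spot:
    """Fit ``B + A·exp(−(u²/2σ_a² + w²/2σ_b²))`` in a cropped region.

    ``(u, w)`` are ROI coordinates rotated by the orientation β.  Widths are
    returned ordered (σ_long ≥ σ_short) with β normalized to (−90, 90]; a
    circular spot reports β = 0 by convention.

    Raises :class:`FitError` on non-convergence so a failed frame leaves a
    trajectory gap instead of silent garbage.
    """
    roi, gx, gy = _extract_roi(frame, roi_center, roi_halfwidth)
    bg0 = float(np.median(roi))
    amp0 = float(roi.max() - bg0)
    if amp0 <= 0:
        raise FitError("no intensity above background in ROI")
    wgt = np.clip(roi - bg0, 0, None)
    x0 = float((gx * wgt).sum() / wgt.sum())
    y0 = float((gy * wgt).sum() / wgt.sum())
    s0 = init_sigma if init_sigma is not None else max(1.0, roi_halfwidth / 4.0)

    lo = [-np.inf, 1e-9, gx.min(), gy.min(), 0.5, 0.5, -np.pi]
    hi = [np.inf, np.inf, gx.max(), gy.max(),
          float(roi_halfwidth), float(roi_halfwidth), np.pi]
    p0 = np.clip([bg0, amp0, x0, y0, s0 * 1.2, s0 * 0.9, 0.0], lo, hi)
    res = least_squares(lambda p: (_ellipse_model(p, gx, gy) - roi).ravel(),
                        p0, bounds=(lo, hi), method="trf", xtol=1e-10, ftol=1e-10, max_nfev=5000)
    if not res.success or res.x[1] <= 0:
        raise FitError(f"ellipse fit failed: {res.message}")
    bg, amp, xc, yc, sa, sb, beta = res.x
    beta_deg = np.rad2deg(beta)
    if sb > sa:
        sa, sb = sb, sa
        beta_deg += 90.0
    beta_deg = ((beta_deg + 90.0) % 180.0) - 90.0
    if beta_deg == -90.0:
        beta_deg = 90.0
    if (sa - sb) / sa < 1e-4:   # circular: orientation undefined
        beta_deg = 0.0
    return Spot(x=float(xc), y=float(yc), sigma_long=float(sa),
                sigma_short=float(sb), beta=float(beta_deg),
                amplitude=float(amp), background=float(bg))


def _twin_model(p, gx, gy):
    bg, amp, cx, cy, d, theta, sigma = p
    ox, oy = 0.5 * d * np.cos(theta), 0.5 * d * np.sin(theta)
    r1 = (gx - cx - ox) ** 2 + (gy - cy - oy) ** 2
    r2 = (gx - cx + ox) ** 2 + (gy - cy + oy) ** 2
    return bg + amp * (np.exp(-r1 / (2 * sigma ** 2)) + np.exp(-r2 / (2 * sigma ** 2)))


def fit_twin_spot(frame: np.ndarray, roi_center: tuple[float, float],
                  roi_halfwidth: int = 10, init_d: float = 4.0,
                  init_sigma: float = 1.5) -> TwinSpot:
    """Fit two circular Gaussians at separation d (twin-bacteria model).

    A fit collapsing to d < σ/2 is flagged ``degenerate`` (single-spot limit).
    """
    roi, gx, gy = _extract_roi(frame, roi_center, roi_halfwidth)
    bg0 = float(np.median(roi))
    amp0 = max(float(roi.max() - bg0), 1e-9)
    wgt = np.clip(roi - bg0, 0, None)
    cx0 = float((gx * wgt).sum() / max(wgt.sum(), 1e-12))
    cy0 = float((gy * wgt).sum() / max(wgt.sum(), 1e-12))
    # initial lobe axis from the second moments of the intensity
    mxx = float((wgt * (gx - cx0) ** 2).sum() / max(wgt.sum(), 1e-12))
    myy = float((wgt * (gy - cy0) ** 2).sum() / max(wgt.sum(), 1e-12))
    mxy = float((wgt * (gx - cx0) * (gy - cy0)).sum() / max(wgt.sum(), 1e-12))
    theta0 = 0.5 * np.arctan2(2 * mxy, mxx - myy)

    lo = [-np.inf, 1e-9, gx.min(), gy.min(), 0.0, -np.pi, 0.5]
    hi = [np.inf, np.inf, gx.max(), gy.max(),
          2.0 * roi_halfwidth, np.pi, float(roi_halfwidth)]
    p0 = np.clip([bg0, amp0, cx0, cy0, init_d, theta0, init_sigma], lo, hi)
    res = least_squares(lambda p: (_twin_model(p, gx, gy) - roi).ravel(),
                        p0, bounds=(lo, hi), method="trf", xtol=1e-10, ftol=1e-10, max_nfev=5000)
    if not res.success or res.x[1] <= 0:
        raise FitError(f"twin fit failed: {res.message}")
    bg, amp, cx, cy, d, theta, sigma = res.x
    theta_deg = ((np.rad2deg(theta) + 90.0) % 180.0) - 90.0
    if theta_deg == -90.0:
        theta_deg = 90.0
    return TwinSpot(cx=float(cx), cy=float(cy), d=float(d),
                    theta=float(theta_deg), sigma=float(sigma),
                    amplitude=float(amp), background=float(bg),
                    degenerate=bool(d < 0.5 * sigma))


def _aicc(rss: float, n: int, k: int) -> float:
    rss = max(rss, 1e-300)
    aic = n * np.log(rss / n) + 2 * k
    if n - k - 1 > 0:
        aic += 2 * k * (k + 1) / (n - k - 1)
    return aic


def choose_spot_model(frame: np.ndarray, roi_center: tuple[float, float],
                      roi_halfwidth: int = 10) -> Spot | TwinSpot:
    """Pick the single-ellipse or twin-lobe model by small-sample AIC.

    Both models are fitted on the same ROI; the twin model wins only when its
    residual sum of squares, penalized for its parameter count, is lower.
    """
    roi, gx, gy = _extract_roi(frame, roi_center, roi_halfwidth)
    n = roi.size
    single = fit_gaussian_ellipse(frame, roi_center, roi_halfwidth)
    p1 = [single.background, single.amplitude, single.x, single.y,
          single.sigma_long, single.sigma_short, np.deg2rad(single.beta)]
    rss1 = float(((_ellipse_model(p1, gx, gy) - roi) ** 2).sum())
    try:
        twin = fit_twin_spot(frame, roi_center, roi_halfwidth)
    except (FitError, ValueError):
        return single
    p2 = [twin.background, twin.amplitude, twin.cx, twin.cy, twin.d,
          np.deg2rad(twin.theta), twin.sigma]
    rss2 = float(((_twin_model(p2, gx, gy) - roi) ** 2).sum())
    if twin.degenerate:
        return single
    return twin if _aicc(rss2, n, 7) < _aicc(rss1, n, 7) else single


# --------------------------------------------------------------------------
# linking
# --------------------------------------------------------------------------

def link_tracks(per_frame_spots: dict[int, list[Spot]],
                max_link_factor: float = 3.0,
                min_track_len: int = 200,
                fps: float | None = None,
                pixel_scale: float | None = None) -> list[Track]:
    """Greedy nearest-neighbour linking of per-frame detections into tracks.

    Frame i spots are matched to frame i+1 spots when their distance is below
    ``max_link_factor × size`` of the earlier spot (size = 2σ_long).  Conflicts
    are resolved by smallest distance (ties by detection order); unmatched
    spots open new tracks.  No gap closing: a frame without a match terminates
    the track.  Tracks shorter than ``min_track_len`` are discarded.
    """
    if not per_frame_spots:
        return []
    frames = sorted(per_frame_spots)
    next_id = 0
    open_tracks: list[Track] = []
    closed: list[Track] = []

    for spot in per_frame_spots[frames[0]]:
        spot.frame = frames[0]
        open_tracks.append(Track(id=next_id, frames=[frames[0]], spots=[spot],
                                 fps=fps, pixel_scale=pixel_scale))
        next_id += 1

    for prev_f, cur_f in zip(frames[:-1], frames[1:]):
        cur_spots = per_frame_spots.get(cur_f, [])
        if cur_f != prev_f + 1:
            closed.extend(open_tracks)   # gap in frame numbering closes all
            open_tracks = []
        candidates = []
        for ti, tr in enumerate(open_tracks):
            last = tr.spots[-1]
            gate = max_link_factor * last.size
            for si, spot in enumerate(cur_spots):
                dist = float(np.hypot(spot.x - last.x, spot.y - last.y))
                if dist <= gate:
                    candidates.append((dist, ti, si))
        candidates.sort(key=lambda c: (c[0], c[1], c[2]))
        used_t: set[int] = set()
        used_s: set[int] = set()
        survivors = []
        for dist, ti, si in candidates:
            if ti in used_t or si in used_s:
                continue
            used_t.add(ti)
            used_s.add(si)
            spot = cur_spots[si]
            spot.frame = cur_f
            open_tracks[ti].frames.append(cur_f)
            open_tracks[ti].spots.append(spot)
            survivors.append(open_tracks[ti])
        for ti, tr in enumerate(open_tracks):
            if ti not in used_t:
                closed.append(tr)
        open_tracks = survivors
        for si, spot in enumerate(cur_spots):
            if si not in used_s:
                spot.frame = cur_f
                open_tracks.append(Track(id=next_id, frames=[cur_f], spots=[spot],
                                         fps=fps, pixel_scale=pixel_scale))
                next_id += 1
    closed.extend(open_tracks)
    kept = [tr for tr in closed if len(tr) >= min_track_len]
    for new_id, tr in enumerate(sorted(kept, key=lambda t: (t.frames[0], t.id))):
        tr.id = new_id
    return sorted(kept, key=lambda t: t.id)


def track_to_trajectory(track: Track) -> Trajectory:
    """Convert a pixel/frame track to a µm/s trajectory with orientation."""
    if track.fps is None or track.pixel_scale is None:
        raise ValueError("fps and pixel_scale calibration required")
    t = np.asarray(track.frames, dtype=float) / track.fps
    x = np.array([s.x for s in track.spots]) * track.pixel_scale
    y = np.array([s.y for s in track.spots]) * track.pixel_scale
    beta = np.array([s.beta for s in track.spots])
    return Trajectory(t, x, y, beta=beta, meta={"track_id": track.id})


# --------------------------------------------------------------------------
# stack-level convenience
# --------------------------------------------------------------------------

def read_stack(path: str) -> np.ndarray:
    """Read a multi-page TIFF or a globbed image sequence as (T, H, W)."""
    import tifffile

    paths = sorted(_glob.glob(path)) if any(c in path for c in "*?[") else [path]
    if len(paths) > 1:
        import imageio.v3 as iio
        return np.stack([iio.imread(p) for p in paths])
    arr = tifffile.imread(paths[0])
    return arr[None] if arr.ndim == 2 else arr


def process_stack(stack: np.ndarray, fps: float, pixel_scale: float,
                  min_sigma: float = 1.0, max_sigma: float = 6.0,
                  threshold: float = 0.01, roi_halfwidth: int = 8,
                  max_link_factor: float = 3.0,
                  min_track_len: int = 200) -> list[Track]:
    """Detect, fit and link every frame of a stack into calibrated tracks."""
    per_frame: dict[int, list[Spot]] = {}
    for k, frame in enumerate(stack):
        spots = []
        for bx, by, bs in detect_blobs(frame, min_sigma, max_sigma, threshold):
            try:
                spots.append(fit_gaussian_ellipse(frame, (bx, by), roi_halfwidth,
                                                  init_sigma=bs))
            except (FitError, ValueError) as exc:
                warnings.warn(f"frame {k}: fit skipped ({exc})", stacklevel=2)
        per_frame[k] = spots
    return link_tracks(per_frame, max_link_factor, min_track_len,
                       fps=fps, pixel_scale=pixel_scale)


def tracks_to_dataframe(tracks: list[Track]) -> pd.DataFrame:
    """Flatten tracks into the interchange CSV schema."""
    rows = []
    for tr in tracks:
        for f, s in zip(tr.frames, tr.spots):
            rows.append({
                "track_id": tr.id,
                "frame": f,
                "t_s": f / tr.fps if tr.fps else np.nan,
                "x_um": s.x * tr.pixel_scale if tr.pixel_scale else np.nan,
                "y_um": s.y * tr.pixel_scale if tr.pixel_scale else np.nan,
                "sigma_long_um": s.sigma_long * tr.pixel_scale if tr.pixel_scale else np.nan,
                "sigma_short_um": s.sigma_short * tr.pixel_scale if tr.pixel_scale else np.nan,
                "beta_deg": s.beta,
                "amplitude": s.amplitude,
            })
    return pd.DataFrame(rows)
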