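"""Complex-Morlet wavelet spectroscopy of the body-orientation signal.

A running bacterium's flagellar rotation makes the cell body counter-rotate,
so the image orientation β(t) oscillates at the body-rotation frequency
(typically tens of Hz).  The time-resolved frequency is obtained with a
complex Morlet wavelet

    w(t) = exp(i·2π f t) · exp(−4 ln2 · t²/h²),

where h is the FWHM of the Gaussian envelope in seconds (h = n_c·√(2 ln2)/(π f)
for n_c cycles).  The wavelet is convolved with the mean-removed signal; the
magnitude of the complex result, scanned over a frequency grid, forms the
spectrogram, and the per-time argmax above a magnitude threshold is the
peak-frequency ridge.  There is an intrinsic trade-off: long wavelets give
fine frequency resolution, short ones fine time resolution; results below
about 10 Hz or at time resolutions finer than about 50 ms are unreliable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

__all__ = [
    "Spectrogram", "Ridge",
    "h_from_cycles", "morlet", "cwt", "extract_ridge", "unwrap_axial",
    "RELIABLE_FMIN_HZ", "RELIABLE_TMIN_S",
]

#: documented validity floor of the method
RELIABLE_FMIN_HZ = 10.0
RELIABLE_TMIN_S = 0.05


@dataclass
class Spectrogram:
    times: np.ndarray        # s
    freqs: np.ndarray        # Hz, strictly increasing
    magnitude: np.ndarray    # (n_freqs, n_times), >= 0
    h: float                 # s, envelope FWHM used


@dataclass
class Ridge:
    times: np.ndarray
    peak_freq: np.ndarray    # Hz, NaN where below threshold


def h_from_cycles(n_cycles: float, f: float) -> float:
    """Envelope FWHM (s) holding ``n_cycles`` oscillations at frequency f."""
    if f <= 0:
        raise ValueError("frequency must be positive")
    return n_cycles * np.sqrt(2 * np.log(2)) / (np.pi * f)


def morlet(f: float, h: float | None, t_grid: np.ndarray,
           n_cycles: float | None = None) -> np.ndarray:
    """Complex Morlet wavelet samples on a symmetric time grid."""
    if h is None:
        if n_cycles is None:
            raise ValueError("give either h or n_cycles")
        h = h_from_cycles(n_cycles, f)
    t = np.asarray(t_grid, dtype=float)
    return np.exp(2j * np.pi * f * t) * np.exp(-4 * np.log(2) * t ** 2 / h ** 2)


def unwrap_axial(beta_deg: np.ndarray) -> np.ndarray:
    """Unwrap an axial orientation series (defined modulo 180°)."""
    return np.unwrap(np.asarray(beta_deg, dtype=float), period=180.0)


def cwt(signal: np.ndarray, fps: float, freqs: np.ndarray,
        h: float = 0.15, detrend: str = "mean") -> Spectrogram:
    """Continuous wavelet transform magnitude over a frequency grid.

    The signal mean (``detrend='mean'``) or a linear trend
    (``detrend='linear'``) is removed first, since the Morlet wavelet has a
    nonzero DC response at low frequency and the oscillation rides on a
    drifting orientation.  Each wavelet is normalized so a unit-amplitude
    sinusoid at its frequency yields magnitude ≈ 1; edges are handled by
    reflect padding of half the wavelet support.
    """
    sig = np.asarray(signal, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    if np.any(np.diff(freqs) <= 0):
        raise ValueError("freqs must be strictly increasing")
    if freqs[-1] >= fps / 2:
        raise ValueError("all frequencies must be below the Nyquist limit fps/2")
    if freqs[0] < RELIABLE_FMIN_HZ:
        warnings.warn(f"frequencies below {RELIABLE_FMIN_HZ} Hz are unreliable "
                      "for this method", stacklevel=2)
    if h < RELIABLE_TMIN_S:
        warnings.warn(f"h < {RELIABLE_TMIN_S} s gives unreliable time "
                      "resolution", stacklevel=2)

    if detrend == "mean":
        sig = sig - sig.mean()
    elif detrend == "linear":
        t = np.arange(len(sig))
        sig = sig - np.polyval(np.polyfit(t, sig, 1), t)
    elif detrend != "none":
        raise ValueError(f"unknown detrend mode {detrend!r}")

    half = int(np.ceil(2.0 * h * fps))          # half support: 2h covers >3h span
    t_grid = np.arange(-half, half + 1) / fps
    pad = half
    padded = np.pad(sig, pad, mode="reflect")

    mag = np.empty((len(freqs), len(sig)))
    for i, f in enumerate(freqs):
        w = morlet(f, h, t_grid)
        w = w * (2.0 / np.abs(w).sum())         # unit sinusoid → magnitude ≈ 1
        conv = fftconvolve(padded, np.conj(w[::-1]), mode="same")
        mag[i] = np.abs(conv[pad: pad + len(sig)])
    times = np.arange(len(sig)) / fps
    return Spectrogram(times=times, freqs=freqs, magnitude=mag, h=h)


def extract_ridge(spec: Spectrogram, threshold: float = 0.2) -> Ridge:
    """Peak-frequency ridge: per-time argmax over frequency.

    Times where the column maximum falls below ``threshold`` × the global
    maximum get NaN — this reproduces the gap in the frequency trace at
    run–wrap–reverse events, where the oscillation stops.
    """
    if spec.magnitude.size == 0:
        raise ValueError("empty spectrogram")
    gmax = spec.magnitude.max()
    col_max = spec.magnitude.max(axis=0)
    peak = spec.freqs[np.argmax(spec.magnitude, axis=0)].astype(float)
    peak[col_max < threshold * gmax] = np.nan
    if gmax == 0.0:
        peak[:] = np.nan
    return Ridge(times=spec.times, peak_freq=peak)
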