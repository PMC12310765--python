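"""Time-stamped 2D trajectory container shared by all analysis stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Trajectory:
    """A uniformly sampled 2D position series.

    Parameters
    ----------
    t : array of float
        Sample times in seconds, on a uniform grid with spacing ``dt = 1/fps``.
    x, y : array of float
        Positions in micrometres.
    beta : array of float, optional
        Body-orientation angle in degrees, axial (defined modulo 180), one
        value per frame.  Present for swimmer trajectories and for tracks
        fitted with an elliptical model.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    beta: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.beta is not None:
            self.beta = np.asarray(self.beta, dtype=float)
        if self.t.ndim != 1 or self.x.shape != self.t.shape or self.y.shape != self.t.shape:
            raise ValueError("t, x, y must be 1D arrays of equal length")
        if len(self.t) < 2:
            raise ValueError("a trajectory needs at least 2 samples")
        steps = np.diff(self.t)
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-12):
            raise ValueError("trajectory must be uniformly sampled")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def dt(self) -> float:
        """Frame interval in seconds."""
        return float(self.t[1] - self.t[0])

    @property
    def fps(self) -> float:
        return 1.0 / self.dt

    @property
    def positions(self) -> np.ndarray:
        """(N, 2) array of positions in µm."""
        return np.column_stack([self.x, self.y])
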