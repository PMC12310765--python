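"""End-to-end workflow: simulate/track → features → classification → reports."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import motility, synth, timefreq, track, trap
from .trajectory import Trajectory

logger = logging.getLogger("bacmotil")

__all__ = ["RunConfig", "run_pipeline", "trajectories_from_csv",
           "classify_trajectories", "FLOAT_FORMAT"]

FLOAT_FORMAT = "%.6g"


@dataclass
class RunConfig:
    """Configuration of a full analysis run; recorded in the output manifest."""

    video: str | None = None          # multi-page TIFF path
    tracks_csv: str | None = None     # pre-extracted tracks (skips tracking)
    outdir: str = "bacmotil_out"
    pixel_scale: float = 0.26         # µm/px
    fps: float = 500.0
    kT: float = synth.KT_ROOM         # J
    eta: float = 1.0e-3               # Pa·s
    c1_threshold: float = 0.45
    alpha_c_threshold: float = 1.52
    k_threshold: float = 10.0
    n_speed: int = 25
    n_acf: int = 7
    min_track_len: int = 200
    seed: int = 0
    spectrogram_tracks: list[int] = field(default_factory=list)
    spectrogram_h: float = 0.15
    spectrogram_fmin: float = 10.0
    spectrogram_fmax: float = 100.0

    def thresholds(self) -> motility.Thresholds:
        return motility.Thresholds(c1=self.c1_threshold,
                                   alpha_c=self.alpha_c_threshold,
                                   K=self.k_threshold)


def trajectories_from_csv(path: str) -> list[Trajectory]:
    """Load the tracks CSV schema into calibrated trajectories."""
    df = pd.read_csv(path)
    out = []
    for tid, g in df.groupby("track_id"):
        g = g.sort_values("frame")
        beta = g["beta_deg"].to_numpy() if "beta_deg" in g else None
        out.append(Trajectory(g["t_s"].to_numpy(), g["x_um"].to_numpy(),
                              g["y_um"].to_numpy(), beta=beta,
                              meta={"track_id": int(tid)}))
    return out


def classify_trajectories(trajs: list[Trajectory],
                          thresholds: motility.Thresholds | None = None,
                          n_speed: int = 25, n_acf: int = 7) -> pd.DataFrame:
    """Per-trajectory features and labels as one tidy frame."""
    rows = []
    for i, tr in enumerate(trajs):
        try:
            mc = motility.classify(tr, thresholds, n_speed=n_speed, n_acf=n_acf)
            label, feats = mc.label, mc.features
        except Exception as exc:  # isolate failing tracks
            logger.warning("track %d failed: %s", i, exc)
            label, feats = "unclassified", {}
        rows.append({
            "track_id": tr.meta.get("track_id", i),
            "label": label,
            "truth": tr.meta.get("class", ""),
            "n_frames": len(tr),
            "median_speed": feats.get("median_speed", np.nan),
            "K": feats.get("K", np.nan),
            "alpha": feats.get("alpha", np.nan),
            "alpha_c": feats.get("alpha_c", np.nan),
            "C1": feats.get("C1", np.nan),
            "n_reversals": feats.get("n_reversals", 0),
        })
    cols = ["track_id", "label", "truth", "n_frames", "median_speed", "K",
            "alpha", "alpha_c", "C1", "n_reversals"]
    return pd.DataFrame(rows, columns=cols)


def run_pipeline(config: RunConfig) -> dict:
    """Run tracking (if a video is given), classification, trap and wavelet
    reports; write CSV/JSON outputs plus a manifest, and return the summary."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.video is not None:
        stack = track.read_stack(config.video)
        logger.info("tracking %d frames", len(stack))
        tracks = track.process_stack(stack, fps=config.fps,
                                     pixel_scale=config.pixel_scale,
                                     min_track_len=config.min_track_len)
        tracks_df = track.tracks_to_dataframe(tracks)
        tracks_df.to_csv(outdir / "tracks.csv", index=False,
                         float_format=FLOAT_FORMAT)
        trajs = [track.track_to_trajectory(t) for t in tracks]
    elif config.tracks_csv is not None:
        trajs = trajectories_from_csv(config.tracks_csv)
    else:
        raise ValueError("config needs either a video or a tracks CSV")

    features = classify_trajectories(trajs, config.thresholds(),
                                     n_speed=config.n_speed, n_acf=config.n_acf)
    features.to_csv(outdir / "features.csv", index=False,
                    float_format=FLOAT_FORMAT)

    counts = features["label"].value_counts().to_dict()
    summary = {"n_tracks": int(len(features)), "class_counts": counts}

    trapped = features[features["label"] == "trapped"]["track_id"].tolist()
    if trapped:
        reports = {}
        by_id = {tr.meta.get("track_id", i): tr for i, tr in enumerate(trajs)}
        for tid in trapped:
            tr = by_id[tid]
            try:
                ex = trap.estimate_stiffness(tr.x, kT=config.kT, axis="x")
                ey = trap.estimate_stiffness(tr.y, kT=config.kT, axis="y")
            except ValueError as exc:  # e.g. degenerate position variance
                logger.warning("trap report for track %s failed: %s", tid, exc)
                reports[str(tid)] = {"error": str(exc)}
                continue
            reports[str(tid)] = {"kappa_x": ex.kappa, "sigma_x": ex.sigma,
                                 "kappa_y": ey.kappa, "sigma_y": ey.sigma,
                                 "kT": config.kT, "method": "variance"}
        (outdir / "trap_report.json").write_text(json.dumps(reports, indent=2))
        summary["trap_report"] = "trap_report.json"

    for tid in config.spectrogram_tracks:
        tr = next(t for i, t in enumerate(trajs)
                  if t.meta.get("track_id", i) == tid)
        if tr.beta is None:
            logger.warning("track %s has no orientation signal", tid)
            continue
        sig = timefreq.unwrap_axial(tr.beta)
        freqs = np.arange(config.spectrogram_fmin, config.spectrogram_fmax + 0.5, 1.0)
        spec = timefreq.cwt(sig, tr.fps, freqs, h=config.spectrogram_h)
        ridge = timefreq.extract_ridge(spec)
        pd.DataFrame({"t_s": ridge.times, "peak_freq_hz": ridge.peak_freq}).to_csv(
            outdir / f"ridge_track{tid}.csv", index=False, float_format=FLOAT_FORMAT)
        np.savetxt(outdir / f"spectrogram_track{tid}.csv", spec.magnitude,
                   delimiter=",", fmt=FLOAT_FORMAT)

    manifest = {"config": asdict(config), "summary": summary,
                "versions": _versions()}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return summary


def _versions() -> dict:
    import numpy, pandas, scipy, skimage

    from . import __version__

    return {"bacmotil": __version__, "numpy": numpy.__version__,
            "scipy": scipy.__version__, "pandas": pandas.__version__,
            "scikit-image": skimage.__version__}
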