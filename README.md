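# bacmotil

Simulation, tracking, motility classification and optical-trap calibration for
single swimming bacteria imaged at high frame rate.

`bacmotil` covers the analysis chain of a fiber-optical-tweezers motility
experiment end to end:

1. **synth** — generate ground-truth trajectories (fractional Brownian
   motion for passive floaters, run / run–wrap–reverse swimmers with flagellar
   wobble, exact Ornstein–Uhlenbeck motion in a harmonic trap) and render them
   into noisy 16-bit video stacks.
2. **track** — detect bacteria per frame (determinant-of-Hessian blobs),
   localize them to sub-pixel precision with elliptical-Gaussian fits (a twin
   two-lobe model with AICc selection handles dividing cells/chains), and link
   detections into tracks by gated greedy nearest-neighbour matching.
3. **motility** — mean-squared displacement and power-law fits, windowed mean
   speed, the speed autocorrelation function and its FBM model fit, reversal
   detection, and a four-class label: `floating`, `running`, `rwr`
   (run–wrap–reverse), `trapped`.
4. **trap** — equipartition stiffness κ = k\_BT/σ², normalized trapping
   efficiency κ̃ (pN/µm/W) with saturation flagging, chain stiffness profiles,
   and the Stokes-drag force budget for a prolate spheroid.
5. **timefreq** — complex Morlet continuous wavelet transform of the body
   orientation signal, spectrogram and peak-frequency ridge (wobble frequency
   vs. time, gaps at reversals).
6. **pipeline / CLI** — the `bacmotil` command ties these into a reproducible
   run that writes `tracks.csv`, `features.csv`, `trap_report.json`,
   optional spectrograms, and a manifest with configuration and versions.

## The physics in one paragraph

A passive micron-sized particle in water performs (fractional) Brownian motion
with MSD(τ) = 2dKτ^α; a swimmer is ballistic (α → 2) on short times. The
windowed-speed autocorrelation C(ξ) of an FBM process has the closed form
C(ξ) = {(ξ+1)^α + |ξ−1|^α − 2ξ^α}/2, so the pair (C1 = C(1), α\_c) separates
self-propelled cells (C1 > 0.45 **and** α\_c > 1.52) from floaters; detected
~180° reversals refine `running` into `rwr`. In a harmonic optical trap the
position histogram is Gaussian, P(ζ) = N·exp(−κζ²/2k\_BT), so the stiffness
follows from the measured variance. The drag coefficient of a bacterium
(prolate spheroid, a = 0.5 µm, b = 1 µm) is γ0 = 4πηb/[ln(2b/a) − ½]
≈ 1.42×10⁻⁸ Ns/m, which converts observed speeds into flagellar propulsion
forces and trap displacements.

## Worked example

Classify a synthetic four-class set (two trajectories per class, 3000 frames
at 500 fps):

```python
from bacmotil import synth, motility

trajs = synth.gen_class_set(2, seed=7, n_steps=3000)
for tr in trajs:
    mc = motility.classify(tr)
    f = mc.features
    print(f"{tr.meta['class']:>9s} -> {mc.label:>9s}  C1={f['C1']:+.2f}  "
          f"alpha_c={f['alpha_c']:.2f}  reversals={f['n_reversals']}")
```

prints

```
 floating ->  floating  C1=-0.08  alpha_c=0.87  reversals=0
 floating ->  floating  C1=-0.06  alpha_c=0.93  reversals=0
  running ->   running  C1=+0.95  alpha_c=1.96  reversals=0
  running ->   running  C1=+0.98  alpha_c=1.98  reversals=0
      rwr ->       rwr  C1=+0.96  alpha_c=1.97  reversals=3
      rwr ->       rwr  C1=+0.96  alpha_c=1.97  reversals=3
  trapped ->   trapped  C1=-0.29  alpha_c=0.62  reversals=0
  trapped ->   trapped  C1=-0.08  alpha_c=0.90  reversals=0
```

The force budget from the command line:

```bash
$ bacmotil trap forces --v 20 --kappa 0.14
{
  "gamma0_Ns_m": 1.4178551918665878e-08,
  "F_flag_pN": 0.28357103837331754,
  "delta_x_um": 2.025507416952268
}
```

A full video-to-report run:

```bash
bacmotil simulate --class running --n-frames 1000 --seed 3 --out demo.tif
bacmotil run --video demo.tif --outdir demo_out
```

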