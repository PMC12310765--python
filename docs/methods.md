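# Methods

Models, conventions, defaults and numerical choices used throughout
`bacmotil`. Units are µm, seconds, pN, Hz and pN/µm unless noted; thermal
energy defaults to `KT_ROOM = 4.05e-21 J` (~293 K).

## Trajectory container

`Trajectory(t, x, y, beta=None, meta={})` holds a uniformly sampled 2-D path
(µm) with an optional axial body orientation β ∈ (−90°, 90°]. Uniform spacing
is validated on construction; `dt` and `fps` derive from `t`.

## Synthetic generators (`synth`)

### Fractional Brownian motion (floaters)

Increments are fractional Gaussian noise with autocovariance
γ(k) = ½(|k+1|^{2H} − 2|k|^{2H} + |k−1|^{2H}) (unit variance per step, Hurst
exponent H), scaled so the per-component MSD is 2K·τ^{α} with α = 2H.
Synthesis uses the exact Cholesky factor of the covariance matrix for
n ≤ 4096 steps and Davies–Harte circulant embedding above; factors are
memoized per (H, n). x and y components are independent. Defaults:
H sampled from {0.30 … 0.50}, K ~ logU(0.5, 3) µm²/s^α in the class set.

### Run / run–wrap–reverse swimmers

Heading φ(t) = φ_rw(t) + A sin(2πf t + φ₀): a rotational-diffusion random
walk (D_rot = 0.1 rad²/s) plus a sinusoidal wobble from flagellar rotation
(f = 30–40 Hz, A = 10–20°). Speed is constant (20–100 µm/s) except during
reversals: run times are exponential (`reversal_rate`, default class-set
value 0.7 s⁻¹), each reversal pauses the cell for `reversal_pause` (0.15 s)
and flips the heading by 180° ± 15°. Reversal times are recorded in
`meta["reversal_times"]`. β is the axial projection of the heading.

### Trapped cells (Ornstein–Uhlenbeck)

Exact discretization x⁺ = c·x + σ_st·√(1−c²)·ζ with c = exp(−κ dt/γ0) and
stationary width σ_st = √(k_BT/κ); no time-step bias at any dt. Default drag
γ0 = 1.42×10⁻⁸ Ns/m (see force budget).

### Rendering

Scenes are 256×256 px, 0.26 µm/px, 500 fps, 16-bit, background 100 counts,
Gaussian read noise (σ = 200 for the SNR-10 fixtures). A bacterium is an
elliptical Gaussian (amplitude 2000, σ_long = 2.2 px, σ_short = 1.2 px,
rotated by β); chains/dividers render as twin circular Gaussians. Rendering
is local-window (±4σ) for speed and warns on clipping.

**Realism limits.** No photobleaching, motion blur, depth defocus, or pixel
Poisson statistics; noise is additive Gaussian. Swimmer speed is piecewise
constant; real cells accelerate out of reversals. These simplifications do
not affect the closed-form acceptance numbers and make round-trip truth
exact.

## Tracking (`track`)

- **Detection**: scikit-image determinant-of-Hessian blobs on the
  min–max-normalized frame.
- **Localization**: bounded trust-region least squares
  (`scipy.optimize.least_squares`, xtol = ftol = 1e-10, max_nfev = 5000) of
  B + A·exp(−(u²/2σ_a² + w²/2σ_b²)) in a 17×17 px ROI; widths returned
  ordered σ_long ≥ σ_short, β normalized to (−90°, 90°], circular spots
  ((σ_a−σ_b)/σ_a < 1e-4) report β = 0.
- **Twin model**: two equal-width circular Gaussians, orientation initialized
  from image second moments, flagged degenerate when separation < 0.5σ.
  Model choice single-vs-twin is by AICc on the ROI residuals.
- **Linking**: greedy nearest-neighbour, candidates sorted by distance with
  deterministic tie-breaking; the gate is 3 × spot size (size = 2σ_long).
  No gap closing; tracks shorter than `min_track_len` (default 200 frames)
  are discarded. Conflicting matches fragment rather than swap identities.
- **Precision convention**: localization precision is quoted as pooled
  per-coordinate RMSE (x and y errors pooled), the standard single-molecule
  localization convention. At SNR 10 this is ≈ 0.09 px, inside the < 0.1 px
  criterion; the 2-D radial RMSE is √2 larger by definition.

## Motility features and classification (`motility`)

- **MSD**: time-averaged over all origins by default (single-origin
  optional), lags up to N/4; power-law fit MSD = 2dK·τ^α (d = 2) by least
  squares in log–log space.
- **Windowed speed**: v̄_j = |r_{j+n} − r_j| / (n dt) with n = 25 for the
  speed feature, n = 7 for the autocorrelation.
- **Speed autocorrelation**: C(ξ = k/n) with numerator and denominator sums
  over the same index range j = 1 … N−n−k, so C(0) = 1 exactly and n = 7
  gives exactly 8 points in ξ ∈ [0, 1].
- **FBM model**: C^FBM(ξ) = {(ξ+1)^{α_c} + |ξ−1|^{α_c} − 2ξ^{α_c}}/2 fitted
  over ξ ∈ (0, 1] with α_c ∈ (0, 2]. C1 is the *measured* C(ξ=1) (the fitted
  value is exposed as `C1_fitted`); C1 = (2^{α_c} − 2)/2 under the model, so
  sign(C1) = sign(α_c − 1).
- **Decision rule**: `running` requires C1 > 0.45 **and** α_c > 1.52
  (both thresholds, by default); detected reversals promote `running` to
  `rwr`; confinement overrides to `trapped`; everything else is `floating`.
- **Reversals**: compare displacement directions in 0.05 s windows before and
  after each sample, flag angle changes > 120° at speed > 20 µm/s, merge
  contiguous flags, and suppress re-triggers within a 0.1 s guard. The guard
  (a free design parameter) must exceed the reversal pause so the
  post-reversal window clears the stationary wrap phase.
- **Trapped detector (design decision)**: a literal sliding-window rule
  ("1 s window RMS < 0.5 µm while neighbouring segments exceed it") misfires
  on quiet floaters and misses records that are trapped throughout. The
  implemented rule labels a track confined if the full-record RMS spread is
  < 2× the confinement radius (anchored case), or if a confined 1 s window
  coexists with a clearly moving one (> 4× radius). This is the package's own
  choice; thresholds live in `motility.Thresholds`.

## Trap calibration (`trap`)

- **Equipartition**: κ = k_BT/σ² from the position variance
  (κ[pN/µm] = k_BT[J]·10¹⁸/σ[µm]²); σ = 71 nm → κ = 0.8 pN/µm. A
  `histogram_fit` variant fits the Boltzmann Gaussian
  P(ζ) = N·exp(−κζ²/2k_BT) to a Freedman–Diaconis histogram.
- **Normalized efficiency**: κ̃ is the through-origin slope of κ vs laser
  power (pN/µm/W). Saturation is flagged when high-power points fall > 20 %
  below the low-power linear prediction; flagged points are excluded from the
  slope, and `power_cutoff_mw` forces a manual cutoff. κ̃ = 13.6 pN/µm/W at
  10 mW gives 0.14 pN/µm; the annular-beam/Fresnel-lens ratio 13.6/0.31
  exceeds 40.
- **Force budget**: prolate-spheroid drag γ0 = 4πηb/[ln(2b/a) − ½] with
  a = 0.5 µm, b = 1 µm, η = 10⁻³ Pa·s gives 1.42×10⁻⁸ Ns/m; propulsion force
  F = γ0·v is 0.3 pN at 20 µm/s and 1.4 pN at 100 µm/s; trap displacement
  Δx = F/κ gives 2.9 µm for 0.4 pN at 0.14 pN/µm. The formula requires
  b > a > 0 and η > 0 (ln(2b/a) > ½ is then automatic).
- **Chains**: per-member equipartition profile with a `harmonic_valid` flag;
  members far from the trap waist violate the harmonic assumption.

## Time–frequency analysis (`timefreq`)

Complex Morlet wavelet w(t) = exp(i2πft)·exp(−4 ln2·t²/h²) with h the
envelope FWHM in seconds (default 0.15 s; h = n_c√(2 ln2)/(πf) for an
n_c-cycle wavelet). The transform uses reflection padding, FFT convolution,
and a 2/Σ|w| normalization so a unit-amplitude sinusoid produces magnitude
≈ 1 at its own frequency. Frequencies above Nyquist raise; requests below
10 Hz (or records shorter than 50 ms) warn as unreliable. The ridge is the
per-time argmax, masked to NaN where the column maximum falls below 20 % of
the global maximum — oscillation gaps (reversals) therefore interrupt the
ridge. Orientation input should be unwrapped with `unwrap_axial`
(period-180° unwrap).

## Pipeline determinism and problem sizes

All generators take explicit seeds; repeated `run_pipeline` calls produce
byte-identical `features.csv` (`%.6g` float format). Typical costs on one
CPU: 100 trajectories × 3000 steps classify in ~15 s (fGn factors cached);
the full test suite runs in well under the 25-minute budget; the 10
acceptance-criteria tests take ~25 s.

## Known limitations

- Linking has no gap closing or motion model; dense crossings fragment.
- The twin model assumes equal-intensity lobes.
- Thresholds (0.45, 1.52, speed gates, confinement radius) are treated as
  given constants; their derivation is outside the package's scope.
- Classification assumes 500 fps-scale sampling; at low frame rates the
  windowed-speed statistics change meaning.
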