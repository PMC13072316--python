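# Methods

## The measurement model

Breathing displaces the bird's body outline by a sub-pixel amount
δ(t) ≈ a·sin(2πf_r t) with a ≲ 0.5 px at typical camera working
distances and f_r ∈ [0.3, 3.0] Hz across growth stages and heat loads.
Direct intensity differencing cannot resolve such motion against sensor
noise; local *spatial phase* can. A 1-D intensity profile under global
translation, f(x + δ(t)), decomposes into complex sinusoids
A_ω e^{iω(x+δ(t))}, so each frequency component carries the displacement
in its phase, scaled by ω. The pipeline operationalises this in 2-D with
a complex steerable pyramid and reads the breathing frequency from the
temporal spectrum of the phase.

The stages, their parameters, and the reasoning behind every default:

### Quiet-state screening

Dense optical flow (iterative Lucas–Kanade, `scikit-image`) is estimated
between frame pairs inside the body bounding box, summarised per pair as
the median flow vector over gradient-bearing pixels (flat interior pixels
carry no displacement information and would bias the median toward zero).
Signed vectors are integrated into a trajectory; a 10-s window's
*amplitude* is the largest excursion of that trajectory from the window's
first frame, and the window is quiet iff amplitude ≤ 1.5 px.

The amplitude definition matters: summing unsigned per-frame magnitudes
would let zero-mean respiratory motion (≤ 0.5 px) accumulate over 300
frames and trip the threshold, rejecting exactly the birds we want.
Trajectory excursion is bounded by the motion amplitude for zero-mean
motion and grows linearly for drift — the intended discrimination. A
telescoping argument shows temporal striding of the flow pairs (default:
every 3rd frame, i.e. 10-Hz motion sampling, displacements spread
uniformly over the spanned frames) cannot create spurious drift from
oscillatory motion; it only smooths the excursion peak. Flow runs on 2×
down-sampled crops (displacements rescaled); measured accuracy on 1-px
synthetic shifts is ~10⁻³ px, far inside the ≤ 0.2-px contract the
screening threshold needs. Window stride defaults to 1 s.

### Complex steerable pyramid

Frequency-domain polar-separable filters: octave-spaced radial
raised-cosine bands (transition over one octave in log₂ r) crossed with
cos⁷ angular windows, K = 8 orientations over 180°. Oriented filters are
analytic — single half-plane, scaled by √2 — so coefficients are complex
and arg(S_ω) is local spatial phase. With the normalisation
α_K² = 2^{2(K−1)}/(K·C(2K−2, K−1)) the squared filter moduli tile the
frequency plane exactly: the bank is a tight frame and
`reconstruct(build(f))` is exact to float round-off (measured ~5·10⁻¹⁶,
asserted ≤ 10⁻⁴). cos^{K−1} is the *sharpest* exponent that tiles
exactly for K orientations, which fixes the orientation selectivity:
adjacent bands receive cos¹⁴(22.5°) ≈ 0.33 of a grating's dominant-band
energy, non-adjacent bands essentially none.

Levels adapt to frame size as clamp(⌊log₂ min(H, W)⌋ − 4, 1, 4), keeping
the coarsest band supported on ≥ ~16-px structure: 480×640 frames get 4
levels, ROI crops get 1–2. All bands are held at full resolution —
sub-sampling would complicate per-pixel phase time series for no memory
benefit at ROI scale. The per-clip stack caches frame FFTs and
synthesises one sub-band time series at a time; on small crops (often
awkward prime dimensions) the inverse transform is evaluated as two small
DFT-matrix products, which BLAS executes faster than per-slice Bluestein
FFTs.

Phase is unwrapped *temporally only* (per pixel, successive differences
kept in (−π, π]); spatial unwrapping is never needed because each pixel
is its own sensor. Pixels whose time-mean amplitude falls below
10⁻⁶ × frame max are excluded: the phase of a near-zero complex number is
noise, and its unwrapped series is a random walk with a strong
low-frequency spectrum that would otherwise leak into the respiratory
band.

### Temporal filtering and amplification

The ideal band-pass is a hard DFT mask keeping |f| ∈ [0.3, 3.0] Hz
(absolute bandwidth 2.7 Hz) and zeroing DC — applied to the unwrapped
phase, whose motion term is continuous by construction. The filtered
phase B_ω = ω·δ(t) is scaled so the represented displacement is
(1+α)·δ(t) with α = 40: adding α·B to the sub-band phase shifts the
pattern by α·δ more, and the stored motion signal is therefore
(1+α)·B. The gain is exact and linear, verified end-to-end on an
analytic grating (ratio 41.000 at α = 40 vs α = 0). The magnified video
itself is never rendered; only the frequency content matters downstream,
and skipping reconstruction avoids its distortion entirely.

### Aggregation

Thousands of per-pixel series must become one signal. Phase sign depends
on the local gradient direction — opposite edges of a moving blob swing
in antiphase — so naive averaging cancels. Each series is folded into an
amplitude²-weighted running mean in descending weight order, flipped when
negatively correlated with the mean so far. Amplitude² weighting is the
natural choice: phase noise variance scales as 1/A², so this is
inverse-variance weighting. The thoracodorsal and tail ROIs are pooled by
default (`roi_mode=fused`) because both surfaces move with the same
rhythm; `separate` averages per-ROI signals instead.

### Spectral estimation

Magnitude spectrum of the mean-removed signal, rectangular window,
one-sided. The peak-validity rule keeps only bins inside 0.3–3.0 Hz and
takes the global in-band maximum as the RR; ties break toward the lower
(physiologically conservative) frequency. A 10-s window at 30 fps gives
0.1-Hz native resolution; 3-point parabolic interpolation of the
log-magnitude around the peak (default on) refines clean tones to
≤ 0.02 Hz. Refinement is skipped when the neighbour bins are at
numerical-noise level (< 10⁻⁹ of the peak), so exact-bin tones stay
bin-perfect. An optional SNR floor (peak ≥ 5× in-band median,
default off) rejects noise-only spectra instead of returning their
argmax.

## The synthetic generator

The generator renders what the pipeline consumes from real footage and
nothing more: a warm ellipse (default 100×60 px in a 120×160 frame,
contrast 60 units over a 20-unit background, slightly warmer head end)
whose boundary undulates radially on two smooth arcs — thoracodorsal
(top, ±40°) and tail (rear, ±30°), in phase by default, antiphase
switchable to stress-test sign alignment. The edge is an analytic sigmoid
of signed radial distance (scale 0.75 px, ≈ 3-px transition), so
sub-pixel displacement is exact rather than interpolated — interpolation
artifacts would confound the (1+α) gain measurement. Breathing amplitude
defaults to 0.2 px (0.05–0.5 px is the plausible range at working
distance and is swept in tests); Gaussian sensor noise defaults to
0.5 units; optional whole-body drift (px/s) and half-cosine motion bursts
exercise the screening stage. Frames are rendered on a fixed-point 1/64
grid for platform-independent determinism.

Cohort presets draw per-bird true RR from N(mean, 0.12 Hz) truncated to
[0.3, 3.0] Hz — 0.12 Hz being the between-bird spread of manual counts —
with stage means at the control temperature of 1.1 (brooding), 0.9
(growing) and 0.6 Hz (fattening), and heat-stress means of
1.1/1.6/2.1/2.7 Hz (brooding at +0/+2/+4/+5 °C), 0.6→0.9 Hz (fattening,
+50 %). The growing +5 °C mean (1.8 Hz, +100 %) and the intermediate
+2/+4 °C points for growing/fattening are linear interpolations between
reported endpoints — the sources print only the anchors. Ages are drawn
uniformly per stage (4–14, 15–24, 25–36 days).

**What the simulator does not emulate** — and what passing tests
therefore do not show about real data: feather texture and its specular
flicker, multiple birds and occlusion, camera auto-gain, radiometric
temperature, panting posture changes, and detection errors (ROIs are
exact by construction). Results on synthetic cohorts bound the *method's*
error, not field performance.

## Problem sizes

Cohort studies use 12-s clips (one full 10-s screening window plus
margin) at the default 120×160 frame — a single-bird ROI view rather
than the full 640×480 cage view, which the pipeline would process
identically after detection. Acceptance and cohort tests run n = 30
birds per stage. Single-clip examples use the 60-s default duration only
where the screening logic (burst recovery) needs the extra length.

## Design choices that were genuinely open

- **Fallback detection** (learned detectors are out of scope): intensity
  quantile threshold (default 0.7) → largest connected component → body
  box split along its major axis into thirds; middle third =
  thoracodorsal, the end third farther from the brighter (head) end =
  tail. Deterministic and translation-equivariant; a stand-in, not a
  tracker.
- **Pseudo-color collapse**: nearest-neighbour lookup against a bundled
  256-entry rainbow LUT, returning the palette index as a monotone
  intensity proxy. Synthetic fixtures are grayscale, so no test depends
  on the LUT matching any particular camera.
- **fps precedence**: caller override > container metadata > error —
  thermal exports routinely carry wrong rate metadata, and a wrong rate
  silently rescales every frequency in the pipeline.
- **Bland–Altman sign**: bias = mean(algorithm − manual).
- **MAPE denominator**: the manual value.
- **Identity-line R²**: 1 − Σ(y−x)²/Σ(y−ȳ)², deliberately *not* a
  regression R² — a constant inter-method offset lowers it even at
  perfect correlation. The age-trend fit reports the ordinary regression
  R², and the two are kept distinct in the API.

## Known limitations

- Harmonic ambiguity: a strongly non-sinusoidal breath at f could in
  principle present its 2nd harmonic as the in-band maximum; the
  band-max rule does not disambiguate (out of scope).
- The flow summary assumes one dominant rigid motion inside the body
  box; two birds in one box violate it.
- Parabolic refinement assumes an isolated peak; closely spaced
  interference within one bin of the breath peak biases it.
- AVI/MP4 ingestion requires an imageio video backend at run time; the
  lossless TIFF/frame-directory path is the fully tested route.
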