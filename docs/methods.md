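# Methods

## Problem and pipeline

Plants move their leaves on a daily cycle driven by the circadian clock,
and under constant light the period of that movement is a standard proxy
for clock period.  `leafmotion` estimates circadian period from
time-lapse image stacks in three stages:

1. **cropgrid** — each camera frame holds many seedlings; a fixed grid of
   named rectangles (drawn once, against the first and last frame of the
   series so growth never carries a plant out of its cell) splits the
   stack into per-plant sub-stacks.  Crops are pure array slices:
   pixel-exact, no resampling.
2. **motion** — for every consecutive frame pair of a plant's sub-stack,
   a single 2-D translation is estimated by differential (gradient-based)
   motion estimation.  The vertical component per frame step, `v_y(t)`,
   is the rhythm signal.  Working on whole-plant crops means cotyledons
   and emerging true leaves contribute jointly to one waveform per plant;
   no leaf has to be selected or tracked individually.
3. **period** — `v_y(t)` is linearly detrended, an initial period is read
   off a zero-padded FFT periodogram, and a single-frequency cosine model
   is refined by Nelder-Mead in the root-mean-square sense.

A **qc** stage filters per-plant estimates and aggregates per line, and a
**synth** module generates the validation inputs.

## Motion model

Between frames `f(x,y,t-1)` and `f(x,y,t)` the region of interest is
assumed to translate rigidly.  Linearizing the squared brightness
constancy error with a first-order Taylor expansion gives a quadratic in
the motion vector `v = (v_x, v_y)`, minimized by the 2x2 normal-equation
solve

    M v = b,    M = Σ_Ω f_s f_sᵀ,    b = Σ_Ω f_s f_t,

with `f_s = (f_x, f_y)` the spatial gradient and the sums over the ROI Ω.
Derivatives use separable two-tap filters, derivative `d = (0.5, -0.5)`
and prefilter `p = (0.5, 0.5)`: spatial derivatives act on the average of
the two frames and are smoothed with `p` along the other axis; the
temporal derivative is the half-difference smoothed with `p` along both
axes.  Only the valid convolution region is kept (output one pixel
smaller per axis); no boundary padding is invented.  Both spatial and
temporal derivatives carry the same 0.5 scale, so the solve is unaffected
by it.

Numerical choices:

* **Sign convention.** The solve is negated so that the reported vector
  is the displacement of the image content from the earlier to the later
  frame: a pattern moving one pixel down (+y in image coordinates) gives
  `v_y = +1`.  Display code may negate `v_y` to plot "upward leaf
  movement" as positive; the stored series never flips.
* **Conditioning.** M is singular on textureless regions.  A pair is
  declared untrackable when M's smallest eigenvalue falls below
  `1e-9 x (ROI pixel count)` or its condition number exceeds `1e8`.
  Untrackable pairs are recorded as missing, filled by linear
  interpolation from neighboring pairs, and flagged — interpolation
  preserves the uniform time grid the FFT needs without biasing the
  solve (ridge regularization would).  A stack with no trackable pair at
  all raises.
* **ROI default.** The full valid region of the (already per-plant
  cropped) frame.  A sub-rectangle can be passed when a crop contains
  clutter.
* **Single-shot solve.** The estimator is the one-step linearized solve;
  there is no coarse-to-fine pyramid or iterative warping.  It is
  accurate for per-step motion up to ~1-2 px (validated against a
  brute-force SSD grid search to within 0.05 px, typically 0.005 px) and
  degrades monotonically beyond; at 20-minute frame intervals, leaf
  movement sits comfortably inside this regime.  A pyramid is a possible
  extension, not default behavior.
* **No pre-smoothing.** Frames are used as loaded (grayscale, [0,1]);
  the `p` prefilters inside the derivative stencils provide the only
  smoothing.

## Period model

The vertical-motion series (per-pair velocities at frame-pair midpoint
times — the velocity series itself, not its cumulative sum) is fit in
two steps:

1. **Initialization.** After OLS line removal, the magnitude spectrum of
   the series (zero-padded 4x) is maximized over a plausible circadian
   band, default 16-36 h.  Without padding a 120 h record has ~4.8 h
   period resolution near 24 h — too coarse a start; with 4x padding the
   grid is ~1.2 h, well inside the refinement's basin of attraction.
   The band is deliberately wider than the downstream 18-32 h QC gate so
   the estimator is not clipped before QC sees it.
2. **Refinement.** Nelder-Mead minimizes the RMS residual of

       y(t) ≈ offset + slope·t + A·cos(2πt/τ + φ)

   over `(τ, φ, A, offset, slope)`, started at the periodogram period
   with `(A, φ)` from the complex single-frequency DFT coefficient at
   that period, `offset` at the trace mean and `slope` at 0.  Settings:
   `xatol 1e-6`, `fatol 1e-12`, at most 2000 iterations, initial simplex
   perturbation 2% per parameter.  The returned RMS never exceeds the
   starting cosine's (the simplex only ever keeps improvements), and the
   optimizer's own success flag is passed through as `converged`.

**Why the model refits a baseline it just detrended.**  Pre-detrending
uses the OLS line of the *data*; when the record holds a non-integer
number of cycles, the OLS line of the cosine component itself is not
zero, so detrending leaves a small residual line behind.  A cosine-only
fit can lower the residual by tilting the period — a bias we measured at
+0.017 h for a noise-free 25 h cosine and -0.15 h at 36 h over a 120 h
window.  Re-estimating `offset + slope·t` jointly with the cosine makes
the estimator exact on noise-free cosines (< 1e-5 h error anywhere in
the band) at a modest variance cost at very low SNR.  On detrended input
both baseline terms converge to ~0.

The estimator was checked against a fine profile grid search (closed-form
linear least squares for `(A, φ, offset, slope)` at each trial period,
0.05 h spacing): both return the same optimum, i.e. Nelder-Mead from the
padded-FFT start reliably finds the global single-frequency NLLS
solution.  At high noise the estimates' scatter matches the
information-theoretic limit for this model; the residual mean deviations
seen in 10-replicate experiments at noise sd equal to the signal
amplitude (~±0.1 h) are sampling noise, not bias (measured bias ≤ 0.015 h
at 100 replicates).

## Quality control

Per-plant fits with period below 18 h or above 32 h are removed (bounds
inclusive: exactly 18.0 or 32.0 h is kept).  Retained estimates are
aggregated per line; SEM uses the sample sd (n−1) over √n, and a line is
excluded when SEM exceeds 0.50 h (30 min) — SEM is the precision gate on
the line-level phenotype handed to downstream QTL software (which is out
of scope here).  Lines with a single retained estimate are excluded
rather than passed with SEM 0: the precision certificate is undefined at
n = 1.  The bounds filter runs before the SEM gate; both removals are
logged so the accounting conserves every input estimate.

## Synthetic data

**Traces.** `simulate_trace` draws

    y(t_i) = exp(-r·i)·cos(2π t_i/τ) + ε_i,    ε_i ~ N(0, σ²) iid,

on an inclusive uniform grid (default 20-minute sampling over 120 h, 361
samples — the standard "image every 20 minutes for 5 days" protocol).
Amplitude trends I/II/III set the per-sample decay rate r to 0, 0.001,
0.002 (at r = 0.002 the envelope roughly halves over 5 days — visually
plausible damping for leaf movement as petiole growth slows); noise
levels A/B/C set σ to 0.2, 0.6, 1.0 in units of the initial amplitude
(1).  The envelope is taken exponential and the noise Gaussian; a linear
envelope or heavier-tailed noise would be easy swaps but are not
defaults.  Replicate k of a condition uses the stream seeded by
`(condition_seed, k)`; grid generation derives one sub-seed per condition
from a base seed, so the whole 27-condition x 10-replicate recovery
experiment is reproducible from one integer.

**Image sequences.** `simulate_image_sequence` renders a Gaussian-profile
elliptical blob (default σ_y x σ_x = 12 x 8 px in a 120x120 px frame,
matching the ~100x100 px-per-plant imaging guideline) whose vertical
center follows `y0 + A·cos(2πt/τ)`.  The profile is evaluated
analytically at pixel centers, so subpixel positions are exact and blob
mass is conserved to <1% across frames.  Construction rejects scenes
whose implied per-step displacement exceeds 2 px (outside the
small-motion regime) or whose foreground/background contrast is under
5x the pixel noise sd.

**What the simulator does not emulate** — and hence what passing tests do
not show about real data: growth and shape change of the plant between
frames (the translation model sees pure rigid motion here), occlusion and
overlap of neighboring leaves, illumination drift, camera vibration,
JPEG artifacts, and non-stationary noise.  The validation therefore
certifies the estimation chain on its stated model class, not robustness
to every field condition; the design of the original imaging protocol
(black background, fixed focus, watering to suppress soil motion)
exists precisely to push real data toward this model class.

## Problem sizes and runtimes

The recovery experiment regenerates all 27 conditions x 10 replicates
(2,700 fits of 361-sample traces run in well under a minute); the
pipeline validation renders two 361-frame 120x120 px sequences and
recovers their 24 h and 25 h periods to well under 0.1 h; the motion
validation compares 50 random subpixel shifts against a brute-force SSD
oracle at ~3e-4 px grid resolution.  All sizes match the validation
design the simulator encodes; none are reduced.

## Known limitations

* One translation per frame pair: rotation, shear and per-leaf motion
  fields are out of scope (a dense flow field is a debug visualization at
  most, not an output).
* Per-step motion beyond ~2 px biases the estimate toward zero; very
  fast movers need shorter frame intervals rather than algorithm changes.
* The period model is a single frequency; multi-component rhythms are
  deliberately not modeled (the motion series is clean enough that one
  frequency suffices, and the trace CSVs can be exported to external
  rhythm-analysis platforms when more is wanted).
* A 10-replicate mean at noise sd equal to the signal amplitude still
  carries ~0.1 h sampling error in the mean — experiment designs that
  need tighter line means should image more plants per line, which is
  exactly what the SEM gate enforces downstream.
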