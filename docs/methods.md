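# Methods

## Model

The assay observes single labeled enzymes interacting with a substrate
film. Three processes are modeled:

1. **Landing.** New binding events form a spatio-temporal Poisson process
   with intensity `r · A · C` per unit time, where `r` is the normalized
   landing rate (events·μm⁻²·s⁻¹·M⁻¹), `A` the imaged area (μm²) and `C`
   the solution enzyme concentration (M). The normalized rate is the
   concentration- and geometry-independent observable that compares
   on-rates across enzyme variants.

2. **Residence.** Dwell times follow a two-population mixture. The
   *specific* population is exponential with mean τ_fast; since a bound
   enzyme exits either by unbinding (rate k_off) or by catalysis followed
   by rapid product release (rate k_cat), both memoryless, the fast
   constant measures the apparent off-rate `k_off_app = k_off + k_cat =
   1/τ_fast`. The *nonspecific* population is long-lived sticking of the
   label itself, exponential with mean τ_slow; its apparent duration is
   set by photobleaching/blinking of the emitter rather than
   dissociation, which is why τ_slow shortens with laser power while
   τ_fast does not.

3. **Photobleaching.** An ensemble of immobilized emitters under constant
   illumination loses its population-mean intensity as `I₀·exp(−t/τ_bleach)`
   (+ optional camera baseline). Fitting this decay at several laser
   powers provides the control that identifies the slow dwell phase as a
   photophysical artifact.

The survival function (1 − CDF) of observed dwells is fit as

    S(t) = A·exp(−(t − t₀)/τ_fast) + (1 − A)·exp(−(t − t₀)/τ_slow)

with `0 ≤ A ≤ 1`, τ > 0, and `t₀` the shortest observable dwell.

## Key parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `frame_interval` | 0.2 | s | 5 frames/s acquisition |
| `psf_fwhm` | 300 | nm | diffraction-limited spot size |
| `pixel_size` | 60 | nm | 5-pixel reslice spacing spans one PSF FWHM |
| `output_spacing` | 5 | px | y-band height matched to the PSF |
| `tau_fast`, `tau_slow` | 2.7, 38.6 | s | wild-type-like dwell mixture |
| `fast_fraction` | 0.7 | — | configurable stand-in; relative amplitudes are condition-dependent and not a fixed constant of the system |
| `tau_bleach` | ∞ | s | see below |
| `landing_rate_norm` | 1070 | μm⁻²·s⁻¹·M⁻¹ | wild-type-like on-rate |
| `concentration` | 8×10⁻⁹ | M | enzyme concentration used for normalization |
| `fov_width/height`, `movie_duration` | 80×80, 600 | μm, s | chosen for statistical adequacy (~33 expected events per movie), not measured geometry |
| `k_sigma` | 4 | — | detection threshold, mean + 4·σ_MAD |

`tau_bleach` defaults to infinity because the mixture's slow constant
*already is* the bleach-truncated apparent duration the fits see; a
finite value adds an explicit truncation clock to nonspecific dwells for
control-experiment simulations (the truncation is recorded per event).

## What the generator emulates — and what it does not

Emulated: Poisson landing statistics with uniform positions and times;
frame discretization (a dwell visible in any part of a frame occupies
it, i.e. durations are ceiled to whole frames); boundary censoring;
diffraction-limited Gaussian spots on a constant background with
additive Gaussian noise; population bleaching of emitter ensembles.

Not emulated: EMCCD gain/shot-noise statistics, stage drift, the TIRF
evanescent illumination profile, emitter blinking as a separate process
from bleaching (one truncation clock covers both), spot overlap
resolution, autofluorescent background structure, and any lateral
mobility of bound enzymes. Passing tests therefore demonstrate that the
analysis correctly inverts this statistical model, not that it is robust
to every instrumental artifact of real movies.

## Numerical choices

* **Conditioning at t₀.** Sub-frame dwells are unobservable, so fits
  condition at `t₀ = min_observable` (one frame interval for quantized
  data). For ceiled dwells the empirical survival at `t = kΔ` equals the
  continuous-model value at `t − Δ`, so this choice makes frame
  quantization exactly bias-free for exponential mixtures — no
  half-frame correction is needed.
* **Fitting.** Unweighted nonlinear least squares on the empirical
  survival steps (the convention for 1−CDF plots), `scipy.optimize`
  underneath. Multi-start initialization: τ guesses from the 25th/90th
  dwell percentiles, amplitude 0.5, five jittered restarts; best
  residual wins; failure only if every start fails. Fast/slow labels are
  assigned by sorting after the fit, so the result is invariant to
  permuted starting guesses. Fits with the two constants within 5% are
  flagged degenerate (the data support only one phase).
* **Standard errors.** Default SEs come from the least-squares
  covariance ("fit ± SE of the fit"). Because survival steps are highly
  correlated, those SEs understate replicate-to-replicate scatter
  (observed ~10× at n = 2000); `se_method="bootstrap"` resamples the
  dwell multiset and refits, giving SEs whose ±2SE intervals cover the
  truth in ≳95% of seeded replicates. Use bootstrap SEs whenever the SE
  itself matters.
* **Independent cross-check.** A direct maximum-likelihood mixture fit
  (`fit_biexponential_mle`, Nelder–Mead on logit/log-transformed
  parameters) provides a second route; LS and MLE agree within 5% at
  n = 10⁴ in the test suite. The closed-form exponential MLE (sample
  mean) plays the same role for the mono fit.
* **Detection.** Background threshold is mean + k·σ with σ estimated
  robustly via the median absolute deviation, so sparse bright streaks
  do not inflate it; it is undefined (explicit error) on constant
  images — use Otsu or an absolute threshold for noiseless renders.
  Components are 8-connected in (x, t) so one-pixel column jitter does
  not split an event. Gap tolerance defaults to 0 frames: blinking
  truncates the observed duration by definition, and bridging is opt-in.
* **Censoring.** Events touching the first/last frame are flagged;
  duration analyses exclude them by default, landing counts keep all but
  left-censored events (whose landing was never observed).
* **Projection.** The y-collapse uses max projection by default: binding
  events are focal-limited, and a mean over a 5-row band would dilute a
  one-row spot five-fold. Mean projection is available for parity with
  grouped-average workflows.
* **Photobleach fits** include an additive offset by default (camera
  baseline); the fit is flagged unidentifiable when the decaying
  amplitude is negligible or no curvature falls inside the window.
* **Determinism.** All randomness flows from one integer seed through
  `numpy` `SeedSequence` spawning, so cohorts are bit-reproducible and
  replicate sub-streams independent.

## Problem sizes

Statistical recovery runs use 2000 dwells per replicate and 50 seeded
replicates (dwell-constant recovery), 500 emitters × 600 s traces
(bleach recovery), 5000 dwells (additive-rate identity) and 9-movie
cohorts at ~33 events per movie (landing-rate round trip). Rendered-movie
tests use scaled-down fields of view (8–10 μm at 100 nm pixels) and
minute-scale movies so the imaging path is exercised end-to-end on small
stacks; statistical recovery through the pipeline runs on event lists,
which the run configuration supports as a first-class input precisely so
the statistical core is testable without rendering.

## Known limitations

* The decomposition of k_off_app into (k_off, k_cat) is not identifiable
  from dwell data alone; the package only computes the k_cat upper bound
  and carries user-supplied decompositions.
* Excluding right-censored events biases τ_slow downward when the movie
  is not much longer than τ_slow; survival-with-censoring estimators are
  out of scope.
* Otsu thresholding assumes a bimodal histogram; on signal-free images
  it labels noise, so the false-positive control is defined for the
  robust MAD threshold.
* Dense fields violate the sparse-events assumption behind the
  y-collapse: overlapping streaks merge. Per-band analysis (`reslice`
  without projection) is the escape hatch for crowded data.
* The t-test on per-movie rates assumes approximate normality of
  per-movie means; with very few movies the Welch test is only nominal.
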