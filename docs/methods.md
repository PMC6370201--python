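# Methods

## Detection model

Movement synchrony is operationalized as a locally linear, possibly
time-lagged association between two motion-energy time series (METS)
sampled at 25 fps.  For window start `t` (every `step = 2` frames) and lag
`ℓ` on a grid up to ±`max_lag = 75` frames, the detector associates
`a[t:t+W]` with `b[t+ℓ:t+ℓ+W]`:

- **WCLC** — squared Pearson correlation; significance from the two-sided
  t statistic `r·√((W−2)/(1−r²))` with `W−2` degrees of freedom.
- **WCLR** — within the window, the response `b[i]` is regressed on an
  intercept and `b[i−1]` (autoregressive control); the full model adds
  `a[i]`.  The score is ΔR² = R²_full − R²_base, tested with the F
  statistic for the added predictor on (1, W−4) degrees of freedom (the
  window provides W−1 usable observations and the full model fits three
  parameters).  The exact autoregressive terms of the original MATLAB
  implementation are not published; the AR(1) control is this package's
  documented stand-in.

Windows that would overrun either series are skipped (NaN cells), not
padded.  Both scores are computed by rolling-sum algebra on globally
centered series — Pearson correlation and OLS R² are invariant to a
constant shift, and centered cumulative sums keep float64 cancellation
error far below the 1e-10 oracle-equivalence tolerance the tests enforce.
A window with numerically zero variance raises an error naming the frame:
this only happens when the noise-injection step was skipped.

Positive lag means person B's behavior follows person A's.  Squaring makes
both scores sign-blind: a perfectly anti-correlated window counts as
synchrony.  This is retained deliberately and worth knowing when
interpreting results.

### Lag grid

The grid is zero-centered with spacing `step`: ℓ ∈ {−k·step, …, 0, …,
k·step} with k = ⌊max_lag/step⌋, plus one extra positive endpoint
(k+1)·step when max_lag is not a multiple of step — 76 lags of even parity
for the default (75, 2).  Containing lag 0 (and hence every even lag, in
particular the 50-frame echo used by the artificial condition) matters
more than covering the odd endpoint ±75 exactly: real pulse trains carry
strong frame-to-frame innovation, so the R² ridge of an echoed signal is
sharply peaked *at the true lag* and flat-shouldered beside it.  A grid of
the wrong parity samples only the shoulder and makes the recovered lag
wander.

### Peak-picking

The landscape-to-interval step works per time column: among significant
cells, take the lag maximizing R²; chain consecutive columns while that
lag moves by at most 2 grid steps and stays significant.  A chain over
window starts `[t_first, t_last]` is mapped to the frame span
`[t_first + W − step, t_last + step)` on A's timeline — the window before
`t_first` did not track the ridge, so the event cannot have begun before
`t_first + W − step`, and the window after `t_last` did not, so it ends by
`t_last + step`.  The chain's lag is the argmax of the R² profile averaged
over its columns (a single column's maximum is noisy on a broad ridge; the
average centers on the peak), and `mean_r2` averages the picked cells.
Intervals shorter than 13 frames (~0.5 s) are dropped; the interval-level
cutoff filter keeps intervals with `mean_r2 > r2_cutoff` (strictly).

Two properties of this construction are worth spelling out:

- Neighbouring columns share all but `step` frames of data, so the
  landscape is strongly autocorrelated along time and chance ridges
  persist for many columns.  Their frame span still rarely exceeds the
  bandwidth (so the `span − W` mapping usually erases them), and their low
  mean R² is exactly what the cutoff removes.
- The onset inference assumes a window becomes significant as soon as it
  captures enough of the event.  When the event sits closer than W frames
  to the sequence start (or the lag-shifted window hits the boundary), the
  first trackable column is clipped and the detected interval starts late.
  This is a genuine property of windowed detection and is what makes large
  bandwidths (250, 750 frames) fail on short sequences — visible in the
  validation results as bandwidth dominating every influence statistic.

## Preprocessing

Pipeline order is fixed: transform → smooth → add noise.

- Transforms: raw; ROI-size standardization (the series of the person with
  the smaller region of interest is multiplied by the larger/smaller area
  ratio); log(x+1) (Box–Cox with λ=0 after adding 1 to avoid log 0);
  Anscombe 2√(x+3/8).  All are monotone and map constant windows to
  constant windows — hence the Gaussian noise floor (M = 0, SD = 0.1)
  injected last, which makes every local correlation well defined over
  motionless stretches.
- Smoothing: natural cubic smoothing splines over the frame index in the
  `p·misfit + (1−p)·roughness` convention, so `p = .900` is slight and
  `p = .005` is heavy smoothing.  Implemented via the equivalent Reinsch
  penalty λ = (1−p)/p.  Only curvature is penalized, so exactly linear
  series pass through unchanged at any p (tested to 1e-8).  Smoothed
  values may be negative; they are passed through (transforms have already
  run) rather than silently clipped.  The spline basis and boundary
  conditions are not dictated by anything upstream; the natural cubic
  spline at observed frames is the assumption, and the fitter requires at
  least 5 points.
- Noise seeds derive deterministically from (master seed, dyad id, person,
  config id), so grid runs are reproducible and independent of task order.

## Synthetic data generator

The generator replaces undistributable therapy-session videos and is the
package's definition of the study conditions:

| parameter | default | rationale |
|---|---|---|
| fps | 25 | frame rate of the emulated recordings |
| sequence duration | N(118 s, 12.94 s), min 60 s | matches the emulated material |
| interval duration | N(145, 57.93) frames, clipped [26, 282] | matches the emulated material |
| pulse shape | raised-cosine envelopes, width 10–60 frames, amplitude 5–80 | smooth bursts of realistic scale |
| within-pulse jitter | i.i.d. Gamma(shape 4, mean 1), multiplicative | see below |
| background rate | 2 pulses / 1000 frames / person | sparse non-event movement, ≥40% zero frames |
| ROI areas | base 40 000 px, ratio U(1.03, 1.99) | drives size standardization |
| echo lag | 50 frames | artificial-condition construction |
| embedded copy | lag U(−37, 37), scale U(0.3, 1.5) | "a large movement echoed by a weak one" |
| edge margin | 150 frames | events sit away from sequence ends (the emulated sequences were cut around rated events) |

The multiplicative jitter is load-bearing: frame-differencing pixel counts
fluctuate strongly frame to frame in real recordings, and that
within-movement innovation is (a) what sharpens the R² ridge at the true
lag and (b) what an autoregressive control cannot predict — without it,
smooth envelopes are so self-predictable that WCLR's ΔR² collapses toward
zero even for a perfect echo.  Conversely the log transform *compresses*
the jitter share, which is why WCLR clears the 0.25 cutoff on raw data
more easily than on log-transformed data in this regime.

Per base pair, person A carries the event signal spanning the reference
interval exactly (zero at its endpoints, like interval endpoints snapped
to zero crossings of motion energy); person B either echoes it (sync:
rescaled, small random lag, own jitter) or moves independently within the
same designated interval (nosync).  The three conditions are derived
deterministically: *isolated* zeroes both series outside the interval;
*artificial* replaces B by `a` shifted forward 50 frames (sync) or by
zeros (nosync).  All randomness flows from one master seed through keyed
SeedSequence derivation.

What the generator does **not** emulate: camera noise and compression
artifacts, rater disagreement about interval endpoints, multi-limb
composition of the motion-energy aggregate, and natural lag drift within
an event.  Consequently the embedded-condition concordance numbers of this
synthetic study characterize the generator, not human-rated material, and
passing tests show that the detection stack recovers *constructed* ground
truth — not that it matches human raters.

## Evaluation and study layer

Detected and reference intervals are rasterized to per-frame binary
ratings (kappa is computed over the full sequence at frame resolution).
Cohen's kappa = (p_o − p_e)/(1 − p_e) from the 2×2 table; the degenerate
p_e = 1 case returns 1 for identical series, else 0.  pr_out is the
fraction of flagged frames in no-sync sequences.

Identification-rate boundaries, all in one place (`evaluation.py`): sync
good requires min kappa strictly > .60, acceptable is [.40, .60]
(inclusive at .40, closing the gap between "below .40" and ".41–.60" in
the usual band wording), poor below; nosync good requires max pr_out ≤ 5%,
acceptable (5%, 10%], poor above.  The combined IR is the minimum of the
two classes, so it is good exactly when both sides are.  Sequential
gating: stage 1 keeps good configurations on artificial; stage 2 keeps
stage-1 survivors good-or-acceptable on isolated; stage 3 reports those on
embedded.

Statistics layer: Fisher's exact test is exact (hypergeometric) for 2×2
tables and a seeded Monte-Carlo approximation (10⁵ permutation draws of
the label vector, add-one corrected) for larger tables; Cramér's V =
√(χ²/(N·(min(r,c)−1))).  The ordinal regression is a proportional-odds
logit (statsmodels `OrderedModel`) on dummy-coded families with reference
groups WCLC / raw / none / 75 / 0.25; when gating removes a reference
level the lowest observed level substitutes, and coefficients above 15 in
magnitude (or a non-converged fit) are flagged as complete separation
rather than reported as estimates.  Kruskal–Wallis tests use the
tie-corrected H with mean ranks per sequence; identical values return
H = 0 with a warning instead of an undefined statistic.

## Problem sizes and determinism

The default validation dataset is 10 sync + 10 nosync base pairs × 3
conditions (60 dyads, ~3000 frames each).  The landscape computation is
O(n · n_lags) per configuration and dyad (~60 ms), so the bundled reduced
grids (16–32 configurations) run in minutes on one CPU; the full 600-config
grid is a `--full` flag away.  Every stochastic component — generator,
noise injection, Monte-Carlo Fisher — is keyed to explicit seeds, and equal
seeds reproduce results bit-for-bit.

## Known limitations

- The peak-picker is a documented concretization, not a bit-exact
  replication of the original MATLAB peak-picking code.
- Off-grid lags (odd lags under the default even grid) are detected via
  the ridge shoulder; their recovered lag is the nearest grid point and
  their effective sensitivity is lower.  Embedded-condition copies drawn
  at odd lags are therefore harder to detect — one reason isolated- and
  embedded-condition concordance is low, matching the qualitative finding
  that validation quality degrades with condition complexity.
- Kappa is computed per frame over the whole sequence; with rare positives
  it is dominated by boundary agreement, so short reference intervals are
  scored harshly.
- WCLR's ΔR² depends on the innovation share of the signal; heavily
  smoothed or heavily compressed (log) series push it below useful
  cutoffs.
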