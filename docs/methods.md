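# Methods

This note documents the models, estimators and numerical choices behind
`periotherm`, and what the synthetic phantom can and cannot say about real
thermal video.

## The measurement model

A radiometric thermal camera reports temperature pixels in Kelvin at
0.1 mK resolution; all arithmetic is double precision so that resolution
is never the limiting factor. A trial is a 30 s clip at 15 Hz (450
frames). In half the trials an unexpected auditory stimulus occurs at a
time drawn uniformly from [2 s, duration − 7 s], guaranteeing room for the
2 s analysis windows and the 3 s startle-inspection window on either side.

## Synthetic phantom

The rendered scene is `background + elliptical face plateau + two Gaussian
hot spots` at the inner canthi, with defaults

| parameter | default | rationale |
|---|---|---|
| frame size, rate | 480 × 640 px, 15 Hz | study recording conditions |
| background / face / canthus peak | 295 / 306 / 307.5 K | room ≈ 22 °C, facial skin ≈ 33 °C, canthus scale matching the reported group means |
| canthus σ | 10 px | a 27 × 38 px manual box is drawn snugly around the warm region, so the box spans ≈ ±1.35 σ and most border pixels fall in the coolest half — the premise of the trimmed-mean estimator |
| canthus centres | rows 0.44·H, cols 0.40/0.60·W | the inner canthi flank the nose near the facial midline, well inside the face ellipse |
| sensor noise sd | 0.03 K | typical NETD of a research-grade LWIR camera |
| jitter sd | 0.3 px/frame | integer-pixel random walk; total excursion a few pixels over a trial |
| startle jerk | 6 px, one-frame onset, ~0.4 s out-and-back | a sudden twitch of ~2 mm at this imaging geometry; onset within one frame at 15 Hz |
| startle probability | 0.18 | fraction of stimulus trials with a visible formal startle observed in this kind of protocol |
| drift | 0.05 K rms, 10 s timescale | free parameter (no published magnitude for periorbital drift); large enough that full-trial series are non-stationary by the runs test, as real periorbital series are |
| participant baseline sd | 0.3 K | between-participant variation dominates the between-condition sd of the reported group means |
| effect δ, latency, ramp | 0 K, 0.3 s, 1 s | null model by default; a response, when injected, begins within 300 ms |
| series noise sd | 0.033 K | makes the 2 Hz-filtered 2 s windows have variance ≈ 3 × 10⁻⁴ K², the study scale |

Motion is **integer-pixel** (the continuous jitter walk is rounded), a
deliberate simplification that makes block-matching ground truth exact.
The startle jerk reaches full amplitude within one frame — the property
the detector keys on — and decays over ~0.2 s. Drift is white noise
low-passed at 1/timescale, demeaned and rescaled to the target rms: the
simplest process that defeats stationarity tests without adding structure.
The injected effect ramps linearly from 0 to δ over 1 s starting at
t_stim + 0.3 s, applied to the canthus peak temperature.

Seeding: a single study seed; every trial derives its own substream from
`(seed, participant, session, trial)` so any trial is re-creatable in
isolation, bit-identically. Frame stacks are written as multi-page float32
TIFF with a JSON metadata sidecar (HDF5 is an alternative reader path);
float32 storage keeps ≈0.03 mK precision at 307 K.

A **series-level fast path** (`simulate_mean_series`, `run_series_study`)
models the extracted mean-temperature series directly — baseline +
participant offset + drift + ramped effect + white measurement noise —
skipping rendering and tracking. Statistical calibration experiments
(type-I error, power, stationarity rates) use it; the imaging chain is
exercised separately by the tracking/extraction/detection tests. Problem
sizes used by the shipped experiments (reduced frames 64 × 160 for imaging
tests, 1000 studies of 4 participants × 2 sessions × 10 trials for
calibration) were chosen so the whole suite runs comfortably on one CPU.

### What the phantom does *not* emulate

Sub-pixel motion and rotation, perspective and viewing-angle effects,
emissivity/humidity variation, occlusions (eyewear, blinking), spatially
correlated sensor noise, and physiological structure beyond a single
drift + effect process. Passing tests therefore demonstrate correctness of
the *algorithms* under the stated model, not performance on real faces;
in particular real tracking error is plausibly worse than the exact
recovery achieved on integer-pixel phantoms.

## Tracking

Cross-search block matching with the MSE criterion
(`mse_score = mean((A−B)²)`, units K²). The search evaluates, at each step
size from `max_step` (8, a power of two) down to 2, the four diagonal
(×-shaped) neighbours of the current best, recentring until the centre
wins, then halves the step; the final unit step evaluates the full
8-neighbourhood (the +/× end pattern). Repeating moves at a fixed step
makes every integer displacement reachable while visiting far fewer
candidates than the (2r+1)² exhaustive scan (≤ ~53 vs 289 at r = 8 in
practice); on noiseless phantoms it recovers every |d| ≤ 8 shift exactly
(verified against the exhaustive oracle). Ties break by smallest
Manhattan displacement then row-major order, favouring no motion, making
both searches fully deterministic. Candidate placements that leave the
frame are excluded; if none remain the tracker signals failure.

`track_region` uses a fixed reference block (no re-templating — reference
regions are set once per trial) and the previous frame's position as each
search's centre. Failure rule: winning MSE above 25 × the median winning
MSE of the first 15 tracked frames for 5 consecutive frames (the median is
floored at 1e-9 K² so a noiseless track cannot divide by zero). The
threshold is a convention — the original criterion, "excessive movement
prevented tracking", was qualitative — and `failure_frame` marks the start
of the failing run.

## Extraction

`trimmed_mean_upper` takes the mean of the warmest ⌈N·fraction⌉ pixels
(default fraction 0.5; ties at the boundary are resolved by value only,
which cannot affect the mean). The untrimmed mean (`fraction=1.0`) exists
for illustration but is not part of the pipeline output.

The low-pass filter is a causal single-pass second-order digital
Butterworth (bilinear design) with 2 Hz cutoff: DC gain 1, −3.01 dB at
cutoff. "Second order" is taken literally, so no forward–backward pass;
the startup transient is suppressed by initialising the filter state to
the steady-state response of the first sample.

Windows: pre = [t_stim − 2 s, t_stim], post = [t_stim, t_stim + 2 s], both
endpoints included — 31 samples each at 15 Hz, sharing the boundary sample
at t_stim. The 31-sample convention is supported by the entropy level it
implies: 31 mostly-distinct samples in 1000 bins give a mean entropy of
log₂31 ≈ 4.954 minus an expected tie loss of ≈ 0.03 bits, i.e. ≈ 4.92
bits, which is what the entropy calibration reproduces; a 30-sample window
could never exceed log₂30 ≈ 4.907 bits.

## Window statistics and tests

* Moments: biased (1/n) central moments; skewness g₁ = m₃/m₂^1.5;
  kurtosis on the Pearson scale m₄/m₂² (normal = 3). Short, positively
  correlated windows bias Pearson kurtosis below 3 (≈ 2.25 for these
  windows). Constant windows have undefined skewness/kurtosis, flagged.
* Entropy: 1000 equal-width bins spanning [min, max] with the last bin
  closed; pᵢ = countᵢ/n; 0·log 0 ≡ 0; a constant window has entropy 0.
* Chi-squared normality: k equiprobable bins under Normal(x̄, s) with the
  ML (1/n) scale, k = max(4, ⌊n/5⌋) so every expected count is ≥ 5;
  statistic vs χ²(k−3). At n = 31 this is mildly anti-conservative
  (measured type-I ≈ 0.067 at α = 0.05, the Chernoff–Lehmann effect of
  moment-estimated parameters); reported as is.
* Runs test: dichotomise about the median, drop ties, two-sided normal
  approximation of the Wald–Wolfowitz runs distribution. Fewer than two
  values on either side → indeterminate, flagged.

## Mixed ANOVA

`PeriorbitalAnova(table, measure).fit()` follows the statsmodels
Model/Results idiom. Window (pre/post) and side (left/right) are fixed;
participant is random. Because usable-trial counts differ between cells,
each participant's (window × side) cell means are computed first — the
unweighted-means solution — giving a balanced P × 2 × 2 table whose
classical decomposition keeps the expected-mean-squares denominators
valid: window is tested against window × participant, side against
side × participant, window × side and participant against the three-way
residual (restricted mixed model). With one value per cell there is no
within-cell error term, which is exactly the structure a repeated-measures
ANOVA expects; the implementation is verified against statsmodels
`AnovaRM` on the same data. A zero denominator mean square (e.g. a forced
identical shift in every participant) reports F = ∞, p = 0 with a flag.
No correction is applied across the six measures, each reported ANOVA
standing alone. `build_report` assembles pre/post × left/right group means
± sd for all usable stimulus trials and for the formal-startle subset,
starring pairs whose effect is significant at α.

Calibration: with the null phantom the window effect rejects at the
nominal rate (measured 4.9% over 2500 simulated studies of
4 × 2 × 10; the F(1, P−1) statistic is algebraically a paired t² on
participant window-contrasts, exact under the Gaussian model). An
injected 0.3 K effect — whose 0.3 s latency + 1 s ramp average ≈ 0.6 of
full amplitude over the post window — is detected essentially always at
this scale.

## Startle detection

Motion energy = mean squared difference of consecutive frames. Under
integer-pixel motion its null distribution is bimodal: most pairs are
motion-free (2 × noise²) while single-pixel steps carry a large, nearly
constant energy dominated by the face-silhouette edge. A plain MAD
collapses onto the noise mode, so the robust scale is
max(1.4826·MAD, (q90 − median)/1.2816), which brackets the ordinary-motion
cluster whenever it holds ≥ 10% of the pre-stimulus pairs. A trial is
flagged when the maximum energy within (t_stim, t_stim + 3 s] exceeds
median + z·scale with z = 3 — chosen once from an operating-characteristic
sweep (sensitivity 1.00, specificity 0.995 at the default 6 px jerk).
Detection is invariant to constant temperature offsets, and its
sensitivity is monotone in jerk amplitude. The threshold remains a
convention: the original identification of formal startles was by eye.

## Known limitations

* Exact tracking on the phantom is a property of integer-pixel motion;
  real video needs sub-pixel handling and a more robust tracker.
* The unweighted-means mixed ANOVA is not REML; with severe imbalance or
  missing cells a likelihood-based mixed model would be preferable (a
  missing cell raises an error naming it).
* The chi-squared normality test's mild anti-conservatism at n = 31 is
  inherent to moment-estimated parameters with the χ²(k−3) reference.
* The startle detector is a stand-in for human inspection; its threshold
  has no empirical anchor in real thermal video.
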