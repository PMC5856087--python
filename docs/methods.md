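# Methods

This note records the models, parameter choices and numerical
conventions behind cardiofuse, and what its synthetic benchmarks do
and do not demonstrate.

## Signal model and segmentation

A recording is a uniformly sampled amplitude vector (mV) with sampling
rate `Sr` (Hz) and mean heart rate `Hr` (beats/s; 60 bpm ⇒ `Hr = 1`).
The cycle length `CL = round(Sr/Hr)` uses round-half-to-even so the
rounding is unbiased and reproducible.  Indices are 0-based and cycle
intervals half-open.  Default segmentation is fixed tiling
`[i·CL, (i+1)·CL)` — the convention the delineation algorithms assume;
an R-anchored mode re-estimates CL per beat from the median of the
last 8 RR intervals and starts each cycle 30 % of the current CL
before its R peak.  Fixed tiling is the default because the whole
delineation chain is defined relative to per-cycle windows; the
R-anchored mode exists for drifting heart rates but is not used by the
benchmarks.

## ECG delineation

* `σ_R = 0.7` (fraction of the global maximum ζ for candidate R
  peaks).  "Local maximum" is implemented discretely as a
  first-difference sign change (rising before, non-rising after),
  ties to the earliest sample.
* Error margin `α = 0.02·Sr` samples (20 ms).  It widens every search
  range; the method's source calls it user-defined without a value.
* Search ranges around R use standard clinical normal durations
  (configurable): QRS 0.12 s, PR interval 0.20 s, QT interval 0.45 s,
  P wave 0.12 s, T wave 0.20 s.
* The P range excludes the Q sub-range and the T range excludes the S
  sub-range.  Without the exclusion the max/min rules can capture the
  Q or S extremum and break the canonical ordering
  Ponset < P < Poffset ≤ QRSonset < Q < R < S < QRSoffset ≤ Tonset <
  T < Toffset.
* Endpoints: minima of half-wave-width windows on either side of P
  and T (`[P − ΔP·Sr/2 − α, P]` etc.); QRS onset/offset are *maxima*
  of `[Q − α, Q]` and `[S, S + α]`.  The max rule for QRS endpoints is
  physiologically odd but is the literal published rule; a
  min-|slope| alternative sits behind `qrs_endpoint_rule="min_slope"`.
  The window width for QRS endpoints (α, one-sided) is our choice —
  no width is published.
* Known failure mode, kept deliberately: an inverted T wave is
  mislocated by the max-amplitude T rule.  A regression test pins
  this behaviour rather than "fixing" it, because the rule is the
  contract.

### Consequence for measured durations

On a clean bump on a flat baseline the endpoint minima land on the
window *edges*, so the measured P width is `ΔP + 2α = 160 ms` and the
T width `ΔT + 2α = 240 ms` regardless of the rendered bump.  The
default reference table therefore bounds P duration at 0.20 s and T
duration at 0.28 s so that normal morphology passes; duration checks
consequently fire mainly through range clipping, while amplitude and
RR checks carry the discriminative load.  This is a property of the
published endpoint construction, not of the implementation.

## SCG delineation

* `σ_AO = 0.75`.
* Windows are learned from annotated healthy cycles:
  `SW(X) = mean(X − AO)` in samples, half-width `max(2·SD, α)`
  (`window_mode="fixed"` forces exactly α).  The α floor prevents
  zero-width windows on degenerate training sets.  Training on ~20
  cycles matches the monitor's calibration span.
* Polarity map (peak/valley per label): AS+, MC−, IM−, AO+, IC−, RE+,
  AC−, MO+, RF+ — configurable, as published morphologies vary by
  sensor site.

## ECG morphology checks

Amplitudes are measured relative to the per-cycle **median** (a robust
stand-in for the isoelectric level), durations from the endpoint
pairs, RR from consecutive R peaks (undefined for the first beat).  A
check fails only on a *strict* bound violation; undefined measurements
never fail.  Default bounds (mV / s): P amplitude [0.05, 0.25], QRS
[0.5, 2.0], T [0.1, 0.5]; P duration [0.06, 0.20], QRS [0.06, 0.12],
T [0.10, 0.28], RR [0.6, 1.2]; PR/QT interval and PR/ST segment
bounds exist behind `extended_checks` (off by default, matching the
base rule set).  Group counters reset per group in both disjoint and
sliding modes (the literal pseudo-code never resets, which would make
counters unbounded); disjoint grouping is the default used for CAI
reporting.

## SCG feature-variables and the running statistics

Six durations per beat: MC→AO (isovolumic contraction), AO→AC
(ejection), MC→MO (systole), AC→MO (isovolumic relaxation), RE→AC
("ejection" variable) and MO→RF ("filling" variable).  The last two
pairs are configurable: the source material names the quantities but
never pins their endpoints, so RE→AC and MO→RF are documented
defaults.  With `normalize=True` (default) durations are divided by
the concurrent cycle length, making calibration heart-rate-relative.

Calibration (first η = 20 defined beats per variable) weights beats
1..η, favouring recent ones:

    Wavg = Σ j·D_j / Σ j,   Wstd = sqrt(Σ j·(D_j − Wavg)² / Σ j)

The published initialisation of the variance accumulator subtracts a
first moment from a second moment; we use the dimensionally consistent
weighted variance above and scale the accumulator by (η−1) so the
later square-root formula is continuous at k = η.  After calibration:

    Wavg_k = Wavg_{k−1} + (2/(η+1))·(D_k − Wavg_{k−1})
    S_k    = S_{k−1} + k·(D_k − Wavg_{k−1})·(D_k − Wavg_k)
    Wstd_k = sqrt(S_k / (k−1))

S is non-negative by construction (the two deltas share a sign).  A
`uniform_weights` degenerate mode reproduces the plain two-pass
mean/population-SD at the end of calibration, which the property tests
verify to 1e-9 relative.

A beat's variable is an outlier when `|D − Wavg|/Wstd` exceeds the
Chauvenet tolerance `|Φ⁻¹(1/(4k))|` (scipy's normal quantile; 2.2414
at k = 20).  The published ±1 SD band check would flag ~32 % of normal
Gaussian beats, contradicting the stated ≤5 % outlier budget, so it is
only available as `strict_band`.  When Wstd = 0 (exact noiseless
streams) the deviation is 0 if `|D − Wavg| ≤ 1e-9` and ∞ otherwise;
the tolerance absorbs the last-ulp error of weighted averaging of a
constant.

**Robust vs continuous updates.**  By default every evaluated beat —
flagged or not — updates the state.  That choice has a sharp
consequence: a single large outlier inflates Wstd proportionally to
its own magnitude, so a *sustained* identical anomaly standardises to
≈0.93 from the second beat on and is never flagged again, whatever its
size.  Group-level monitoring of persistent abnormality therefore runs
the pipeline with `robust=True` (flagged beats excluded from the
update); the streaming monitor object keeps the continuous update as
its default for single-transient use.

## Naive Bayes fusion

Per-modality feature vectors (7 ECG: three wave amplitudes, three wave
durations, RR; 6 SCG: the feature-variables) feed a Gaussian Naive
Bayes with class-frequency priors, per-feature class-conditional
mean/variance (variance floored at 1e-6 in squared feature units), and
log-space MAP classification.  Missing features drop out of the
product; a fully missing vector abstains and counts as normal; exact
ties resolve to normal (the conservative direction for an alarm
system).  The Gaussian likelihood is our choice — the published model
never names a density family.  Training labels come from the synthetic
generator's injection truth; when no truth exists the rule-based
monitors provide fallback labels.

The joint outcome is `CC_ecg AND CC_scg`; CAI is the mean of joint
bits in a group (sizes 5/10/25/50 are the conventional presets,
default 5) with an alert at CAI > δ = 0.2 (δ is explicitly a
deployment parameter, clinically calibrated in practice).  The
per-beat bits may come from the NB classifiers or from the rule-based
monitors (`cc_source`); the worked case studies use the rule-based
wiring since they are defined in terms of the reference-value and
Chauvenet checks.

## Synthetic generator

Each beat is a sum of Gaussian bumps (centre = ground-truth fiducial,
SD = "width", sign = polarity) on a zero baseline, rendered
cycle-locally (truncated at cycle boundaries, error < 1e-3 mV for the
defaults) so that anomaly injection leaves untouched cycles
bit-identical.  Defaults, chosen to sit inside the reference bounds
and to respect the electromechanical order (R before AO in every
beat):

* ECG (offset ms / mV / SD ms): P 150/+0.15/25, Q 250/−0.10/8,
  R 280/+1.50/8, S 310/−0.20/8, T 500/+0.30/40.  The R amplitude of
  1.5 mV (rather than a lower typical value) keeps normal beats above
  the 0.7·ζ candidate threshold even when one beat's R is scaled past
  the 2.0 mV reference bound — with a smaller normal R, any
  upper-bound R anomaly would silently blind the detector to all
  *normal* beats, since ζ is global.  The global-max threshold rule
  tolerates amplitude anomalies only up to a factor 1/σ_R ≈ 1.43 of
  the normal peak; this is a real limitation of the rule, exercised
  by the tests.
* SCG (offset ms / mV / SD ms): AS 300/+0.30/10, MC 325/−0.40/8,
  IM 355/−0.25/6, AO 380/+1.00/8, IC 410/−0.50/8, RE 440/+0.45/10,
  AC 560/−0.35/10, MO 590/+0.40/10, RF 660/+0.25/12.  The SCG
  amplitude scale is arbitrary (published chest-accelerometer
  amplitudes vary by orders of magnitude between sites and sensors)
  and fully configurable.  Offsets are spaced so that neighbouring
  bump tails displace extrema by < 1 sample at 1000 Hz.
* Noise defaults: white noise SD 0.02 mV, baseline wander 0.05 mV at
  0.25 Hz with random phase, multiplicative RR jitter SD 2 %
  truncated at ±3 SD.  A seed is mandatory.

Anomalies: `amplitude_scale`, `duration_stretch` (delays the target
fiducial and all later ones in the beat), `drop_fiducial` (these three
re-render the affected cycles from the modified template),
`st_shift` (adds a constant from S+20 ms to T−80 ms), `noise_burst`,
and `rr_prolong`, which inserts isoelectric samples at the end of the
*preceding* cycle so that the targeted beat's RR interval
(R(k) − R(k−1)) is the one prolonged.

**What the generator does not emulate:** physiological waveform
dynamics (no ODE model), respiration coupling beyond the sinusoidal
wander, inter-subject morphology variation, sensor transfer functions,
or pathological morphologies beyond the parametric anomalies.  Passing
the synthetic benchmarks shows the algorithms implement their
contracts and behave correctly on signals whose ground truth is known
exactly; it does not certify clinical performance on real recordings.

## Evaluation conventions

Matching tolerance 25 ms per label, one-to-one, greedy by increasing
|error| with earliest-first tie-breaks.  Greedy equals the optimal
assignment whenever a label's reference points are separated by more
than twice the tolerance — true for beat-level fiducials (≈1000 ms
apart) — and the tests verify this against scipy's Hungarian solver;
on adversarial sub-tolerance clusters greedy can match fewer pairs.
Delineation errors are reported as mean ± sample SD (n−1).  The ROC
sweep's FPR is the unmatched-detection fraction (precision
complement), since at most one R/AO is emitted per cycle and no
negative class exists.  Cohen's κ uses the standard
(po − pe)/(1 − pe) with chance agreement over the pooled label set.

## Benchmark problem sizes

The shipped benchmarks use 5–40 beats per trace at 1000 Hz for
delineation checks, 20-beat calibration + 5/10-beat evaluation groups
for the CAI case studies, 200-beat corpora for the NB accuracy check,
and 10,000 beats for the Chauvenet flag-rate Monte-Carlo — sizes at
which every expected value is exact or statistically stable while the
whole suite runs in well under a minute.
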