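# cardiofuse

Joint analysis of the heart's electrical and mechanical activity from
paired single-channel recordings: an **ECG** (electrocardiogram) and a
**seismocardiogram** (SCG, a chest-surface accelerometer trace).  The
package delineates the fiducial points of every cardiac cycle in both
modalities, checks each beat for abnormal morphology with
modality-specific rules, fuses the two per-beat decisions, and
summarises groups of beats as a **Cardiac Abnormality Index**.  It is
aimed at wearable-monitoring research, where single-channel artifacts
are common and a second, independent modality can veto false alarms.

## What it computes

**Cycle segmentation.**  A trace sampled at `Sr` Hz with mean heart
rate `Hr` beats/s is tiled into cycles of `CL = round(Sr/Hr)` samples
(an R-anchored mode with a per-beat CL re-estimate from the median of
the last 8 RR intervals is also available).

**ECG delineation.**  R is detected per cycle as the largest local
maximum with amplitude ≥ `σ_R · ζ`, where `ζ` is the global maximum
over all cycles and `σ_R = 0.7`.  P, Q, S, T are the extrema of search
ranges around R derived from normal clinical wave/interval durations,
and the six wave endpoints (`P/QRS/T` onset and offset) are located in
half-wave-width windows around their anchors.

**SCG delineation.**  AO (aortic valve opening), the dominant SCG
peak, is detected with the same rule at `σ_AO = 0.75`.  The eight
remaining fiducials (AS, MC, IM, IC, RE, AC, MO, RF) are found inside
per-label windows whose offsets from AO are *learned* from annotated
healthy training cycles: `SW(X) = mean(X − AO)`, half-width
`max(2·SD, α)`.

**Per-beat abnormality.**  ECG beats are checked against a table of
referenced normal values (amplitude and duration bounds for P, QRS, T,
plus the RR interval).  SCG beats are summarised by six fiducial-pair
durations (e.g. `Π_AO,AC`, the left-ventricular ejection time); each is
tracked by a weighted running mean/SD (weights 1..η over a η = 20-beat
calibration phase, then an exponential update) and flagged by
Chauvenet's criterion when its standardized deviation exceeds
`|Φ⁻¹(1/(4k))|`.  A Gaussian Naive Bayes classifier per modality is
available as an alternative per-beat decision source.

**Fusion and CAI.**  A beat's joint outcome is the logical AND of the
two per-modality bits, and for a group of beats

```
CAI = (# beats with joint outcome 1) / (group size) ∈ [0, 1],
```

with an alert when CAI exceeds a threshold δ (default 0.2).

**Evaluation.**  Automatic annotations are compared to reference ones
by greedy one-to-one tolerance matching (default 25 ms), reported as
precision / recall / F-measure, per-label mean ± SD timing error, ROC
threshold sweeps for the R/AO detectors, and Cohen's κ for
inter-annotator agreement.

Because clinical recordings of this kind are not publicly
distributable, the package includes a first-class synthetic generator:
paired, time-aligned ECG and SCG beats built from Gaussian-bump
templates with exact ground-truth fiducials, beat-to-beat RR jitter,
additive noise, baseline wander, and injectable anomalies (amplitude
scaling, interval stretching, RR prolongation, ST shift, dropped
fiducials, noise bursts).

## Worked example

Five clean beats plus two injected ECG-only anomalies (an R peak
scaled beyond the 2.0 mV reference bound in beat 2, a P peak beyond
0.25 mV in beat 4), after a 20-beat calibration stream:

```sh
$ cat anomalies.yaml
- kind: amplitude_scale
  label: R
  magnitude: 1.4
  cycles: [1]
- kind: amplitude_scale
  label: P
  magnitude: 2.0
  cycles: [3]
$ cardiofuse run --seed 1 --n-eval 5 --anomalies anomalies.yaml
{
  "ecg_bits": [0, 1, 0, 1, 0],
  "scg_bits": [0, 0, 0, 0, 0],
  "joint_bits": [0, 0, 0, 0, 0],
  "cai_ecg": 0.4,
  "cai_scg": 0.0,
  "cai_joint": 0.0,
  "alert": false
}
```

The ECG channel flags exactly the two injected beats (ECG-side
CAI = 0.4), but the untouched SCG channel vetoes both under AND
fusion, so the joint CAI is 0 and no alert is raised — the behaviour
that motivates using the mechanical channel as a second witness.  The
individual stages are available as `simulate`, `delineate-ecg`,
`delineate-scg`, `monitor-ecg`, `monitor-scg`, `fuse`, `evaluate` and
`roc` subcommands operating on CSV/YAML files.

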