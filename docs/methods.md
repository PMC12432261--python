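# Methods

This note documents the models, defaults and numerical choices behind the
package, and what the synthetic benchmark does and does not demonstrate.

## Forward model

Each eye carries a corneo-retinal dipole whose orientation follows gaze.
For gaze angles (θh, θv) the unit gaze vector in the head frame (x right,
y anterior, z superior) is

    p̂ = (sin θh cos θv, cos θh cos θv, sin θv)

and the potential at an electrode at position **e** is the homogeneous-
medium dipole field summed over both eyes:

    V(e) = k · Σ_eyes (p̂ · r) / |r|³,   r = e − eye center.

No skull/tissue conductivity is modelled.  The pipeline consumes
*correlation and gain structure* across electrode positions — which pair is
more sensitive, how signals scale with angle — and that structure is set by
geometry alone; absolute biophysical fidelity is not required and not
claimed.

**Dipole moment** `dipole_moment_uVm2 = 0.09` is calibrated so the
periorbital horizontal channel (hEOG) moves ≈7 µV/deg and the best
cross-ear pair ≈1.3 µV/deg, i.e. a 15° saccade deflects hEOG ≈104 µV and
L8−R8 ≈20 µV — the order of magnitude of wet-electrode EOG, with the
ear channels several-fold weaker as observed in around-ear recordings.

**Default layout.** Eyes at (±3.5, 7.5, 0) cm; 8 ring positions per ear at
5 cm radius around each ear canal at (±7.75, 0, 0) cm, with index 8
anterior at eye level (nearest the eyes), 4 posterior, 2 superior, 6
inferior; the two inferior slots carry the reference (left) and ground
(right), leaving 14 measurement channels L1–L5, L7, L8, R1–R5, R7, R8.
With these positions the distance from an eye to the frontal electrodes on
the same side is ≈5.2 cm, matching typical head anthropometry.
Periorbital electrodes sit at the outer canthi (bipolar hEOG = right −
left) and above/below the left eye (vEOG = upper − lower).  Vertical
weakness of the ear montages is emulated purely by geometry (ear
electrodes sit roughly at eye height, so vertical rotation barely changes
their projection); no ad-hoc attenuation factor is applied.  All geometry
is user-overridable; published around-ear devices do not share exact
coordinates, so these defaults are explicit placeholders.

Measurement channels are referenced to the REF electrode as in a
single-reference amplifier.  The reference potential cancels in every
differential pair, which is the only way channels enter the analysis.

## Noise and camera model

Defaults approximate a dry-electrode wearable after amplification:

| parameter | default | meaning |
|---|---|---|
| `noise_white_uV` | 2.0 | white sensor noise σ per channel |
| `drift_random_walk_uV_per_sqrt_s` | 1.0 | electrode/skin baseline drift |
| `line_50hz_uV` | 3.0 | mains interference amplitude (random phase per channel) |
| `camera_noise_deg` | 0.25 | remote-tracker angle noise σ |
| `camera_dropout_prob` | 0.02 | per-sample tracking loss (valid=false, NaN) |
| `camera_latency_s` | 0.05 | device + processing delay, up to 0.5 s supported |

Per-channel noise streams are keyed by `(rng_seed, channel index in sorted
label order)`, so output is bit-reproducible for a fixed config, and a
pipeline seed fans out to participants via `SeedSequence([seed, id])` —
adding participants never perturbs existing ones.

Not emulated: blinks and EMG artifacts, head movement, electrode–skin
impedance drift beyond the random walk, realistic EEG background.  Passing
tests therefore show that the *analysis chain* is correct and robust to
generic noise at realistic SNR, not that it survives every artifact class
of real recordings.

## Preprocessing

All EOG channels are band-pass filtered 0.1–15 Hz (5th-order Butterworth)
once at ingest.  Trial-level chains:

* EOG: linear detrend → centered mean filter (length 50) → min–max
  normalization to [−1, 1];
* camera: interpolate missing samples → resample to 125 Hz → band-pass →
  mean filter (50) → normalization.

Choices worth noting:

* **Zero-phase filtering** (forward–backward `sosfiltfilt`): downstream lag
  estimation must not inherit the filter's group delay.  The effective
  magnitude response is therefore |H|².
* **Mean-filter edges** are truncated to the available samples (no
  reflection or zero-padding) — the simplest contract to reason about.
* **Normalization is min–max**, so both interval endpoints are attained.
  Spans below max(10⁻⁹, 10⁻¹²·max|x|) are flagged *degenerate* and the
  trial is excluded from correlation, rather than amplifying float residue
  (e.g. after detrending a constant) into a fake unit-amplitude signal.
* Normalization is applied trial-wise, after trial cutting.

## Montage correlation

For each 6 s pursuit trial, Pearson r between the preprocessed montage
differential and the preprocessed reference is maximized in |r| over
integer lags: ±12 samples against gold EOG (device-internal alignment),
±64 samples against the camera (device latency and clock mismatch).  The
signed r at the winning lag is kept; ties break toward smaller |lag|, then
negative lag.  |r|-maximization is deliberate: the ordering of a pair
fixes its sign arbitrarily (the simulated L8−R8 is anti-correlated with
hEOG purely by wiring).  Per-trial r = ±1 is clipped to ±(1−10⁻⁶) before
the Fisher transform so noiseless trials keep finite z.

With near-sinusoidal pursuit signals the |r|-maximizing lag can lock onto
the half-period anti-correlated alignment when the true lag approaches
half a stimulus period (1 Hz trials with ~0.4 s latency); latency is
therefore summarized by the *median* recovered lag, which is robust to
these flips.

The montage comparison uses participant-level Fisher-mean correlations as
the observation unit (one row per participant): a Friedman test across
montages, followed — only when p < 0.05 — by all-pairs two-sided Wilcoxon
signed-rank tests with Bonferroni correction (p × number of comparisons,
clipped at 1).

## Saccade analysis

Epochs are 2 s windows starting 0.75 s before each outbound fixation jump;
with the default 0.2 s reaction latency the saccade lands near the window
center.  Labeling runs on the gold-standard channel of the saccade's axis:
differentiate, smooth (mean filter, length 15 ≈ 120 ms), locate the peak
velocity whose sign matches the stimulus direction, and extend to the
nearest crossings below 15% of the peak speed.  An epoch is invalid when
the peak speed is below 5× the MAD of the window velocity — the automatic
counterpart of excluding saccades "without a clear start and end".  The
smoothing length is chosen so labelled spans comfortably exceed the 20
samples needed by the deflection statistic at 125 Hz; at this rate a raw
saccade occupies only a handful of samples and the span is effectively the
band-limited transition region.

The deflection is ΔV = mean(last 10 samples of the span) − mean(first 10
samples), **post-minus-pre**, so leftward/downward saccades on a
right/up-positive channel give negative deflections (a 15° left saccade on
hEOG ≈ −104 µV in the simulator).  A flanking-plateau variant
(`mode="flank"`) is available; the span-endpoint default slightly
overshoots the raw step (≈3%, the zero-phase Butterworth edge overshoot),
which is part of the realized measurement gain and identical across
amplitudes, so linearity is unaffected.  Return saccades are extracted on
request but excluded from amplitude analyses (center-resting design).
Average waveforms are baseline-shifted by each epoch's pre-start mean
before pointwise mean/SD, making them exactly invariant to constant
offsets.

Vertical epochs are processed identically but the vertical ear montages
are geometrically insensitive, and downstream reports treat them as
unreliable; angle prediction uses horizontal saccades only.

## Gaze-angle prediction

OLS maps deflection features (µV) to signed angle change (deg).  Feature
sets: the best horizontal pair, all configured candidate pairs, and the
gold-standard hEOG.  Targets are the schedule's signed amplitudes (in the
simulator the camera ground truth equals the schedule up to noise).
Evaluation is leave-one-participant-out by default (an in-sample option
exists for structural comparisons); errors are reported as direction ×
amplitude MAE/SD tables with per-direction and overall totals.  Agreement
between two prediction methods uses Bland–Altman statistics: mean
difference and mean ± 1.96 × sample SD (n−1) limits of agreement.

At smoke scale (2 participants, 24 saccades) the all-pairs model overfits
and loses to the single best pair out-of-sample; at cohort scale (≥6
participants) the ordering reverses, as expected for OLS with 11 features.

## Problem sizes

The bundled verification runs use desk-scale cohorts chosen to exercise
every code path at stable statistics: 4 participants × 1 cycle for the
pursuit/montage checks, 8 participants × 3 cycles (576 saccades) for
deflection linearity and gain recovery, 4-participant cohorts for the
noise sweep (white σ = 0.5, 2, 8, 32 µV, spanning clean lab recordings to
very poor electrode contact), and 8 participants for the acceptance
script.  Amplitude SNR for a montage is defined as RMS(signal)/RMS(noise
difference); white-noise σ for a target SNR is RMS/(SNR·√2) since a
differential of two independent streams carries σ√2.

## Known limitations

* The dipole model omits volume-conductor effects; absolute µV values are
  calibrated, not derived.
* The saccade labeler assumes the stimulus schedule is known (no free
  -viewing saccade detection) and one saccade per epoch.
* Camera clock skew is modelled as a constant offset, not drift.
* Real-recording headline values (specific r and MAE magnitudes measured
  on human participants) depend on data that is not publicly deposited;
  the simulator reproduces the qualitative structure — montage ordering,
  deflection linearity, gold-vs-ear performance gap — not those exact
  numbers.
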