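# Methods

`tscs-tune` implements the signal-processing and machine-learning chain of
an MMG-based calibration procedure for transcutaneous spinal cord
stimulation (tSCS), together with a synthetic evoked-response cohort
generator that makes the whole chain testable without human data. This note
documents the models, the numerical choices, and what the synthetic data do
and do not establish.

## The calibration problem

Before tSCS therapy, an examiner determines a back-electrode position and a
stimulation current for each person. The classical procedure delivers
double pulses (50 ms inter-pulse interval) of increasing current while
recording leg-muscle EMG: a posterior-root (reflex) response appears at low
currents and is strongly suppressed on the second pulse of a pair
(post-activation suppression), whereas a direct muscular response appears
at higher currents and is barely suppressed. The package reproduces this
EMG ground-truth pipeline and asks whether skin-normal accelerometry (MMG)
can substitute for the EMG: acceleration responses are classified by
supervised learning against the EMG classes, and therapy parameters are
derived from both label sources and compared.

## Synthetic cohort generator

The generator is first-class, tested code. Per muscle it models:

- **Recruitment.** Two logistic recruitment curves in current `I`:
  reflex `r(I) = σ((I − θ_r)/s)` and direct `d(I) = σ((I − θ_d)/s)` with
  `θ_r < θ_d` and slope `s` (default 1 mA). The expected EMG response to
  pulse 1 is `A1 = g·(r + d)` μV peak-to-peak (gain `g`, default range
  250–500 μV).
- **Suppression.** The second EMG response of a double pulse is scaled by
  `1 − S_eff/100`, where `S_eff` interpolates between `S_true` (default
  70–95 %, reflex-dominated) and a residual `S_direct = 10 %` according to
  the recruitment mix `r/(r+d)`. This makes suppression collapse once motor
  fibres recruit, which is exactly the property the 3-class labels exploit.
- **Waveforms.** The EMG response is a Gaussian-derivative biphasic wave
  (width σ = 2 ms, unit peak-to-peak) at the muscle latency (thigh ≈ 8 ms,
  calf ≈ 18 ms — the calf is farther from the root). The mechanical twitch
  is a double-exponential envelope `exp(−t/τ_d) − exp(−t/τ_r)` (rise ≈
  30 ms, decay ≈ 80 ms, unit peak) starting one electromechanical delay
  (5 ms) after the EMG response. These shapes are the package's own choice:
  the physiology constrains latencies and durations (twitches last hundreds
  of milliseconds and overlap within a double pulse) but not a parametric
  form, so any smooth waveform with those time constants would serve.
- **Non-linear twitch summation.** The second twitch of a double pulse is
  additionally scaled by `summation_gain` (default 1.0–1.5): sequential
  twitches can sum more than linearly in force, which is the main reason
  suppression cannot be read directly from acceleration.
- **Artifacts and noise.** A biphasic stimulation artifact (±3000 μV, 1 ms
  per phase) enters the EMG only — accelerometers do not see the electrical
  pulse. Both channels carry additive white Gaussian noise (EMG 2–5 μV,
  ACC 0.01–0.03 m/s², scaled by a cohort-level `noise_scale`).

Sessions follow the clinical protocol: per current (5 mA start, 5 mA
steps), three double then three single biphasic pulses, 5 s apart; EMG at
1 kHz, acceleration at 0.5 kHz on a shared clock (the acceleration is
generated directly at 0.5 kHz, no decimation). Per-subject maximum currents
are drawn from {25, …, 45} mA to emulate termination at the discomfort
level, so subjects contribute unequal event counts. Ground-truth classes
are derived from each model's *expected noise-free* A1 and S through the
same classification rules used on measured signals; near a threshold the
logistic tail makes this the only self-consistent reading of "truth from
thresholds".

**What the generator does not emulate:** motor-unit structure of the EMG,
movement or crosstalk artifacts, spontaneous muscle twitches, skin
impedance or electrode geometry, inter-muscle mechanical coupling beyond
the partner-muscle features, and any realistic relation between subject
metadata and thresholds (metadata are drawn independently). Consequently,
passing tests show that the *pipeline* is correct and that the method
recovers parameters when its assumptions hold — they say nothing about
classification accuracy on real human data, and the human study's accuracy
values are not reproduction targets here.

## Preprocessing

- **Artifact detection.** The double-differenced EMG is thresholded at
  `k·MAD` (k = 8, MAD scaled by 1.4826) with a 10 ms refractory period; on
  an all-quiet sweep the threshold falls back to a fraction of the maximum
  so that a noise-free recording still detects its artifacts. There is no
  canonical numeric threshold for this detector; `k` is configurable.
- **Cropping.** Half-open window [−10, 400) ms around the first artifact:
  410 samples at 1 kHz, 205 at 0.5 kHz. This half-open convention is
  binding throughout.
- **EMG filtering.** Zero-phase second-order IIR notch at 50 Hz (Q = 30,
  forward–backward) against mains hum, then subtraction of a 31-sample
  running median (reflect padding) as a ringing-free high-pass. The median
  subtraction interpretation ("signal minus sliding median") is inferred
  from the filter's high-pass role. Note that within a 410 ms crop the
  notch's filtfilt edge transients limit realized 50 Hz rejection to about
  10 dB even though the steady-state notch exceeds 40 dB; tests assert
  both measured figures.
- **Acceleration.** Cropped on the EMG artifact clock (the acceleration has
  no artifact of its own), then the mean of the first 10 ms (5 samples) is
  subtracted as a static gravity filter.
- **Similarity-checked averaging.** Pairwise coefficients of determination
  (squared Pearson r) between the three repetitions form a connectivity
  matrix; repetitions linked at R² ≥ 0.8 are grouped by connected
  components and the largest group (≥ 2) is averaged. For the acceleration
  channel, sweep pairs whose RMS both stay below 0.05 m/s² count as
  connected: two no-response sweeps contain only sensor noise whose mutual
  correlation is near zero although nothing disagrees — without this floor
  every sub-threshold event would be discarded, which contradicts how real
  no-response events survive averaging. Identical repetitions average to
  the input exactly (guarded special case).
- **Exclusions.** Events whose repetitions never agree (including sweeps
  whose artifact could not be detected) are flagged `similarity_fail`;
  averaged EMG with pre-stimulus baseline RMS above 20 μV is flagged
  `noisy_emg`. Both are recorded, never raised, and reported as fractions.
- **DIFF.** Sample-wise double-minus-single acceleration, isolating the
  second pulse's mechanical response despite twitch overlap.

## EMG labeling

A1 and A2 are peak-to-peak amplitudes in windows [5, 45] ms and
[55, 95] ms after pulse 1 (the second window is the first shifted by the
50 ms inter-pulse interval; window edges are configurable — the bounds must
end before the next pulse). Suppression is `S = (1 − A2/A1)·100`. Classes:
A1 ≤ 50 μV → 0 (no response); A1 > 50 μV and S > 60 % → 1 (reflex);
A1 > 50 μV and S ≤ 60 % → 2 (direct muscular). The 2-class scheme merges
1 and 2. Boundary values fall to the lower class, and A1 = 0 yields class 0
with S reported as 0 and flagged. The windows themselves are a package
choice; the thresholds (50 μV, 60 %) are the established ones.

## MMG features

36 features per event: 4 meta (BMI, sex, age, height), 2 stim (electrode
position, current), 30 MMG-data. Amplitude features use winA1 = [10, 60] ms
after pulse 1 for the thigh and [15, 65] ms for the calf (delayed onset),
and winDIFF with the same offsets after pulse 2. Choices where the feature
list under-specifies:

- Spectral features (mean power frequency, area under and maximum of the
  PSD) use a Hann-windowed periodogram of the **full cropped signal**;
  MPF = Σ fᵢPᵢ / Σ Pᵢ, and the PSD area is trapezoidal.
- Zero-crossing rates are crossings per second over the full crop;
  zero-valued samples inherit the previous sign.
- The single-vs-double correlation features (r and r²) share one window,
  [50 ms, end of crop].
- Max slope is the largest forward difference times the sample rate.
- The curve-similarity feature is the discrete Fréchet distance between the
  double- and single-pulse signals in winDIFF, treated as (t in ms,
  amplitude in m/s²) polylines — mixed units are inherent to the feature.
- The two crosstalk features are the partner muscle's (other muscle, same
  leg) peak-to-peak amplitudes in the partner's own windows; they are 0
  when the partner event is invalid.

SET-OBSERVE = 30 MMG + 4 meta (34 columns); SET-PREDICT = 4 meta + 2 stim
(6 columns, sensor-less). Features reach tree models unstandardized;
standardization for SVM/LDA happens inside the classification stage, fitted
on training folds only.

## Classification

Leave-one-subject-out over subjects (a patient's two measurement days stay
in one fold). Balanced accuracy = mean per-class recall over the classes
present in the fold's ground truth (unadjusted; some subjects lack class
2). Hyperparameters are tuned per outer fold by random search (default 50
candidates) scored by inner LOSO over the n−1 training subjects, on the
3-class labels, and reused for 2-class. Search distributions (the parameter
names are fixed; the distributions are package defaults): SVM (RBF kernel)
C and gamma log-uniform [1e−3, 1e3]; RF min_samples_split 2–20,
min_samples_leaf 1–10, max_depth 3–30 or unlimited, max_samples
[0.3, 1.0] (100 trees); LDA solver {svd, lsqr, eigen}, tol log-uniform
[1e−6, 1e−2], n_components {1, K−1}. Class weights are balanced for SVM and
RF; LDA has no class-weight parameter, so uniform priors serve as the
balanced analogue. A candidate whose fit fails (e.g. singular covariance
under the eigen solver) scores 0 in the search. All per-fold randomness
derives from the experiment seed and fold index; reruns are byte-identical.

## Therapy parameters

The nested position/current search is applied as a lexicographic cascade:
(1) eligibility — ≥ 2 class-1 labels at one current; (2) largest class-1
count at any current (the smallest current achieving it is the candidate);
(3) smallest distance between that candidate and the onset of any
response (smallest current with a non-0 label); (4) lowest candidate
current; (5) largest total class-1 count; residual ties go to the most
caudal position. The cascade order realizes the "nested" search; the
candidate current accompanying the chosen position is used for ranking
only. The therapy current is exactly 0.9 × the smallest current with a
class-1 label at the chosen position (evaluated at that position only), or
0 mA when no position is eligible. Patients have single-position grids: the
position is not reported, but the eligibility gate still applies.
Agreement with EMG-derived parameters reports ground truth minus
prediction, exact matches, inclusive ±5 mA matches, and position matches.

## Problem sizes and defaults

The study-scale cohort layout (11 healthy × 3–4 positions, 11 patients × 2
days) is available (`study_cohort_spec`), but the shipped experiments run
on desk-scale cohorts chosen as the package's working sizes: a noise-free
4-subject cohort for label-recovery checks and a 12-subject low-noise
(`noise_scale = 0.25`) cohort with subject-specific maximum currents for
the end-to-end parameter-recovery study, with the random search reduced to
5 iterations for the random forest. These sizes keep a full run in minutes
while leaving every pipeline stage exercised at full fidelity.

## Known limitations

- The connectivity-based similarity check keys on the stimulation artifact
  for EMG sweeps; a real recording with artifact-sized non-stimulus
  transients could pass repetitions that differ in their physiological
  content.
- The exclusion fraction of the default synthetic conditions (~5–10 %,
  mostly transition-region acceleration events) emerges from the noise
  model rather than being calibrated against real exclusion causes.
- Run logs are plain JSON files per experiment; there is no experiment
  tracker, database, or GUI, and no hardware interfacing.
- LDA with the eigen solver can fail on collinear features; the search
  treats that as a zero-score candidate rather than an error.
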