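# Methods

## Radar signal model

The simulator works directly at baseband.  Chest-wall displacement is the sum
of three components, `x(t) = xm(t) + xb(t) + xh(t)`, and the quadrature pair
is

    I(t) = cos(θ + 4π x(t)/λ + Δφ(t)) + e_I(t)
    Q(t) = sin(θ + 4π x(t)/λ + Δφ(t)) + e_Q(t)

with carrier wavelength λ = c / 24 GHz ≈ 12.5 mm, a constant phase offset θ
encoding target distance, a Gaussian random-walk phase noise Δφ and additive
white channel noise e.  Carrier-level effects (oscillator, mixing, antenna
pattern) are not modeled: the staging pipeline only ever sees baseband
channels, so the baseband equations are the natural interface.  Radar
channels are sampled at 1000 Hz, epochs are 30 s (the PSG scoring unit).

**Phase noise.**  Δφ is a random walk with per-sample step σ = 0.001 rad
(configurable).  In a CW radar the transmitter and receiver share one
oscillator, and at bedside range the range-correlation effect cancels most
oscillator phase noise, so the residual must be small against the breathing
phase swing (4π·4 mm/12.5 mm ≈ 4 rad).  A step of 0.001 rad/√sample
accumulates ≈0.17 rad drift per 30-s epoch — visible as slow baseline wander,
invisible inside the physiological bands.  A much larger value would flood
the absence-detection energy floor with drift that no empty room produces.

**Deep phase modulation.**  At the default 4-mm breathing amplitude the
modulation index is ≈4 rad, so the raw channel spectrum spreads into Bessel
harmonics of the breathing rate; the in-band spectral peak is then often a
harmonic rather than the fundamental.  This is real radar physics, and it is
why the simulator's demodulation oracle uses arctangent demodulation
(`atan2(Q, I)` unwrapped), which recovers x(t) exactly at any modulation
depth.  Spectral-fidelity checks of the breathing-rate feature are therefore
run noise-free and in the small-modulation regime (amplitude ≤ λ/8 ≈
1.6 mm): there the IQR-selected channel is linear in displacement and the
peak must sit within one 1/30-Hz FFT bin of the programmed rate.  With phase
noise on, the effective phase offset wanders across the night and epochs
whose offset nears 0 (mod π) are dominated by the even Bessel harmonic at
twice the breathing rate on the globally selected channel.  The staging forests do not rely on the peak
being the fundamental — any stage-dependent, subject-stable spectral
statistic is usable evidence.

## Synthetic subjects

The generator emulates what the classifier assumes about real overnight
recordings:

* **Hypnogram** — first-order Markov chain over {WAKE, NREM, REM} at the
  epoch level, starting with two WAKE epochs ("awake for the first minute").
  Default transition matrix gives ≈17% wake, ≈58% NREM, ≈25% REM and mean
  bouts of 5–10 min.  REM draws within 100 epochs (50 min) of sleep onset are
  redirected to NREM, matching the physiological REM latency.
* **Breathing** — quasi-sinusoid; per-second instantaneous rate follows an
  AR(1)-smoothed multiplicative jitter around the stage base rate (defaults
  WAKE 14, NREM 12, REM 15 breaths/min; jitter 10% / 5% / 20% — REM breathing
  is irregular).  Amplitude 4 mm.
* **Heartbeat** — same construction, 50–90 bpm by stage, amplitude 0.3 mm.
* **Movement** — sparse raised-cosine bursts of 20 mm lasting 1–3 s, Poisson
  rate 1/min in WAKE and 0.05/min in sleep.
* **Snore features** — per-epoch SE ~ Poisson with stage means WAKE 0.2,
  NREM 3, REM 1.5 (snoring concentrates in sleep); CI ~ Gamma(2) scaled by
  stage means WAKE 0.1, NREM 1.0, REM 0.6.  Generated directly at epoch
  level; the audio-waveform path (16 kHz WAV → denoising → snore/CI
  extraction) exists to exercise the acoustic operators but is not needed by
  the classifier.
* **Absence** — optional (start, end) epoch intervals with zero displacement
  and zero sound; ground truth labels them WAKE, as reference PSG scores an
  empty bed.
* **Cohorts** — each subject draws its own rates, amplitudes, radar phase
  offset and (for about one in three) an absence interval, so that
  personal-adjusted thresholds and cross-subject generalization are actually
  exercised.

What the generator does **not** emulate: apnea/hypopnea events and arousals,
posture-dependent radar geometry changes, non-stationary environmental noise,
multi-sleeper beds, and the N1/N2/N3 substructure of NREM.  Passing tests
therefore demonstrate that the pipeline recovers the structure this model
encodes — stage-dependent rates, regularity, movement and snoring — not
clinical performance on sleep-disorder patients.

## Feature extraction

Per 30-s epoch of the IQR-selected channel:

* 14 statistics × 3 bands (movement 2–10 Hz, breathing 0.1–0.5 Hz, heartbeat
  0.8–2.0 Hz; 4th-order Butterworth applied forward–backward so peak timing
  is preserved).  Peaks are local maxima with prominence ≥ 0.1 × segment SD;
  zero-cross rate counts sign changes of the mean-removed signal; slope is
  the least-squares line slope per sample.
* Spectral peak (Hz) of the breathing and heartbeat bands: the
  maximum-magnitude FFT bin inside the pass-band, DC excluded.
* Skewness `E[((s−μ)/σ)³]` and kurtosis `E[(s−μ)⁴]/E[(s−μ)²]²` (population
  moments, kurtosis of a Gaussian is 3).  A constant epoch yields (0, 0)
  with a warning — absence epochs must not crash the pipeline.
* SVD and PCA features of the epoch's sub-window matrix: the 30,000-sample
  epoch reshaped to 30 rows × 1,000 columns (1-s sub-windows).  The three
  largest singular values, and the three largest eigenvalues of the
  centralized covariance `(A−μ_A)ᵀ(A−μ_A)/(N−1)` (computed via the SVD of
  the centered matrix — the covariance has rank ≤ 29, so this is exact and
  avoids a 1000×1000 eigendecomposition).  Eigenvalues are used as scalar
  summaries of the principal directions because a feature-table cell must be
  a scalar; they carry the same variance-structure signal.

Per-epoch decomposition is equivalent to filtering the framed
(n_epochs × 30,000) matrix along its last axis in one call, which is how the
batch path does it.  The batch and per-epoch paths are tested to agree.

**WRMEnAD.**  Epoch energy `E(i)` is the mean squared amplitude of the
band-limited signal (sum of the three band energies).  Defining it on the raw
channel would make an empty room's energy depend on the arbitrary DC level
cos(θ) and on sub-0.1-Hz drift, neither of which is physiological.  Absence:
`E(i) < γ_ABS`, default 1% of the recording's median epoch energy.  Movement:
the 0.5-s RMS envelope of the movement band crosses `γ_MOVE` (default 3 × the
recording's median envelope) at least twice in the epoch — one burst produces
one up- and one down-crossing.  Both thresholds are self-calibrating per
recording and configurable.

**Acoustic features (operational definitions).**  Audio denoising is
magnitude spectral subtraction with the noise profile estimated from the
lowest-energy 5% of 32-ms windows, plus a noise gate that silences frames at
the noise-energy level when the profile is broadband (profile max < 10 × its
median); a spiky profile indicates narrowband signal in the quiet frames,
which must not be gated.  A snore event is a short-time-energy burst
(50-ms frames) above median + 25% of the median-to-max range, lasting
0.2–2 s, standing ≥10× above the background energy, and recurring within
10 s of a neighbour when several bursts are present.  Cycle intensity is the
mean energy of the 100–2000 Hz band, normalized to [0, 1] per recording.

## Staging

* Normalization (z-score) uses training-set statistics only; zero-variance
  training features are dropped and logged.
* Feature selection ranks by absolute standardized mean difference between
  the task's two classes on training data; defaults keep 44 (wake/sleep) and
  35 (NREM/REM).
* Forests: 500 trees, √k features per split, seeded; wake/sleep trained on
  all epochs, NREM/REM on sleep epochs only.
* Likelihood smoothing: `p̃_c(i) = α p̃_c(i−1) + (1−α) p_c(i)` with α = 0.9
  and `p̃_c(1) = p_c(1)` (the recursion needs an initial value; the first
  observation is the only unbiased choice).  Likelihood ratio
  `R = p̃₁/(p̃₀ + ε)`, ε = 10⁻⁶ to avoid division by zero.
* Personal thresholds are nearest-rank percentiles of the subject's own
  ratio sequence: rank = ⌈η/100 · n⌉ clamped to [1, n].  Defaults η = 30
  (wake/sleep), η_RNR = 75 with the in-latency-window threshold δ = 20
  percentile points higher (γ_RNR1 ≥ γ_RNR2 — stricter REM evidence early).
* Snore context rule: a WAKE-decided epoch with SE ≥ 2 whose nearest SLEEP
  neighbours on both sides are ≤ 2 epochs away becomes SLEEP; SLEEP is never
  flipped to WAKE by sound.

## Post-processing

Fixed order: wake/sleep decision → WRMEnAD correction → NREM/REM decision →
sound-based wake detection → REM outlier elimination.

1. **WRMEnAD correction** — absence epochs become WAKE; then every single
   sleep epoch sandwiched between two WAKE epochs becomes WAKE, evaluated
   simultaneously (flipping a lone epoch cannot create a new lone epoch, so
   one pass is idempotent; absence is applied first because it can create
   sandwiches).
2. **Sound wake detection** — CI is zeroed on epochs with SE < 1 and
   normalized CI < 0.05; maximal zero-CI runs of 110–170 epochs (inclusive)
   become WAKE.  The run bounds (≈55–85 min) are retained as published
   defaults.
3. **REM outlier elimination** — REM runs separated by ≤ 2 NREM epochs merge
   (the gap becomes REM; WAKE blocks a merge), then REM runs shorter than 3
   epochs become NREM.  WAKE epochs are never altered.

`finalize` repeats the chain until no rule fires (rule 2 can occasionally
leave a fresh lone sleep epoch for rule 1); one pass almost always suffices,
and the fixpoint guarantees idempotence.  Every mutation is logged as
(epoch, rule, old, new).

## Evaluation

Per-stage accuracy is the recall of that stage — reference-stage epochs also
predicted as that stage, ×100; total accuracy is overall fraction correct.
This reading lets per-stage columns and the total disagree, which is the only
way a per-stage/total accuracy table can behave.  A stage absent from the
reference is reported as missing, never 0.  Chance levels are
prevalence-matched under a permutation null: the expected recall of stage s
is the predicted prevalence of s.  Bland–Altman agreement between paired
per-subject accuracy series reports bias, SD of differences and
bias ± 1.96 SD limits.  Mann–Whitney U and Pearson correlation, when needed,
come from scipy.stats.

## Problem sizes and numerics

The reference experiment (tests and `scripts/acceptance.py`) uses 6 training
and 4 test subjects at 720 epochs (6 h) each — large enough for stable
per-stage accuracies and several absence intervals, small enough to run on a
single CPU in minutes.  The fusion-vs-single-sensor non-inferiority check
repeats the experiment over 5 seeds.  Heavy array math (displacement,
baseband synthesis, band matrices) runs in float32 — sub-micrometre
displacement resolution, far below the channel noise floor — with float64
accumulators for all moments and reductions; demodulation unwraps in
float64.  CSV round-trips are bit-exact via shortest-repr writing and
round-trip float parsing.

## Known limitations

* REM detection rests entirely on breathing/heart-rate differences between
  REM and NREM; with subtle programmed differences or heavy phase noise the
  NREM/REM forest degrades toward its prior, as it does for real radar data.
* With very small training cohorts (2–3 short subjects) cross-subject
  feature shift can invert the wake/sleep ratio for an unlucky held-out
  subject; personal thresholds recenter the operating point but cannot fix
  an inverted ranking.  The reference cohort size avoids this regime.
* The snore/CI operators are operational definitions standing in for
  published acoustic algorithms whose training data are unavailable; they
  are faithful to the features' roles (stage-dependent counts, per-cycle
  energy), not to the original implementations.
* The sound-based wake rule fires only on zero-CI runs of 110–170 epochs;
  wake periods outside that length window are invisible to it by design.
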