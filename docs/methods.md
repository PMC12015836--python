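# Methods

This note documents the models, parameters and numerical choices behind
`alphatse`, in the spirit of a methods appendix: what each stage computes,
what the synthetic data do and do not emulate, and where design decisions
were genuinely open.

## 1. The TSE decomposition

All time–frequency analysis is Temporal Spectral Evolution: band-pass,
rectify, average, baseline-correct. The three branches are

* **evoked** — rectified band-passed across-trial average (the ERP's
  spectral content; only phase-locked activity survives averaging),
* **total** — across-trial average of rectified band-passed single trials,
* **induced** — total − evoked.

Both branches are baseline-corrected (mean over −100…0 ms) *before* the
subtraction, so `induced = total − evoked` is exact by construction and is
asserted at machine precision in the tests. Rectification is absolute
value, not squaring, so the traces stay on the µV amplitude scale.

**Filter.** "48 dB/octave" is read as the one-pass asymptotic rolloff of a
Butterworth band edge at 6 dB/octave/pole, i.e. an order-8 design; the
forward–backward (zero-phase) pass doubles the magnitude attenuation and is
accepted as part of zero-phase filtering — this matches common ERP-software
labelling, and the alternative (order 4 combined) is available through
`FilterSpec(rolloff_db_per_octave=24)`. The filter runs as second-order
sections for numerical stability, with odd-reflection padding of two
low-edge periods per pole (clipped to the epoch length). An order-8 filter
with a 5 Hz passband rings for seconds (maximum pole radius ≈ 0.995 at
500 Hz), so epoch-edge transients cannot be removed entirely on 1.2 s
epochs: they bias the interior rectified level by ~0.7% and suppress
amplitude near the epoch edges. The −200 ms pre-stimulus segment buffers
the analysis windows from the worst of this; the residual bias is far below
the Monte-Carlo standard error of a 140-trial average (≈ 2.6% of the
amplitude per sample), which is the scale against which the analytic
2A/π level is verified.

**Envelope smoothing.** Rectifying a narrowband signal leaves deterministic
ripple at twice the carrier frequency. The rectified traces are therefore
smoothed with a centered 100 ms moving average — one cycle of the band
centre, which nulls the 20 Hz ripple of 10 Hz activity exactly — before
baseline correction. The smoother is linear and identical in every branch,
so the construction identity, the evoked ≤ total ordering, and window means
are unaffected; `smooth_ms=0` disables it.

**Temporal resolution.** The narrow band limits how fast an amplitude
envelope can be represented: modulation sidebands outside ±2.5 Hz are
clipped, and heavily band-limited features are smeared and can be
displaced. Single-dataset peak latencies on TSE traces consequently jitter
by ~10–20 ms at realistic SNR (in-band background beats against the carrier
and fluctuates on the ~200 ms timescale of the band's correlation length).
This is inherent to the method, and consistent with the large
between-subject latency spreads such analyses report; parameter-recovery
checks therefore assess the *bias* of latency estimates across 20 simulated
datasets rather than single-dataset error.

## 2. Synthetic data

Each subject × condition is 140 epochs × 60 channels × 600 samples
(−200…1000 ms at 500 Hz, half-open window so stimulus onset is sample 100).
Channels are the 6×7 analysis grid (F/FC/C/CP/P/PO × lines 5,3,1,z,2,4,6)
plus 16 outer 10–10 positions and bipolar VEOG/HEOG. Topographies are
per-channel Gaussian weights on a schematic electrode grid (alpha maximal
at PO6, P3 at Pz, per the measurement profile); no dipole forward model is
attempted, so volume-conduction structure and reference-dependent
topography changes of real EEG are not emulated.

Components, with defaults chosen as typical literature magnitudes:

| component | default | rationale |
|---|---|---|
| P3 wave | Gaussian, σ 60 ms; 12/9 µV (ST/DT) ± 2 µV; latency 353/405 ± 30 ms | parietal slow wave, load-sensitive |
| evoked alpha burst | 10 Hz, fixed phase across trials; 4 µV; Gaussian envelope σ 50 ms; centre 146/151 ± 12 ms | a burst must span ≥2–3 alpha cycles to live inside an 8–13 Hz band — briefer envelopes are destroyed by the band-pass |
| induced alpha | 10 Hz sinusoid, per-trial uniform phase, 10 µV; envelope 1 − d·Gauss(L, σ 80 ms), d = 0.8; L = 168/198 ± 20 ms | strong posterior ERD; σ 80 ms keeps the envelope's ±2 Hz sidebands representable within the band (a faster trough is smeared *and shifted* by the filter, making its latency unrecoverable by any analysis in this band) |
| background | 1/f (exponent 1.0), 5 µV RMS per channel | broadband EEG floor |
| blinks | 400 µV VEOG pulses, σ 50 ms (~300 ms duration), rate 0.3/trial; propagation 0.40 frontally → ~0.05 occipitally | Gratton-style front-to-back gradient; blink duration matters — much faster pulses acquire alpha-band energy and would confound the propagation regression |
| HEOG | ±60 µV tanh steps on 10% of trials | saccade-like; drives the ±50 µV rejection |
| behaviour | RT 384/447 ms (correlated across conditions), accuracy ≈ 99.5% with a 100% ceiling | matches the reported descriptives; the ceiling makes accuracy non-normal, exercising the Wilcoxon pathway |

The ongoing alpha oscillator is a fixed-frequency sinusoid (not narrowband
noise) so that the rectified-amplitude ground truth is analytic: the mean
of |A sin φ| over uniform phase is 2A/π. A narrowband-noise oscillator is
available behind `narrowband_noise=True`. Because a null cognitive-load
effect on induced alpha is a finding of interest in this design, condition
parameters can be set equal (`equal_condition_parameters` in the pipeline
config); the defaults carry distinct condition means.

All randomness derives from one seed through `SeedSequence` spawn keys
(subject × condition × purpose), so any subject can be regenerated in
isolation, bit-identically. Ground truth records every latent draw; the
induced-trough truth is the argmin of the generating envelope on the sample
grid. What passing tests show is that the pipeline recovers the parameters
of *this* generative model; real EEG adds non-stationarity, correlated
noise, reference effects and inter-subject montage variation that the model
does not contain.

## 3. Preprocessing

Order: HEOG rejection → blink regression → common average reference.
Re-referencing is listed first in typical acquisition descriptions, but CAR
mixes the ocular propagation across channels (each factor becomes
b − mean b); estimating the regression on the original reference keeps the
factors physically interpretable and auditable against ground truth.

* **HEOG rejection** flags trials whose |HEOG| strictly exceeds 50 µV
  ("exceeding" ⇒ a trial peaking exactly at the bound is kept). Rejection
  is mask-based and non-destructive; counts are logged.
* **Blink correction** is a pooled per-channel least-squares regression on
  VEOG over all retained trials and samples, computed on average-subtracted
  data: stimulus-locked components (P3) overlap blink pulses with a
  consistent sign and bias a raw regression by several percent at posterior
  channels, while subtraction of the across-trial mean leaves the
  propagation relation intact. This is a regression stand-in for dedicated
  ocular-correction algorithms and is validated only against synthetic
  ground truth (mean relative factor error ≈ 0.7% at default SNR). The
  corrected signal is scalp − b·VEOG; factors are exposed for audit.
* **CAR** subtracts the instantaneous mean over scalp channels; EOG
  channels are excluded and untouched. Idempotent.

## 4. Phase analysis

The evoked component is removed by subtracting the across-trial mean from
every trial; residuals are band-passed with the same filter and the
analytic-signal phase extracted. Phases are summarized per trial by the
circular mean over the analysis window (phase wraps; an arithmetic mean is
meaningless), and trials whose window-mean envelope falls below 0.05 µV are
excluded — the phase of a near-zero analytic signal is noise. Whether
phases should be taken per trial or per subject-average, and at the window
centre or as a window mean, is not fixed by the usual description of this
analysis; per-trial window-means are the default and both choices are
parameters. Phase concentration is quantified by the resultant vector
length and the Rayleigh test — an explicit statistical operationalization
of "randomly distributed polar values", which goes beyond the qualitative
plot.

## 5. Measurements

Amplitude windows are the printed profile: P3 350–410 ms, evoked alpha
140–155 ms, induced alpha 165–200 ms (closed windows, nearest-sample
endpoints). Peak *latencies* are identified per subject in wider search
windows (P3 250–600 ms, evoked 100–220 ms, induced 100–320 ms) at the
electrode with the largest grand-average extremum (EOG channels excluded;
Pz and PO6 with the default topographies) — the printed windows are
amplitude windows, and clipping latency searches to them would truncate the
latency distributions. Latencies stay on the 2 ms grid without
interpolation; ties break to the earliest sample. The induced measure
defaults to the signed extremum of largest absolute deviation ("absmax"):
the desynchronization is a trough, but the windows are described as
capturing maximum amplitudes, so both polarities are supported and the
default is a documented choice, not a claim about the original intent.

## 6. Statistics

* Shapiro–Wilk gates the paired behavioral/latency comparisons: Student t
  when normality is not rejected, Wilcoxon signed-rank otherwise. The
  "Wilcoxon U test with Z" reported for paired conditions is implemented as
  the signed-rank test with the continuity- and tie-corrected normal
  approximation (a paired "U test" is a common terminological slip).
* The rm-ANOVA is fully within-subject: per-effect orthonormal Helmert
  contrasts (Kronecker products for interactions), F from contrast scores,
  Greenhouse–Geisser ε̂ = tr(S)²/(q·tr(S²)) from the contrast-score
  covariance, GG p from ε-scaled dfs, partial η² = SS_eff/(SS_eff+SS_err).
  It matches pingouin exactly on one- and two-factor designs and a
  brute-force sums-of-squares oracle on a 2×3×2 toy; pingouin does not
  support the 2×6×7 three-factor design, hence the in-package
  implementation. Note that ε-scaling is only guaranteed to *increase* the
  p-value in the significance tail (p ≲ 0.2); for clearly non-significant
  effects it can go either way, as in SPSS/pingouin.
* Degenerate inputs: effects whose contrast scores are numerically zero
  (relative to the table's total sum of squares) report F = 0, p = 1.
* Bonferroni is min(1, m·p); α = 0.05 throughout; descriptives use n−1.
* Grand latency summaries are the unweighted mean of the two condition
  means, rounded half-up to integer ms — the only reading consistent with
  the printed grand values ((146+151)/2 → 149, (168+198)/2 → 183).

## 7. Pipeline and problem sizes

A single YAML/JSON config is the only parameter source; unknown keys are
rejected and every error names its field. Stages write a hash of the
config subset they depend on; re-running skips fresh stages and reproduces
deleted intermediates bit-identically. Large intermediates are not kept:
stages regenerate epochs deterministically from the seed and persist only
traces, tables, phase exports and the report (a full 26-subject run keeps
~60 MB on disk).

Problem sizes used by the test suite and the acceptance script, chosen to
exercise the full study geometry where it matters and smaller geometries
elsewhere: the complete pipeline runs at the study size (26 subjects × 2
conditions × 140 trials × 60 channels); parameter recovery uses 20
independent single-subject datasets at full trial count; statistical
calibration uses 2000 null replicates at n = 26; unit tests use reduced
trial counts where the property under test does not depend on n.

## 8. Known limitations

* No head model: topographies are schematic weights, so spatial statistics
  (the 6×7 ANOVA factors) exercise the bookkeeping, not realistic field
  patterns.
* The induced trace inherits a small nonlinear cross-term where evoked and
  induced activity overlap in time (rectification is nonlinear), a known
  property of subtraction-based TSE; the phase analysis exists precisely to
  show the residual is non-phase-locked.
* Epoch-edge filter transients are irreducible at this filter order and
  epoch length (§1); analysis windows should stay ≥100 ms from the epoch
  edges.
* Only BrainVision IEEE_FLOAT_32 / INT_16 (multiplexed or vectorized) and
  the internal `.npz` epoch store are supported; other formats error
  clearly.
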