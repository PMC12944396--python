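# Methods

## Problem setting

Wearable gesture-recognition interfaces (e.g. prosthetic-hand controllers)
record muscle activity on many channels — surface electromyography (sEMG,
electrical, useful band roughly 20–450 Hz) and pressure-based force myography
(pFMG, mechanical, band roughly 0–10 Hz) — but deployed systems can only
afford a few sensors. `dqiselect` implements a data-quality-driven way of
choosing a small channel subset (by default 3 of 8): score every channel with
five data quality indices (DQIs), learn how those indices relate to
recognition accuracy across subjects, and pick the combination predicted to
perform best for a new subject without ever training a classifier on that
subject's combinations.

## The five data quality indices

For each channel, with active (gesture) and rest (label 0) samples and the
Welch power spectral density `P(f)` of the active signal:

| index | definition | units | sensitive to |
|---|---|---|---|
| SNR | `20 log10(RMS_active / RMS_rest)` | dB | background noise floor |
| SMR | `10 log10(P_total / P_0–20Hz)` | dB | motion artifact (low-frequency drift) |
| OHM (Ω) | `sqrt(M2/M0) / (M1/M0)` with `Mn = ∫ f^n P(f) df` | ratio | spectral deformation |
| SHR | `10 log10(P_total / P_upper-20%)` | dB | high-frequency noise |
| DPR | `10 log10(max MPD / min MPD)`, MPD = mean density of 13 consecutive bins | dB | spectral peakedness vs a flat noise floor |

Numerical choices:

* All band powers use trapezoidal integration on the Welch grid; every
  denominator is floored at `1e-12`, so indices are finite on degenerate
  inputs (a warning is emitted for a near-zero spectrum).
* OHM is reported as the raw dimensionless ratio, which is the scale on which
  the quantity is conventionally quoted (a pure tone gives exactly 1); a dB
  variant is available via `ohm(spec, db=True)`.
* The upper-20 % band of SHR is `[0.8 f_max, f_max]` on the one-sided grid.
* Welch defaults: Hann taper, `nperseg` = 1 s of samples, 50 % overlap — the
  usual bias/variance compromise; all configurable.
* Preprocessing filters (20–450 Hz Butterworth band-pass plus a Q = 30 mains
  notch for sEMG, 10 Hz low-pass for pFMG) are applied forward-backward with
  one second of reflection padding: the high-Q notch settles slowly, and the
  default short padding would leak mains power back in at the record edges.
  The brief residual ring at the very boundaries is unavoidable for any
  finite record; steady-state mains attenuation is on the order of 10⁻⁶.
* `profile_recording` computes the indices per repetition and averages, with
  the repetition scope defaulting to whatever the caller designates as
  training repetitions. This reduces estimator variance and guarantees that
  DQIs used for selection never see test repetitions. Rest samples carry
  repetition id 0 and are pooled: each repetition's SNR compares that
  repetition's active RMS against the pooled rest RMS.

## Recognition pipeline

Features are extracted on 200 ms windows with a 40 ms stride, cut strictly
inside constant (label, repetition) segments so windows never straddle a
gesture or repetition boundary. sEMG channels yield RMS, VAR (unbiased), MAV,
SSI (simple square integral, `Σx²`), AAC and DASDV; pFMG channels yield IAV
(`Σ|x|`). These are the standard definitions from the myoelectric-control
literature. The classifier contract is a seeded 100-tree random forest with
library defaults; accuracies are stored as fractions in `[0, 1]` and rendered
as percentages only in reports.

The train/test split is by repetition (default 5 train / 4 test of 9), never
by shuffled windows, because windows within a repetition are strongly
correlated and would leak. For each subject, all `C(8,3) = 56` channel
combinations are evaluated; each row of the resulting combination table holds
the combination's mean DQI 5-vector (training repetitions only) and measured
test accuracy. Selection may also operate on *units* larger than one channel
(e.g. co-located sEMG-pFMG pairs) by passing channel-index groups; the DQI of
a combination is then the mean over all member channels.

## Selection methods

Both run under leave-one-subject-out (LOSO) cross-validation: the selector is
fitted on all other subjects' tables and the held-out subject's *measured*
accuracy of the chosen combination is what counts.

**ML-based.** Ordinary least squares of accuracy on the five DQIs pooled over
training subjects (`numpy.linalg.lstsq`, so a rank-deficient design yields the
minimum-norm solution plus a warning); seeded random-forest and SVR regressors
are drop-ins behind the same `predict` contract. The held-out subject's 56
combinations are scored with the fitted model and the argmax is selected, ties
broken toward the lexicographically smallest combination.

**Correlation-based.** Pearson correlation of each DQI with accuracy over the
pooled training rows; indices significant at p < 0.05 (no multiple-testing
correction — the gate is applied per index as stated) receive weight
`ρ_l / Σ_m |ρ_m|` over the significant set. The signed absolute-value
normalization is a deliberate choice: normalizing by the plain sum is unstable
when positive and negative correlations nearly cancel, while the `Σ|ρ|` form
preserves both the sign and the relative magnitude ranking. If no index is
significant the weights fall back to uniform 1/5 with a warning (otherwise
every combination would score zero and the argmax would be meaningless).
Combinations are scored by the weighted DQI sum on the raw index values by
default; optional per-index min-max normalization across the 56 candidates is
provided because the indices mix dB and ratio scales.

**Baselines.** Random selection is reported as its exact expectation — the
mean of all 56 measured accuracies — rather than a sampled mean, since every
accuracy is already computed; a seeded Monte-Carlo mode (`n_draws`) exists for
fidelity experiments. The feature-importance baseline trains the seeded forest
on all channels, sums impurity importances per channel, takes the top 3 and
measures that combination's accuracy. Paired t-tests across subjects compare
selected vs random accuracy (all-zero differences return t = 0, p = 1 by
convention).

## Synthetic cohort generator

Real armband datasets of this kind are typically not redistributable, so the
package ships a generator that emulates the recording protocol and serves as
ground truth for selection-recovery tests. Defaults (the study conditions for
the acceptance run): 10 subjects, 8 sEMG channels, 7 gestures × 9 repetitions
at 1 kHz, 1 s active blocks separated by 0.5 s rests — roughly 95 s per
subject, sized so a full cohort evaluation (560 random-forest fits) completes
in a few minutes on one CPU.

* **Carriers.** sEMG active bursts are band-limited (20–450 Hz) Gaussian noise
  under a Tukey envelope, amplitude-modulated per gesture — the standard
  surrogate for interference EMG. pFMG bursts are smooth (< 10 Hz) baseline
  shifts. Per-gesture gains are RMS-normalized so a channel's active/rest
  ratio equals its `target_snr_db` (the carrier is scaled by
  `sqrt(10^(SNR/10) − 1)` times the noise-floor RMS, so the *total* active RMS
  hits the target including the noise contribution).
* **Noise.** Three contaminant types: powerline (mains-frequency tone with
  random phase, amplitude = RMS), white Gaussian noise, and motion artifact
  (white noise low-passed below 20 Hz and rescaled to the requested RMS — by
  construction exactly the band SMR penalizes).
* **Quality engineering.** Three designated good channels get ~16 dB SNR, a
  wide per-gesture gain separation (±45 %), and light contamination; the
  other five get ~7 dB, narrow separation (±12.5 %), strong motion artifact
  and powerline. Per-subject jitter (gain noise, ±1 dB SNR) makes subjects
  distinct while preserving the quality ordering. Subject i is seeded with
  `master_seed + i`, so the whole cohort is a pure function of its spec.
* **What it does not emulate.** Motor-unit physiology, electrode-shift or
  inter-session drift, crosstalk between channels, or class-dependent spectral
  (rather than amplitude) signatures. Passing recovery tests on this cohort
  shows the selection machinery is correct and leakage-free under a known
  quality ordering — not that the method's accuracy figures transfer to any
  particular real dataset.

## Degenerate inputs and tie-breaking

* Windows shorter than 2 samples, signals shorter than `nperseg`, spectra with
  fewer bins than the DPR window, empty channel sets and overlapping
  repetition splits raise typed errors naming the offending quantity.
* All argmax selections break ties toward the lexicographically smallest
  combination, which makes every run reportable and repeatable.
* Recordings without rest samples cannot produce an SNR; the error says so and
  suggests labeling rest periods.

## Known limitations

* Selection quality on real data depends on the DQI-accuracy relationship
  transferring across subjects; the generator builds that relationship in, so
  synthetic results are a correctness check, not a field validation.
* Only the single repetition-based split the protocol prescribes is
  implemented (no nested cross-validation over windows).
* The subset size k is a parameter but the shipped defaults and tests target
  k = 3 of 8 channels.
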