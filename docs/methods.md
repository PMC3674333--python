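# Methods

This note documents the models, parameter choices and numerical decisions
behind `muerd`. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The analysis pipeline

The package analyses Mu-rhythm (8–11 Hz) event-related desynchronization
(ERD) and synchronization (ERS) in a fully within-subject design: each
subject is recorded in three tDCS priming sessions (anodal, cathodal, sham),
and within each session performs two tasks (observation, imagery) with three
movement types each (biological, non-biological, and a white-noise control).
Each condition consists of two fixed-length trials.

Preprocessing follows a fixed, numbered order:

1. **Band-pass filtering**, 1–30 Hz. The corner frequencies are the
   protocol's; the realization is ours: a 4th-order Butterworth high-pass
   and low-pass, each applied forward–backward (`sosfiltfilt`), i.e.
   zero-phase with 8th-order effective magnitude response. Zero phase keeps
   epoch boundaries and artifact latencies undistorted. The two sections are
   cascaded into one second-order-section filter; since both are applied
   forward–backward the cascade is mathematically the same as applying them
   in sequence (up to edge padding).
2. **Trimming and concatenation**: the first and last 10 s of each trial
   are dropped and the remainders concatenated (two 80-s trials → 120 s).
   Every retained sample keeps a pointer to its source trial and original
   sample index.
3. **Epoching** into non-overlapping 2-s epochs. Epochs restart at each
   trial seam — the trial halves are physically discontinuous — and the
   trailing remainder of each trial is dropped.
4. **Threshold artifact rejection**, evaluated *before* re-referencing (it
   is step 3 of the protocol's list): an epoch is rejected if the
   above-minus-below periocular difference of either eye exceeds 140 µV, the
   outer-canthus left-minus-right difference exceeds 55 µV, or any channel
   exceeds 200 µV. Comparisons use the instantaneous absolute maximum by
   default; a peak-to-peak mode is available
   (`detect_artifacts(..., mode="peak-to-peak")`) because the original
   description does not disambiguate the two.
5. **Average re-referencing**: the instantaneous mean over scalp channels
   (all channels minus the six periocular/canthus sensors) is subtracted
   from every channel. Idempotent by construction.
6. **Baseline correction** from the 200 ms immediately preceding each
   epoch's onset, looked up in the untrimmed (filtered, re-referenced)
   recording — the only reading under which a pre-epoch window exists for
   every epoch, the first epoch of a trial drawing its baseline from the
   trimmed lead-in.

**Band power.** Per retained epoch and channel, a complex Morlet transform
is taken at 8–11 Hz in 0.5-Hz steps with 7 cycles (σ_t = n_cycles/2πf;
wavelets truncated at ±3.5 σ_t). Power is the squared magnitude averaged
over time — excluding the cone-of-influence margin (the longest wavelet's
half-support) at both epoch edges — then over frequencies, then over
epochs. Wavelets are unit-gain at their centre frequency and the frequency
average is divided by the bank's mean in-band power gain
G = mean_i (1/B)∫_band exp(−4π²σ_i²(f−f_i)²) df, which makes the estimate
approximately unbiased for the band-limited variance (µV²) of a flat-band
process; tests verify agreement with a Welch periodogram integral within 5%.
The wavelet grid, cycle count and edge policy are package choices (the
protocol names only the 8–11 Hz band); the convolution runs in single
precision, whose ~1e-7 relative rounding is orders of magnitude below the
statistical error of any 2-s epoch estimate.

**ERD index.** For each subject × session × task × movement (biological,
non-biological), the per-channel condition power (mean over all retained
epochs, pooled across the condition's trials) is divided by the same task's
control-condition power and log-transformed: `erd = ln(P_cond / P_control)`.
Negative = ERD, positive = ERS. The natural log is a package choice (the
base rescales all values by a constant and affects no statistic; it is
recorded in the table metadata). The ratio is taken between condition-level
mean powers, not averaged per-epoch ratios, which is robust to unequal
retained-epoch counts. Electrode units are C3, C4, Cz (single sensors) and
surroundC3/surroundC4, the arithmetic means of the six member sensors'
per-electrode log ratios (the unit is the mean of the dependent variable,
not the log of mean powers).

**Statistics.** `rm_anova` implements the classical univariate
decomposition for complete balanced fully-within designs: subject is a
random blocking factor crossed with all treatment factors; for every effect
E, SS_E comes from the Möbius (Yates) expansion of marginal means, the error
stratum is the E × subject interaction, F = MS_E/MS_error(E), and partial
η² = SS_E/(SS_E+SS_error(E)) (algebraically equal to F·df1/(F·df1+df2)).
The expansion is orthogonal, so all effect, error and subject strata sum to
the total SS; the function verifies this and records the residual. No
sphericity correction is applied by default — the reported statistics use
uncorrected degrees of freedom — but a Greenhouse–Geisser ε per effect is
available behind the `gg` flag as an advisory column. A zero error stratum
with a non-zero effect is reported as F = +∞, p = 0.

Fisher LSD comparisons between the cells of an effect use that effect's own
error stratum, SE = √(2·MS_error/n_obs) with df = df_error, where n_obs is
the number of observations each cell mean averages (subjects × levels of the
factors not in the effect). This reduces to √(2·MS/n_subjects) for
full-design cells and to the exact paired-t equivalence for single-factor
designs. No multiplicity adjustment (that is what "LSD" means). The error
stratum can be overridden (`error_term=`) for the alternative convention of
testing sub-effect contrasts against a higher-order stratum.

## The synthetic-data generator

No raw data accompany the study, so all quantitative validation runs on
synthetic experiments with known injected structure. Each trial is:

* **1/f background noise** on every channel (spectrum ∝ f^(−1) above 1 Hz,
  flat below), normalized to 2.5 µV RMS per channel;
* a **Mu oscillator** on every scalp channel: white noise band-passed to
  8–11 Hz (raised-cosine edges), i.e. a stationary narrowband process with
  realistic within-epoch power variability rather than a sinusoid, scaled to
  15 µV RMS × condition factor × subject factor. Condition factors are
  declared per (task, movement, cluster-role); because power goes as
  amplitude², a factor g injects a true log power ratio of 2·ln g, which is
  what `GroundTruth` records. Subject factors are log-normal
  (SD 0.25 log units) so they cancel exactly from every ERD index;
* **artifacts** as Poisson event streams: blinks (400-ms raised-cosine
  pulses, +60%/−40% of the nominal 400 µV deflection on the above/below-eye
  sensors of both eyes, 4/min) and high-amplitude transients (200-ms
  raised-cosine pulses of 450 µV on one random scalp channel, 1/min).
  Amplitudes are chosen so the *filtered* waveforms clear their rejection
  rules decisively (the 1-Hz zero-phase high-pass attenuates a 400-ms pulse
  to ~61% of its nominal peak).

Randomness derives from one master seed through fixed `SeedSequence` spawn
keys per subject and per (subject, session), so any subset of an experiment
regenerates identically.

**Choice of SNR defaults.** The generator's Mu/background amplitudes are the
package's study conditions and were fixed once, to satisfy the design
requirement that the pipeline recover injected C3 effects across
[−1.4, +0.7] log units to within ±0.05 in the mean. Two small biases are
inherent: (i) the synthetic channels are *independent* sources (no volume
conduction is modelled), so average-referencing mixes 1/n of the other
channels' Mu power into each channel — a ≈0.02 log-unit attenuation floor at
128 channels that grows on small nets; (ii) broadband noise power inside and
near the band enters both numerator and denominator, shrinking ratios toward
zero. A 15 µV Mu rhythm over a 2.5 µV (1–30 Hz) background — a subject with
a prominent idling rhythm — keeps the combined bias within the requirement.
Consequences for interpretation: passing recovery tests demonstrate the
estimator chain is calibrated at favourable SNR; they do not certify
performance on low-SNR recordings, volume-conducted topographies, or
non-stationary artifacts, none of which the generator emulates.

## Simulation studies (`muerd.studies`)

Problem sizes are package choices balancing Monte-Carlo precision against
one-core runtimes of a few minutes per study:

* **Null calibration** — 500 experiments of 8 subjects × 3 sessions with all
  factors 1.0, 8-s trials at 100 Hz on the 21-channel minimal layout,
  trimming reduced to 1 s; the C3/C4 four-way ANOVA's per-effect type-I
  error at α = 0.05 is checked against [0.03, 0.07] (±≈2 SD of
  Binomial(500, 0.05)). Artifacts are disabled here: the study isolates the
  statistical chain, and artifact handling is validated separately.
* **Parameter recovery** — 200 subjects × 1 sham session per injected
  effect (−1.4, −0.35, +0.7), 12-s trials at 100 Hz on the full 128-channel
  layout (see the bias discussion above for why the small net is not used
  here).
* **Post-hoc power** — 100 replicates of the full 21-subject design with the
  sham-session sign pattern (C3: −0.35 biological, +0.15 non-biological;
  0.5 log-unit separation) injected in the sham session only, 10-s trials;
  the (sham, biological, C3) vs (sham, nonbiological, C3) LSD contrast is
  required to be significant in ≥80% of replicates.
* **Artifact recovery** — one session with 40-s trials and elevated
  transient rate. Expected rejections are derived from ground truth alone:
  the artifact-only signal is rendered from the recorded placements, passed
  through the same published filter, and thresholded with a guard band
  (±50/±20/±90 µV for the three rules). Epochs overlapping only the
  sub-threshold tail of a waveform fall inside the guard band, are
  inherently ambiguous under background noise, and are excluded (and
  counted); sensitivity and specificity must be exactly 1 on the rest.

## Degenerate inputs and numerical conventions

* Sample indexing is 0-based; annotation and epoch spans are half-open.
* Trials shorter than twice the trim are a degenerate-input error; epochs
  with no 200-ms pre-onset window are an error naming the epoch; conditions
  with zero retained epochs propagate a degenerate-condition error naming
  the cell; unbalanced ANOVA input is an error listing missing cells — no
  imputation anywhere.
* ERD requires strictly positive powers (a zero control power is a domain
  error, not −∞).
* EDF output is 16-bit with integer-rounded physical limits per channel
  (quantization ≤ range/65535); recordings whose length is not a whole
  number of 1-s records are zero-padded on disk and the true length stored
  in the reserved header field, which the package's reader honours.
* Human-readable reports round F/p/η² in the field's style; all
  machine-readable outputs keep full precision.

## Known limitations

* No volume conduction, realistic EOG spectra, head-model forward
  simulation, channel interpolation, ICA/regression ocular correction, or
  time-resolved ERD curves (all out of scope).
* The ANOVA handles complete balanced within-subject designs only.
* Per-subject Mu peak selection is not implemented; the band is fixed at
  8–11 Hz.
* The illustrative per-session effect maps (`illustrative_session_maps`)
  reproduce a qualitative sign pattern for demonstrations and are not
  fitted to any empirical effect sizes.
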