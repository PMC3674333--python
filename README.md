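# muerd

Mu-rhythm ERD/ERS analysis for EEG experiments on movement observation and
imagery under tDCS priming — plus a synthetic-EEG generator with known
injected effects, so every stage of the pipeline can be validated against
ground truth.

## Who this is for

Researchers analysing sensorimotor (Mu, 8–11 Hz) oscillations in
within-subject designs: each subject performs movement *observation* and
*imagery* of *biological* and *non-biological* movement, each with its own
white-noise *control*, across three stimulation sessions (anodal, cathodal,
sham tDCS over left M1). The package turns raw multichannel recordings
(EDF or delimited text, EGI-128 sensor numbering) into a tested chain of:

1. preprocessing — 1–30 Hz zero-phase band-pass; removal of the first and
   last 10 s of each 80-s trial and concatenation (→ 120 s per condition);
   2-s epochs; threshold artifact rejection (>140 µV above/below-eye
   difference, >55 µV canthus difference, >200 µV any channel); average
   re-referencing; 200-ms pre-epoch baseline correction;
2. spectral analysis — complex Morlet wavelet band power at 8–11 Hz
   (0.5-Hz grid, 7 cycles), calibrated to band-limited signal variance in µV²;
3. the ERD index — per channel, `erd = ln(P_condition / P_control)` with the
   same task's control as denominator (negative = desynchronization,
   positive = synchronization), aggregated to the five electrode units C3,
   C4, Cz, surround-C3 and surround-C4 (surrounds = mean of six sensors);
4. statistics — from-scratch fully within-subject factorial repeated-measures
   ANOVA (condition × movement × tDCS × hemisphere, and the
   condition × movement × tDCS × electrodes model for Cz/surrounds) with
   per-effect error strata, partial η², optional Greenhouse–Geisser ε, and
   Fisher LSD post-hoc comparisons.

The core statistic for each effect E is

    F = MS_E / MS_{E×subject},   partial η² = SS_E / (SS_E + SS_{E×subject}),

with df_E = Π(levels−1) and df_error = df_E·(n−1); see `docs/methods.md`
for the full model and every numerical convention.

## Worked example

Simulate a 10-subject experiment in which the sham session carries the
classic contralateral pattern — Mu ERD at C3 for biological movement
(−0.35 log units) and mild ERS for non-biological (+0.15) — and analyse it:

```python
from muerd import SynthSpec, minimal_layout, analyze_erd_table
from muerd.synth import sham_pattern_erd_map
from muerd.studies import reduced_params, simulate_erd_table
from muerd.stats import format_anova_report

layout = minimal_layout()
spec = SynthSpec(n_subjects=10, sfreq=100.0, trial_duration_s=12.0,
                 erd_map_by_session={"sham": sham_pattern_erd_map()}, seed=42)
table = simulate_erd_table(spec, layout, reduced_params())
print(f"ERD table: {len(table)} rows")
print(table.head(4).to_string(index=False))
res = analyze_erd_table(table)
print(format_anova_report(
    res["anova_main"].loc[["movement", "movement:hemisphere",
                           "movement:tdcs:hemisphere"]],
    title="C3/C4 model (selected effects)"))
```

prints

```
ERD table: 600 rows
 subject session        task   movement       unit       erd
       0  anodal observation biological         C3 -0.308560
       0  anodal observation biological         C4  0.022550
       0  anodal observation biological         Cz  0.080830
       0  anodal observation biological surroundC3  0.085551
C3/C4 model (selected effects)
  movement: F(1, 9) = 6.74; p = 0.029; eta2p = 0.43
  movement:hemisphere: F(1, 9) = 22.10; p = 0.00112; eta2p = 0.71
  movement:tdcs:hemisphere: F(2, 18) = 20.75; p = 2.12e-05; eta2p = 0.70
```

The 600 rows are 10 subjects × 3 sessions × 2 tasks × 2 movements × 5
electrode units; each `erd` value is a control-normalized log power ratio
(dimensionless). Because the injected effect lives at C3 only and only under
sham, it surfaces as movement × hemisphere structure modulated by tDCS — the
three-way interaction — rather than as a plain movement main effect.

## Command line

```bash
muerd simulate --config config.yaml --out data/      # synthetic experiment + ground truth
muerd run      --data data/ --out results/           # ERD table, 2 ANOVAs, LSD, report
muerd erd      --data data/ --out results/           # signal side only → erd_table.tsv
muerd anova    --erd-table results/erd_table.tsv --out results/   # stats side only
```

All stages exchange plain delimited files; `erd_table.tsv` is the contract
between the signal side and the stats side. Exit codes: 0 ok, 2 validation,
3 I/O, 4 degenerate data.

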