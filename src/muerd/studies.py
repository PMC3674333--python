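"""Simulation studies: null calibration, parameter recovery, artifact
recovery and post-hoc power, all on synthetic data with known ground truth.

These are the package's validation experiments.  Problem sizes are reduced
relative to the full study design (shorter trials, and the 21-channel
minimal layout where per-channel bias is immaterial) so each study runs in
minutes on one core; the full-size generator defaults remain untouched.

Every study takes a single integer seed and derives all further randomness
from it, so results are exactly reproducible.
"""

from __future__ import annotations

from typing import Dict, Sequence

import numpy as np
import pandas as pd

from .conditions import SESSIONS, TASKS, ConditionKey
from .erd import build_erd_table
from .layout import ChannelLayout, default_egi128_layout, minimal_layout
from .pipeline import PipelineParams, process_session
from .preprocess import (
    ArtifactThresholds,
    PreprocessParams,
    bandpass_filter,
    condition_trials,
    detect_artifacts,
    epoch as cut_epochs,
    trim_and_concatenate,
)
from .stats import fisher_lsd, rm_anova, erd_table_to_design
from .synth import (
    SynthSpec,
    full_erd_map,
    generate_session,
    render_artifacts,
    sham_pattern_erd_map,
)

#: pipeline settings for reduced trial lengths (everything else at defaults)
def reduced_params(trim_s: float = 1.0) -> PipelineParams:
    return PipelineParams(preprocess=PreprocessParams(trim_s=trim_s))


def _sub_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


def simulate_erd_table(
    spec: SynthSpec,
    layout: ChannelLayout,
    params: PipelineParams,
    sessions: Sequence[str] = SESSIONS,
) -> pd.DataFrame:
    """Generate an experiment and push it through the full signal pipeline."""
    results = []
    for subject in range(spec.n_subjects):
        for session in sessions:
            rec, _ = generate_session(spec, subject, session, layout=layout)
            sp, _ = process_session(rec, subject, session, layout, params)
            results.append(sp)
    return build_erd_table(results, layout)


# ---------------------------------------------------------------------------
# null calibration


def null_calibration(
    n_experiments: int = 500,
    n_subjects: int = 8,
    trial_duration_s: float = 8.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Type-I-error calibration of the main ANOVA on null experiments.

    Each experiment is a full synthetic design with every amplitude factor at
    1.0 (no true effect anywhere) pushed through the complete signal pipeline
    and the C3/C4 ANOVA.  Artifacts are disabled -- this study isolates the
    statistical chain, and artifact handling is validated separately.

    Returns a DataFrame of p values, one row per experiment, one column per
    effect of the four-way model.
    """
    rng = np.random.default_rng(seed)
    layout = minimal_layout()
    params = reduced_params()
    rows = []
    for _ in range(n_experiments):
        spec = SynthSpec(
            n_subjects=n_subjects,
            sfreq=100.0,
            trial_duration_s=trial_duration_s,
            blink_rate=0.0,
            transient_rate=0.0,
            seed=_sub_seed(rng),
        )
        table = simulate_erd_table(spec, layout, params)
        anova = rm_anova(erd_table_to_design(table, "main"))
        rows.append(anova["p"])
    out = pd.DataFrame(rows).reset_index(drop=True)
    return out


def rejection_rates(pvals: pd.DataFrame, alpha: float = 0.05) -> pd.Series:
    return (pvals < alpha).mean(axis=0)


# ---------------------------------------------------------------------------
# parameter recovery


def recovery_study(
    targets: Sequence[float] = (-1.4, -0.35, 0.7),
    n_subjects: int = 200,
    trial_duration_s: float = 12.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean recovered C3 ERD vs. injected log power ratio.

    Uses the full 128-channel layout (average-referencing on very small nets
    adds a layout artifact that has nothing to do with the estimator) with
    one sham session per synthetic subject and shortened trials.
    """
    rng = np.random.default_rng(seed)
    layout = default_egi128_layout()
    params = reduced_params()
    rows = []
    for target in targets:
        g = float(np.exp(target / 2.0))
        overrides = {(t, "biological", "C3"): g for t in TASKS}
        spec = SynthSpec(
            n_subjects=n_subjects,
            sfreq=100.0,
            trial_duration_s=trial_duration_s,
            erd_map=full_erd_map(overrides=overrides),
            seed=_sub_seed(rng),
        )
        table = simulate_erd_table(spec, layout, params, sessions=("sham",))
        sel = table[(table.movement == "biological") & (table.unit == "C3")]["erd"]
        rows.append(
            {
                "target": target,
                "recovered": sel.mean(),
                "abs_error": abs(sel.mean() - target),
                "se": sel.std(ddof=1) / np.sqrt(len(sel)),
                "n_values": len(sel),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# post-hoc contrast power


def lsd_power_study(
    n_replicates: int = 100,
    n_subjects: int = 21,
    bio_c3_log_ratio: float = -0.35,
    nonbio_c3_log_ratio: float = 0.15,
    trial_duration_s: float = 10.0,
    seed: int = 0,
    alpha: float = 0.05,
) -> Dict[str, float]:
    """Monte-Carlo power of the C3 biological-vs-nonbiological LSD contrast.

    The sham-session sign pattern (contralateral ERD for biological movement,
    mild ERS for non-biological; separation 0.5 log units by default) is
    injected in the sham session only; each replicate runs the full design
    (n subjects x 3 sessions) and tests the (sham, biological, C3) vs
    (sham, nonbiological, C3) cells of the tdcs x movement x hemisphere
    effect.
    """
    rng = np.random.default_rng(seed)
    layout = minimal_layout()
    params = reduced_params()
    sham_map = sham_pattern_erd_map(bio_c3_log_ratio, nonbio_c3_log_ratio)
    pvals = []
    for _ in range(n_replicates):
        spec = SynthSpec(
            n_subjects=n_subjects,
            sfreq=100.0,
            trial_duration_s=trial_duration_s,
            erd_map_by_session={"sham": sham_map},
            seed=_sub_seed(rng),
        )
        table = simulate_erd_table(spec, layout, params)
        design = erd_table_to_design(table, "main")
        lsd = fisher_lsd(
            design, within=["condition", "movement", "tdcs", "hemisphere"],
            effect=["tdcs", "movement", "hemisphere"],
        )
        # cells are ordered by the design's factor order (movement, tdcs, hemisphere)
        a = ("biological", "sham", "C3")
        b = ("nonbiological", "sham", "C3")
        row = lsd[
            ((lsd.cell_a == a) & (lsd.cell_b == b))
            | ((lsd.cell_a == b) & (lsd.cell_b == a))
        ]
        pvals.append(float(row["p"].iloc[0]))
    pvals = np.array(pvals)
    return {
        "power": float((pvals < alpha).mean()),
        "median_p": float(np.median(pvals)),
        "n_replicates": n_replicates,
    }


# ---------------------------------------------------------------------------
# artifact recovery


def artifact_recovery_study(
    seed: int = 0,
    trial_duration_s: float = 40.0,
    trim_s: float = 2.0,
    veog_guard: float = 50.0,
    heog_guard: float = 20.0,
    amp_guard: float = 90.0,
) -> Dict[str, float]:
    """Sensitivity/specificity of threshold rejection against ground truth.

    Epochs are classified a priori from the injected artifacts alone: the
    artifact-only signal (rendered from the recorded placements) is passed
    through the same published band-pass filter, and an epoch whose
    artifact-only extremum clears a rule's threshold by more than the guard
    band *must* be rejected, while an epoch below every threshold by more
    than the guard *must* be retained.  Epochs whose artifact-only extremum
    falls inside a guard band overlap only the sub-threshold tail of a
    waveform and are inherently ambiguous under background noise; they are
    excluded and counted.
    """
    layout = minimal_layout()
    spec = SynthSpec(
        n_subjects=1,
        sfreq=125.0,
        trial_duration_s=trial_duration_s,
        transient_rate=2.0,
        seed=seed,
    )
    rec, gt = generate_session(spec, 0, "sham", layout=layout)
    art_only = render_artifacts(rec, gt, layout)
    filt = bandpass_filter(rec)
    filt_art = bandpass_filter(art_only)

    thr = ArtifactThresholds()
    hi = ArtifactThresholds(
        thr.veog_diff + veog_guard, thr.heog_diff + heog_guard, thr.abs_amp + amp_guard
    )
    lo = ArtifactThresholds(
        thr.veog_diff - veog_guard, thr.heog_diff - heog_guard, thr.abs_amp - amp_guard
    )

    pp = PreprocessParams(trim_s=trim_s)
    n_must_reject = n_rejected_ok = n_must_keep = n_kept_ok = n_ambiguous = total = 0
    for task in TASKS:
        for movement in ("biological", "nonbiological", "control"):
            key = ConditionKey("sham", task, movement)
            trials, offsets = condition_trials(filt, key)
            seg = trim_and_concatenate(trials, pp.trim_s, source_offsets=offsets)
            eps = detect_artifacts(cut_epochs(seg, pp.epoch_s, key), layout, thr)

            a_trials, a_offsets = condition_trials(filt_art, key)
            a_seg = trim_and_concatenate(a_trials, pp.trim_s, source_offsets=a_offsets)
            a_eps = cut_epochs(a_seg, pp.epoch_s, key)
            pred_hi = ~detect_artifacts(a_eps, layout, hi).retained  # clears +guard
            pred_lo = ~detect_artifacts(a_eps, layout, lo).retained  # clears -guard

            actual_rejected = ~eps.retained
            total += eps.n_epochs
            for i in range(eps.n_epochs):
                if pred_hi[i]:
                    n_must_reject += 1
                    n_rejected_ok += int(actual_rejected[i])
                elif not pred_lo[i]:
                    n_must_keep += 1
                    n_kept_ok += int(not actual_rejected[i])
                else:
                    n_ambiguous += 1
    return {
        "sensitivity": n_rejected_ok / n_must_reject if n_must_reject else float("nan"),
        "specificity": n_kept_ok / n_must_keep if n_must_keep else float("nan"),
        "n_must_reject": n_must_reject,
        "n_must_keep": n_must_keep,
        "n_ambiguous": n_ambiguous,
        "n_epochs": total,
    }


# ---------------------------------------------------------------------------
# ERD index invariances on pipeline output


def scale_invariance_study(seed: int = 0, scales: Sequence[float] = (0.5, 2.0)) -> float:
    """Max |change| of any pipeline ERD value when a clean recording is
    rescaled by a constant (artifact thresholds are not engaged)."""
    layout = minimal_layout()
    params = reduced_params()
    spec = SynthSpec(
        n_subjects=1, sfreq=125.0, trial_duration_s=12.0,
        blink_rate=0.0, transient_rate=0.0, seed=seed,
    )
    rec, _ = generate_session(spec, 0, "sham", layout=layout)
    sp, _ = process_session(rec, 0, "sham", layout, params)
    base = build_erd_table([sp], layout)["erd"].to_numpy()
    worst = 0.0
    for c in scales:
        scaled = rec.copy_with(rec.data * c)
        sp_c, _ = process_session(scaled, 0, "sham", layout, params)
        erd_c = build_erd_table([sp_c], layout)["erd"].to_numpy()
        worst = max(worst, float(np.max(np.abs(erd_c - base))))
    return worst
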