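"""End-to-end orchestration: recording -> condition powers -> ERD table -> ANOVA.

This is the glue the CLI and the simulation studies share.  Each stage is the
public function of its module; this file only fixes the order (filter,
trim/concatenate, epoch, artifact detection, average reference, baseline,
wavelet power) and the bookkeeping (rejection report, ERD table assembly).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .conditions import MOVEMENTS, TASKS, ConditionKey
from .erd import SessionPowers, build_erd_table
from .io import Recording
from .layout import ChannelLayout
from .preprocess import (
    PreprocessParams,
    average_reference_recording,
    bandpass_filter,
    preprocess_condition,
    rejection_counts,
)
from .spectral import WaveletParams, condition_power, mu_band_power
from .stats import erd_table_to_design, fisher_lsd, rm_anova


@dataclass(frozen=True)
class PipelineParams:
    """All tunables of the signal side of the pipeline."""

    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    wavelet: WaveletParams = field(default_factory=WaveletParams)
    #: 'units' computes band power only on the reported electrode units,
    #: 'all' on every channel
    power_channels: str = "units"


def process_session(
    recording: Recording,
    subject: int,
    session: str,
    layout: ChannelLayout,
    params: PipelineParams = PipelineParams(),
) -> Tuple[SessionPowers, List[Dict]]:
    """Run preprocessing and band power for every condition of one session.

    Returns the condition-level powers and a rejection report (one record per
    condition with kept/rejected counts by reason).
    """
    filtered = bandpass_filter(
        recording,
        params.preprocess.filter_low_hz,
        params.preprocess.filter_high_hz,
        params.preprocess.filter_order,
    )
    baseline_source = average_reference_recording(filtered, layout)
    channels = (
        layout.analysis_channels if params.power_channels == "units" else None
    )
    powers: Dict[Tuple[str, str], pd.Series] = {}
    retained: Dict[Tuple[str, str], int] = {}
    report: List[Dict] = []
    for task in TASKS:
        for movement in MOVEMENTS:
            key = ConditionKey(session, task, movement)
            eps = preprocess_condition(
                filtered, key, layout, params.preprocess, baseline_source
            )
            table = mu_band_power(eps, params.wavelet, channels)
            mean_power, n_kept = condition_power(table)
            powers[(task, movement)] = mean_power
            retained[(task, movement)] = n_kept
            counts = rejection_counts(eps)
            report.append(
                {"subject": subject, "session": session, "task": task,
                 "movement": movement, **counts}
            )
    return SessionPowers(subject, session, powers, retained), report


def run_experiment(
    sessions: Iterable[Tuple[int, str, Recording]],
    layout: ChannelLayout,
    params: PipelineParams = PipelineParams(),
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Process many (subject, session, Recording) triples into the long-format
    ERD table plus the pooled rejection report."""
    results, report = [], []
    for subject, session, rec in sessions:
        sp, rep = process_session(rec, subject, session, layout, params)
        results.append(sp)
        report.extend(rep)
    erd_table = build_erd_table(results, layout)
    return erd_table, pd.DataFrame(report)


def analyze_erd_table(
    erd_table: pd.DataFrame, gg: bool = False
) -> Dict[str, pd.DataFrame]:
    """Both reported ANOVA models plus full-interaction LSD tables."""
    out: Dict[str, pd.DataFrame] = {}
    for model in ("main", "surround"):
        design = erd_table_to_design(erd_table, model)
        factors = [c for c in design.columns if c not in ("subject", "erd")]
        anova = rm_anova(design, dv="erd", subject="subject", within=factors, gg=gg)
        out[f"anova_{model}"] = anova
        out[f"lsd_{model}"] = fisher_lsd(
            design, dv="erd", subject="subject", within=factors, anova=anova
        )
    return out
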