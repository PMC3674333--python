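"""Preprocessing: filtering, trial trimming, epoching, artifact rejection,
average re-referencing and baseline correction.

The pipeline order is fixed -- filter, trim/concatenate, epoch, detect
artifacts, re-reference, baseline-correct -- and artifact thresholds are
evaluated on the filtered but *not yet re-referenced* signal.  Epochs never
span the seam between concatenated trials (the trial halves are physically
discontinuous), and each epoch keeps a pointer to its source trial and
original sample index so the 200-ms pre-epoch baseline window can be looked
up in the untrimmed recording.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal

from .conditions import ConditionKey
from .errors import DegenerateDataError, LayoutError, ParameterError
from .io import Recording
from .layout import ChannelLayout

REASON_VEOG = "veog"
REASON_HEOG = "heog"
REASON_AMPLITUDE = "amplitude"


@dataclass(frozen=True)
class ArtifactThresholds:
    """Rejection thresholds in microvolt.

    ``veog_diff``: above-eye minus below-eye difference; ``heog_diff``:
    left-minus-right outer-canthus difference; ``abs_amp``: any single
    channel's amplitude.
    """

    veog_diff: float = 140.0
    heog_diff: float = 55.0
    abs_amp: float = 200.0

    def __post_init__(self) -> None:
        for name in ("veog_diff", "heog_diff", "abs_amp"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"threshold {name} must be strictly positive")


@dataclass
class Segment:
    """Trimmed, concatenated condition data with per-sample provenance."""

    data: np.ndarray  # (n_channels, n_samples)
    sfreq: float
    channel_ids: Sequence[int]
    source_trial: np.ndarray  # per-sample index of the source trial
    source_index: np.ndarray  # per-sample index into the source Recording

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class EpochSet:
    """Fixed-length epochs with provenance and a rejection mask."""

    epochs: np.ndarray  # (n_epochs, n_channels, n_samples)
    sfreq: float
    channel_ids: Sequence[int]
    onsets: np.ndarray  # epoch onsets in segment coordinates
    source_trials: np.ndarray
    source_onsets: np.ndarray  # epoch onsets in source-Recording coordinates
    epoch_length_s: float
    condition: Optional[ConditionKey] = None
    reject_reasons: Optional[List[Tuple[str, ...]]] = None  # None = not yet screened

    def __post_init__(self) -> None:
        if self.epochs.ndim != 3:
            raise ParameterError("epochs must be 3-D")
        if np.any(np.diff(self.onsets) <= 0):
            raise ParameterError("epoch onsets must be strictly increasing")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def retained(self) -> np.ndarray:
        """Boolean mask of retained epochs (all True before screening)."""
        if self.reject_reasons is None:
            return np.ones(self.n_epochs, dtype=bool)
        return np.array([len(r) == 0 for r in self.reject_reasons])

    def channel_rows(self, channel_ids: Sequence[int]) -> np.ndarray:
        index = {c: i for i, c in enumerate(self.channel_ids)}
        try:
            return np.array([index[int(c)] for c in channel_ids])
        except KeyError as exc:
            raise LayoutError(f"channel {exc} not present in epochs") from exc


# ---------------------------------------------------------------------------
# (1) filtering


def _band_sos(low: float, high: float, sfreq: float, order: int) -> Tuple[np.ndarray, np.ndarray]:
    nyq = sfreq / 2.0
    if not (0 < low < high):
        raise ParameterError(f"need 0 < low < high, got ({low}, {high})")
    if high >= nyq:
        raise ParameterError(f"high corner {high} Hz >= Nyquist {nyq} Hz")
    hp = signal.butter(order, low, btype="highpass", fs=sfreq, output="sos")
    lp = signal.butter(order, high, btype="lowpass", fs=sfreq, output="sos")
    return hp, lp


def bandpass_filter(
    recording: Recording, low: float = 1.0, high: float = 30.0, order: int = 4
) -> Recording:
    """Zero-phase band-pass: 4th-order Butterworth high-pass then low-pass,
    each applied forward-backward (no latency distortion of epoch edges)."""
    hp, lp = _band_sos(low, high, recording.sfreq, order)
    out = signal.sosfiltfilt(np.vstack([hp, lp]), recording.data, axis=-1)
    return recording.copy_with(out.astype(recording.data.dtype, copy=False))


# ---------------------------------------------------------------------------
# (2) trimming, concatenation, epoching


def trim_and_concatenate(
    trials: Sequence[Recording], trim_s: float = 10.0,
    source_offsets: Optional[Sequence[int]] = None,
) -> Segment:
    """Drop ``trim_s`` seconds from both ends of each trial and concatenate.

    ``source_offsets`` gives each trial's onset within a common source
    recording (defaults to each trial's own coordinate frame); retained
    samples keep pointers to their source trial and original index.
    """
    if not trials:
        raise DegenerateDataError("no trials to concatenate")
    sfreq = trials[0].sfreq
    channel_ids = list(trials[0].channel_ids)
    if source_offsets is None:
        source_offsets = [0] * len(trials)
    if len(source_offsets) != len(trials):
        raise ParameterError("source_offsets must match trials")
    n_trim = int(round(trim_s * sfreq))
    parts, trial_ids, src_idx = [], [], []
    for i, tr in enumerate(trials):
        if tr.sfreq != sfreq or list(tr.channel_ids) != channel_ids:
            raise ParameterError("all trials must share sfreq and channel order")
        kept = tr.n_samples - 2 * n_trim
        if kept <= 0:
            raise DegenerateDataError(
                f"trial {i} of {tr.duration_s:.3g} s leaves nothing after "
                f"trimming {trim_s:.3g} s from each end"
            )
        parts.append(tr.data[:, n_trim : n_trim + kept])
        trial_ids.append(np.full(kept, i, dtype=np.int64))
        src_idx.append(np.arange(n_trim, n_trim + kept, dtype=np.int64) + int(source_offsets[i]))
    return Segment(
        np.concatenate(parts, axis=1), sfreq, channel_ids,
        np.concatenate(trial_ids), np.concatenate(src_idx),
    )


def epoch(
    segment: Segment, epoch_length_s: float = 2.0, condition: Optional[ConditionKey] = None
) -> EpochSet:
    """Cut non-overlapping contiguous epochs, restarting at each trial seam.

    The trailing remainder of each trial (shorter than one epoch) is dropped.
    """
    n_ep_samp = int(round(epoch_length_s * segment.sfreq))
    if n_ep_samp <= 0 or segment.n_samples < n_ep_samp:
        raise DegenerateDataError(
            f"segment of {segment.n_samples} samples shorter than one "
            f"{epoch_length_s}-s epoch"
        )
    epochs, onsets, trials, src_onsets = [], [], [], []
    boundaries = np.flatnonzero(np.diff(segment.source_trial)) + 1
    starts = np.concatenate([[0], boundaries, [segment.n_samples]])
    for a, b in zip(starts[:-1], starts[1:]):
        for o in range(a, b - n_ep_samp + 1, n_ep_samp):
            epochs.append(segment.data[:, o : o + n_ep_samp])
            onsets.append(o)
            trials.append(segment.source_trial[o])
            src_onsets.append(segment.source_index[o])
    return EpochSet(
        np.stack(epochs), segment.sfreq, list(segment.channel_ids),
        np.asarray(onsets), np.asarray(trials), np.asarray(src_onsets),
        epoch_length_s, condition,
    )


# ---------------------------------------------------------------------------
# (3) artifact detection


def detect_artifacts(
    epochs: EpochSet,
    layout: ChannelLayout,
    thresholds: ArtifactThresholds = ArtifactThresholds(),
    mode: str = "absolute",
) -> EpochSet:
    """Mark epochs exceeding the ocular or amplitude thresholds.

    An epoch is rejected iff, within the epoch, the above-minus-below
    periocular difference of either eye exceeds ``veog_diff``, the
    left-minus-right canthus difference exceeds ``heog_diff``, or any single
    channel exceeds ``abs_amp``.  ``mode='absolute'`` compares instantaneous
    absolute values (default); ``mode='peak-to-peak'`` compares within-epoch
    peak-to-peak ranges against the same thresholds.
    """
    if mode not in ("absolute", "peak-to-peak"):
        raise ParameterError(f"unknown artifact mode {mode!r}")

    def extreme(x: np.ndarray) -> np.ndarray:
        # reduce over the sample axis
        if mode == "absolute":
            return np.abs(x).max(axis=-1)
        return x.max(axis=-1) - x.min(axis=-1)

    try:
        pairs = layout.veog_pairs
        canthi = layout.heog_pair
    except KeyError as exc:  # pragma: no cover - layout validates at build time
        raise LayoutError(f"layout missing periocular/canthus role: {exc}") from exc

    veog = np.zeros(epochs.n_epochs)
    for above, below in pairs:
        rows = epochs.channel_rows([above, below])
        diff = epochs.epochs[:, rows[0], :] - epochs.epochs[:, rows[1], :]
        veog = np.maximum(veog, extreme(diff))
    lrow, rrow = epochs.channel_rows(canthi)
    heog = extreme(epochs.epochs[:, lrow, :] - epochs.epochs[:, rrow, :])
    amp = extreme(epochs.epochs).max(axis=-1)

    reasons: List[Tuple[str, ...]] = []
    for i in range(epochs.n_epochs):
        r = []
        if veog[i] > thresholds.veog_diff:
            r.append(REASON_VEOG)
        if heog[i] > thresholds.heog_diff:
            r.append(REASON_HEOG)
        if amp[i] > thresholds.abs_amp:
            r.append(REASON_AMPLITUDE)
        reasons.append(tuple(r))
    return replace(epochs, reject_reasons=reasons)


# ---------------------------------------------------------------------------
# (4) average reference


def _scalp_rows(channel_ids: Sequence[int], layout: Optional[ChannelLayout]) -> np.ndarray:
    if layout is None:
        return np.arange(len(channel_ids))
    scalp = set(layout.scalp_channels)
    rows = np.array([i for i, c in enumerate(channel_ids) if int(c) in scalp])
    if rows.size < 2:
        raise LayoutError("average reference needs >= 2 scalp channels")
    return rows


def average_reference(epochs: EpochSet, layout: Optional[ChannelLayout] = None) -> EpochSet:
    """Subtract the instantaneous mean over scalp channels from every channel.

    Idempotent; after application the scalp-channel mean is ~0 at every
    sample.  With no layout, all channels count as scalp.
    """
    rows = _scalp_rows(epochs.channel_ids, layout)
    mean = epochs.epochs[:, rows, :].mean(axis=1, keepdims=True)
    return replace(epochs, epochs=epochs.epochs - mean)


def average_reference_recording(
    recording: Recording, layout: Optional[ChannelLayout] = None
) -> Recording:
    """Continuous-data counterpart of :func:`average_reference` (used so the
    baseline windows are referenced consistently with the epochs)."""
    rows = _scalp_rows(recording.channel_ids, layout)
    return recording.copy_with(recording.data - recording.data[rows, :].mean(axis=0))


# ---------------------------------------------------------------------------
# (5) baseline correction


def baseline_correct(
    epochs: EpochSet, source: Recording, baseline_ms: float = 200.0
) -> EpochSet:
    """Subtract the mean of the ``baseline_ms`` window immediately preceding
    each epoch's onset, looked up in the (untrimmed) source recording.

    The first epoch of a trial draws its baseline from the trimmed lead-in,
    which is the only reading under which a pre-epoch window exists for every
    epoch.
    """
    nb = int(round(baseline_ms / 1000.0 * epochs.sfreq))
    if nb <= 0:
        raise ParameterError("baseline_ms must cover at least one sample")
    rows = np.array([source.channel_index(c) for c in epochs.channel_ids])
    onsets = np.asarray(epochs.source_onsets)
    short = np.flatnonzero(onsets - nb < 0)
    if short.size:
        raise DegenerateDataError(
            f"epoch {short[0]} at source sample {onsets[short[0]]} has no "
            f"{baseline_ms:.0f}-ms baseline window before it"
        )
    windows = onsets[:, None] - nb + np.arange(nb)[None, :]  # (n_epochs, nb)
    base = source.data[rows][:, windows].mean(axis=-1)  # (n_ch, n_epochs)
    return replace(epochs, epochs=epochs.epochs - base.T[:, :, None])


# ---------------------------------------------------------------------------
# condition-level convenience


@dataclass(frozen=True)
class PreprocessParams:
    """Every tunable of the preprocessing stage, with study defaults."""

    filter_low_hz: float = 1.0
    filter_high_hz: float = 30.0
    filter_order: int = 4
    trim_s: float = 10.0
    epoch_s: float = 2.0
    thresholds: ArtifactThresholds = field(default_factory=ArtifactThresholds)
    artifact_mode: str = "absolute"
    baseline_ms: float = 200.0


def condition_trials(
    recording: Recording, key: ConditionKey
) -> Tuple[List[Recording], List[int]]:
    """Extract a condition's trials (sorted by trial index) and their onsets."""
    anns = sorted(
        (a for a in recording.annotations if a.key == key), key=lambda a: a.trial
    )
    if not anns:
        raise DegenerateDataError(f"no trials annotated for {key}")
    trials = [
        Recording(
            recording.data[:, a.onset : a.onset + a.duration],
            recording.sfreq, list(recording.channel_ids),
        )
        for a in anns
    ]
    return trials, [a.onset for a in anns]


def preprocess_condition(
    filtered: Recording,
    key: ConditionKey,
    layout: ChannelLayout,
    params: PreprocessParams = PreprocessParams(),
    baseline_source: Optional[Recording] = None,
) -> EpochSet:
    """Steps (2)-(5) for one condition of an already-filtered recording.

    ``baseline_source`` defaults to the average-referenced filtered
    recording, so baseline windows are referenced like the epochs they
    correct.
    """
    trials, offsets = condition_trials(filtered, key)
    seg = trim_and_concatenate(trials, params.trim_s, source_offsets=offsets)
    eps = epoch(seg, params.epoch_s, condition=key)
    eps = detect_artifacts(eps, layout, params.thresholds, params.artifact_mode)
    eps = average_reference(eps, layout)
    if baseline_source is None:
        baseline_source = average_reference_recording(filtered, layout)
    return baseline_correct(eps, baseline_source, params.baseline_ms)


def rejection_counts(epochs: EpochSet) -> Dict[str, int]:
    """Epoch bookkeeping for the rejection report."""
    out = {"total": epochs.n_epochs, "kept": int(epochs.retained.sum())}
    for reason in (REASON_VEOG, REASON_HEOG, REASON_AMPLITUDE):
        out[reason] = sum(
            1 for r in (epochs.reject_reasons or []) if reason in r
        )
    return out
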