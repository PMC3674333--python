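"""Synthetic multi-subject EEG experiments with known ERD/ERS ground truth.

Each generated session emulates one tDCS priming visit: per condition
(2 tasks x 3 movements) a configurable number of fixed-length trials, each
consisting of

* 1/f background noise on every channel,
* a Mu-band oscillator -- white noise band-passed to 8-11 Hz, i.e. a
  stationary narrowband process with realistic within-epoch power
  variability -- on every scalp channel, whose RMS amplitude equals
  ``base_mu_amplitude x (condition/cluster factor) x (subject factor)``, and
* injectable artifacts: blinks (400-ms raised-cosine deflections of opposite
  polarity above vs. below each eye) and high-amplitude transients (200-ms
  raised-cosine pulses on a random scalp channel).

Because band power scales with the square of amplitude, a condition whose
amplitude factor is ``g`` relative to its control has a true log power ratio
of ``2*ln(g)``; this is what :class:`GroundTruth` records, alongside the
realized placement of every injected artifact.

Randomness derives from a single master seed: per-subject and per-(subject,
session) substreams are spawned with fixed ``SeedSequence`` spawn keys, so a
subject's data are identical no matter which subset of the experiment is
generated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .conditions import ACTIVE_MOVEMENTS, MOVEMENTS, SESSIONS, TASKS, ConditionKey
from .errors import ParameterError, SpecificationError
from .io import Annotation, Recording
from .layout import UNITS, ChannelLayout, default_egi128_layout

#: cluster roles an erd_map entry may address
CLUSTER_ROLES = ("C3", "C4", "Cz", "surroundC3", "surroundC4", "other")

ErdMap = Mapping[Tuple[str, str, str], float]

_BLINK_DUR_S = 0.4
_TRANSIENT_DUR_S = 0.2
#: fraction of the blink deflection carried by the above-eye sensor
_BLINK_ABOVE_FRAC = 0.6


def full_erd_map(default: float = 1.0, overrides: Optional[ErdMap] = None) -> Dict[Tuple[str, str, str], float]:
    """A complete erd_map: every (task, movement, cluster-role) key filled."""
    out = {
        (t, m, r): float(default) for t in TASKS for m in MOVEMENTS for r in CLUSTER_ROLES
    }
    if overrides:
        for key, val in overrides.items():
            if key not in out:
                raise SpecificationError(f"erd_map override key {key} is not a valid (task, movement, role)")
            out[key] = float(val)
    return out


def sham_pattern_erd_map(
    bio_c3_log_ratio: float = -0.35, nonbio_c3_log_ratio: float = 0.15
) -> Dict[Tuple[str, str, str], float]:
    """Amplitude factors reproducing the sham-session sign pattern at C3.

    Biological movement desynchronizes Mu over the contralateral hand area
    (negative log power ratio at C3) while non-biological movement mildly
    synchronizes it; both tasks carry the effect.  Defaults give a
    biological-vs-nonbiological separation of 0.5 log units.
    """
    overrides = {}
    for task in TASKS:
        overrides[(task, "biological", "C3")] = float(np.exp(bio_c3_log_ratio / 2.0))
        overrides[(task, "nonbiological", "C3")] = float(np.exp(nonbio_c3_log_ratio / 2.0))
    return full_erd_map(overrides=overrides)


def illustrative_session_maps() -> Dict[str, Dict[Tuple[str, str, str], float]]:
    """Per-session amplitude-factor maps qualitatively matching the reported
    group pattern (contralateral ERD under sham; anodal priming flipping the
    C3 response to ERS with ipsilateral ERD; cathodal deepening C3 ERD).

    Magnitudes are illustrative -- the study reports no effect sizes in
    physical units -- and are intended for demonstrations, not calibration.
    """

    def m(entries: Dict[Tuple[str, str, str], float]):
        both = {}
        for (mov, role), lr in entries.items():
            for task in TASKS:
                both[(task, mov, role)] = float(np.exp(lr / 2.0))
        return full_erd_map(overrides=both)

    return {
        "sham": m({("biological", "C3"): -0.35, ("nonbiological", "C3"): 0.15}),
        "anodal": m({("biological", "C3"): 0.30, ("biological", "C4"): -0.30}),
        "cathodal": m({("biological", "C3"): -0.40, ("nonbiological", "C3"): -0.30}),
    }


@dataclass
class SynthSpec:
    """Study conditions for a synthetic experiment.

    Defaults mirror the study design: 21 subjects x 3 sessions, two 80-s
    trials per condition, Mu band 8-11 Hz.  Amplitudes are RMS microvolt;
    rates are events per minute; ``subject_sd`` is the between-subject SD of
    the log amplitude factor (log-normal, so ground-truth log ratios stay
    additive and subject scaling cancels from every ERD index).
    """

    n_subjects: int = 21
    sfreq: float = 250.0
    trial_duration_s: float = 80.0
    trials_per_condition: int = 2
    mu_band: Tuple[float, float] = (8.0, 11.0)
    base_mu_amplitude: float = 15.0
    erd_map: Optional[ErdMap] = None
    erd_map_by_session: Dict[str, ErdMap] = field(default_factory=dict)
    noise_exponent: float = 1.0
    noise_amplitude: float = 2.5
    blink_rate: float = 4.0
    blink_amplitude: float = 400.0
    transient_rate: float = 1.0
    transient_amplitude: float = 450.0
    subject_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise SpecificationError("n_subjects must be >= 1")
        if self.sfreq <= 0:
            raise SpecificationError("sfreq must be positive")
        lo, hi = self.mu_band
        if not (0 < lo < hi < self.sfreq / 2):
            raise SpecificationError(f"mu_band {self.mu_band} must lie in (0, Nyquist)")
        if self.trial_duration_s <= max(_BLINK_DUR_S, 1.0):
            raise SpecificationError("trial_duration_s too short")
        if self.trials_per_condition < 1:
            raise SpecificationError("trials_per_condition must be >= 1")
        for name in ("base_mu_amplitude", "noise_amplitude", "blink_amplitude", "transient_amplitude"):
            if getattr(self, name) < 0:
                raise SpecificationError(f"{name} must be >= 0")
        for name in ("blink_rate", "transient_rate"):
            if getattr(self, name) < 0:
                raise SpecificationError(f"{name} must be >= 0")
        if self.subject_sd < 0:
            raise SpecificationError("subject_sd must be >= 0")
        if self.erd_map is None:
            self.erd_map = full_erd_map()
        self._validate_map(self.erd_map, "erd_map")
        for sess, m in self.erd_map_by_session.items():
            if sess not in SESSIONS:
                raise SpecificationError(f"erd_map_by_session key {sess!r} is not a session")
            for key in m:
                if key not in full_erd_map():
                    raise SpecificationError(f"erd_map_by_session entry {key} invalid")
                if m[key] <= 0:
                    raise SpecificationError(f"amplitude factor for {key} must be > 0")

    @staticmethod
    def _validate_map(m: ErdMap, name: str) -> None:
        for t in TASKS:
            for mov in MOVEMENTS:
                for r in CLUSTER_ROLES:
                    key = (t, mov, r)
                    if key not in m:
                        raise SpecificationError(f"{name} missing required key {key}")
                    if m[key] <= 0:
                        raise SpecificationError(f"{name}[{key}] must be > 0, got {m[key]}")

    def session_factors(self, session: str) -> Dict[Tuple[str, str, str], float]:
        eff = dict(self.erd_map)
        eff.update(self.erd_map_by_session.get(session, {}))
        return eff


@dataclass(frozen=True)
class ArtifactEvent:
    """One injected artifact, in trial-relative sample coordinates."""

    kind: str  # "blink" or "transient"
    task: str
    movement: str
    trial: int
    onset: int
    duration: int
    amplitude: float  # blink: peak above-minus-below difference; transient: peak |value|
    channel: Optional[int] = None  # transient only
    sign: int = 1


@dataclass
class GroundTruth:
    """What was injected into one generated session."""

    subject: int
    session: str
    subject_factor: float
    factors: Dict[Tuple[str, str, str], float]
    log_ratio: Dict[Tuple[str, str, str], float]  # (task, movement, unit) -> 2*ln(g/g_control)
    artifacts: List[ArtifactEvent]


# ---------------------------------------------------------------------------
# signal components


def _normalized(x: np.ndarray, target_rms: float) -> np.ndarray:
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x * (target_rms / sd)

def one_over_f_noise(
    rng: np.random.Generator, n_channels: int, n_samples: int, sfreq: float,
    exponent: float, rms: float,
) -> np.ndarray:
    """1/f^exponent background noise, flat below 1 Hz, normalized to ``rms``."""
    if rms == 0:
        return np.zeros((n_channels, n_samples), dtype=np.float32)
    white = rng.standard_normal((n_channels, n_samples), dtype=np.float32)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples, 1.0 / sfreq)
    shape = (1.0 / np.maximum(freqs, 1.0) ** (exponent / 2.0)).astype(np.complex64)
    shape[0] = 0.0
    x = np.fft.irfft(spec * shape, n=n_samples, axis=-1).astype(np.float32)
    return _normalized(x, rms)


def narrowband_oscillation(
    rng: np.random.Generator, n_channels: int, n_samples: int, sfreq: float,
    band: Tuple[float, float], rms: float = 1.0, transition: float = 0.5,
) -> np.ndarray:
    """Gaussian noise band-passed to ``band`` with raised-cosine edges, unit RMS
    scaled to ``rms`` per channel."""
    if rms == 0:
        return np.zeros((n_channels, n_samples), dtype=np.float32)
    white = rng.standard_normal((n_channels, n_samples), dtype=np.float32)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples, 1.0 / sfreq)
    lo, hi = band
    gain = np.zeros_like(freqs)
    gain[(freqs >= lo) & (freqs <= hi)] = 1.0
    rise = (freqs > lo - transition) & (freqs < lo)
    gain[rise] = 0.5 * (1 + np.cos(np.pi * (lo - freqs[rise]) / transition))
    fall = (freqs > hi) & (freqs < hi + transition)
    gain[fall] = 0.5 * (1 + np.cos(np.pi * (freqs[fall] - hi) / transition))
    x = np.fft.irfft(spec * gain.astype(np.complex64), n=n_samples, axis=-1).astype(np.float32)
    return _normalized(x, rms)


def blink_waveform(sfreq: float) -> np.ndarray:
    """Unit-peak raised-cosine blink pulse (400 ms)."""
    n = max(int(round(_BLINK_DUR_S * sfreq)), 3)
    return np.hanning(n)


def transient_waveform(sfreq: float) -> np.ndarray:
    """Unit-peak raised-cosine transient pulse (200 ms)."""
    n = max(int(round(_TRANSIENT_DUR_S * sfreq)), 3)
    return np.hanning(n)


def _add_event_to_block(
    block: np.ndarray, event: ArtifactEvent, layout: ChannelLayout,
    ch_index: Dict[int, int], sfreq: float,
) -> None:
    if event.kind == "blink":
        w = blink_waveform(sfreq)[: block.shape[1] - event.onset]
        for above, below in layout.veog_pairs:
            block[ch_index[above], event.onset : event.onset + len(w)] += (
                _BLINK_ABOVE_FRAC * event.amplitude * w
            )
            block[ch_index[below], event.onset : event.onset + len(w)] -= (
                (1 - _BLINK_ABOVE_FRAC) * event.amplitude * w
            )
    elif event.kind == "transient":
        w = transient_waveform(sfreq)[: block.shape[1] - event.onset]
        block[ch_index[event.channel], event.onset : event.onset + len(w)] += (
            event.sign * event.amplitude * w
        )
    else:  # pragma: no cover
        raise SpecificationError(f"unknown artifact kind {event.kind!r}")


# ---------------------------------------------------------------------------
# session / experiment generation


def _subject_factor(spec: SynthSpec, subject: int) -> float:
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(0, subject)))
    return float(np.exp(spec.subject_sd * rng.standard_normal()))


def generate_session(
    spec: SynthSpec, subject: int, session: str, layout: Optional[ChannelLayout] = None
) -> Tuple[Recording, GroundTruth]:
    """Generate one subject x session recording and its ground truth.

    The recording contains ``trials_per_condition`` annotated trials for each
    of the six conditions, concatenated in a (seeded) shuffled block order.
    Identical (spec, subject, session) always produce identical output.
    """
    if session not in SESSIONS:
        raise ParameterError(f"unknown session {session!r}")
    if not (0 <= subject < spec.n_subjects):
        raise ParameterError(f"subject {subject} outside 0..{spec.n_subjects - 1}")
    layout = layout or default_egi128_layout()
    factors = spec.session_factors(session)
    sub_factor = _subject_factor(spec, subject)
    rng = np.random.default_rng(
        np.random.SeedSequence(spec.seed, spawn_key=(1, subject, SESSIONS.index(session)))
    )

    n_ch = layout.n_channels
    channel_ids = list(range(1, n_ch + 1))
    ch_index = {c: i for i, c in enumerate(channel_ids)}
    n_per = int(round(spec.trial_duration_s * spec.sfreq))

    blocks = [(t, m) for t in TASKS for m in MOVEMENTS for _ in range(spec.trials_per_condition)]
    order = rng.permutation(len(blocks))
    blocks = [blocks[i] for i in order]

    cluster = {c: layout.cluster_role(c) for c in channel_ids}
    scalp_rows = [ch_index[c] for c in channel_ids if cluster[c] != "eog"]

    data = np.empty((n_ch, n_per * len(blocks)), dtype=np.float32)
    annotations: List[Annotation] = []
    events: List[ArtifactEvent] = []
    trial_counter: Dict[Tuple[str, str], int] = {}

    # one batched draw for all blocks (channel x block streams independent)
    n_blocks = len(blocks)
    noise_all = one_over_f_noise(
        rng, n_ch * n_blocks, n_per, spec.sfreq, spec.noise_exponent, spec.noise_amplitude
    ).reshape(n_blocks, n_ch, n_per)
    if spec.base_mu_amplitude > 0:
        mu_all = narrowband_oscillation(
            rng, len(scalp_rows) * n_blocks, n_per, spec.sfreq, spec.mu_band
        ).reshape(n_blocks, len(scalp_rows), n_per)

    for b, (task, movement) in enumerate(blocks):
        trial = trial_counter.get((task, movement), 0)
        trial_counter[(task, movement)] = trial + 1
        block = noise_all[b]
        if spec.base_mu_amplitude > 0:
            amps = np.array(
                [
                    spec.base_mu_amplitude * sub_factor * factors[(task, movement, cluster[c])]
                    for c in channel_ids
                    if cluster[c] != "eog"
                ]
            )
            block[scalp_rows, :] += amps[:, None] * mu_all[b]

        n_blink = rng.poisson(spec.blink_rate * spec.trial_duration_s / 60.0)
        blink_len = len(blink_waveform(spec.sfreq))
        for _ in range(n_blink):
            onset = int(rng.integers(0, max(n_per - blink_len, 1)))
            ev = ArtifactEvent(
                "blink", task, movement, trial, onset, blink_len, spec.blink_amplitude
            )
            _add_event_to_block(block, ev, layout, ch_index, spec.sfreq)
            events.append(ev)

        n_tr = rng.poisson(spec.transient_rate * spec.trial_duration_s / 60.0)
        tr_len = len(transient_waveform(spec.sfreq))
        for _ in range(n_tr):
            onset = int(rng.integers(0, max(n_per - tr_len, 1)))
            ch = int(rng.choice(layout.scalp_channels))
            sign = 1 if rng.random() < 0.5 else -1
            ev = ArtifactEvent(
                "transient", task, movement, trial, onset, tr_len,
                spec.transient_amplitude, channel=ch, sign=sign,
            )
            _add_event_to_block(block, ev, layout, ch_index, spec.sfreq)
            events.append(ev)

        data[:, b * n_per : (b + 1) * n_per] = block
        annotations.append(
            Annotation(b * n_per, n_per, ConditionKey(session, task, movement), trial)
        )

    log_ratio = {}
    for task in TASKS:
        for movement in ACTIVE_MOVEMENTS:
            for unit in UNITS:
                g = factors[(task, movement, unit)]
                g0 = factors[(task, "control", unit)]
                log_ratio[(task, movement, unit)] = 2.0 * float(np.log(g / g0))

    rec = Recording(data, spec.sfreq, channel_ids, annotations)
    gt = GroundTruth(subject, session, sub_factor, dict(factors), log_ratio, events)
    return rec, gt


def generate_experiment(
    spec: SynthSpec, layout: Optional[ChannelLayout] = None, sessions: Sequence[str] = SESSIONS
) -> Iterator[Tuple[int, str, Recording, GroundTruth]]:
    """Yield (subject, session, Recording, GroundTruth) for the full design.

    Lazily generated (a full default experiment is 63 sessions); wrap in
    ``list`` to materialize.
    """
    for subject in range(spec.n_subjects):
        for session in sessions:
            rec, gt = generate_session(spec, subject, session, layout=layout)
            yield subject, session, rec, gt


def render_artifacts(
    recording: Recording, ground_truth: GroundTruth, layout: ChannelLayout
) -> Recording:
    """Artifact-only version of a generated session (no noise, no Mu).

    Used to reason about which epochs an injected artifact can trip: the
    returned recording has the same shape and annotations, containing only
    the ideal artifact waveforms at their recorded placements.
    """
    data = np.zeros_like(recording.data)
    ch_index = {c: i for i, c in enumerate(recording.channel_ids)}
    by_block = {(a.key.task, a.key.movement, a.trial): a for a in recording.annotations}
    for ev in ground_truth.artifacts:
        ann = by_block[(ev.task, ev.movement, ev.trial)]
        block = data[:, ann.onset : ann.onset + ann.duration]
        _add_event_to_block(block, ev, layout, ch_index, recording.sfreq)
    return Recording(data, recording.sfreq, list(recording.channel_ids), list(recording.annotations))
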