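"""Recording container and file I/O.

Two on-disk formats are supported for continuous recordings:

* ``delimited`` -- UTF-8, tab-separated; an optional ``# sfreq_hz: <value>``
  comment line, then a header row of channel ids, then one row per sample
  (values in microvolt).  Lossless.
* ``edf`` -- plain European Data Format, 16-bit.  Written by a minimal
  in-package writer (one-second data records, zero-padded tail recorded in the
  reserved header field so the true length round-trips); readable by any EDF
  reader.  Quantized to the 16-bit physical range.

Condition annotations travel in a sidecar table ``<stem>.annotations.tsv``
with columns onset_s, duration_s, session, task, movement, trial.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .conditions import ConditionKey
from .errors import DegenerateDataError, FormatError, IOFailure, ParameterError

_EDF_DIG_MIN = -32768
_EDF_DIG_MAX = 32767


@dataclass(frozen=True)
class Annotation:
    """A condition trial span, half-open in samples: [onset, onset+duration)."""

    onset: int
    duration: int
    key: ConditionKey
    trial: int


@dataclass
class Recording:
    """Continuous multichannel EEG in microvolt.

    ``data`` has shape (n_channels, n_samples); ``channel_ids`` gives the
    sensor number of each row.  Sample indexing is 0-based.
    """

    data: np.ndarray
    sfreq: float
    channel_ids: Sequence[int]
    annotations: List[Annotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.dtype not in (np.float32, np.float64):
            self.data = self.data.astype(np.float64)
        if self.data.ndim != 2:
            raise ParameterError("recording data must be 2-D (channels x samples)")
        if self.sfreq <= 0:
            raise ParameterError(f"sfreq must be positive, got {self.sfreq}")
        self.channel_ids = [int(c) for c in self.channel_ids]
        if len(self.channel_ids) != self.data.shape[0]:
            raise ParameterError(
                f"{len(self.channel_ids)} channel ids for {self.data.shape[0]} data rows"
            )
        if len(set(self.channel_ids)) != len(self.channel_ids):
            raise ParameterError("channel ids must be unique")
        n = self.data.shape[1]
        for ann in self.annotations:
            if ann.onset < 0 or ann.duration <= 0 or ann.onset + ann.duration > n:
                raise ParameterError(
                    f"annotation span [{ann.onset}, {ann.onset + ann.duration}) "
                    f"outside recording of {n} samples"
                )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sfreq

    def channel_index(self, channel_id: int) -> int:
        try:
            return self.channel_ids.index(int(channel_id))
        except ValueError as exc:
            raise ParameterError(f"channel {channel_id} not in recording") from exc

    def copy_with(self, data: np.ndarray) -> "Recording":
        return replace(self, data=data, annotations=list(self.annotations))


# ---------------------------------------------------------------------------
# annotations sidecar


def _annotations_path(path: Path) -> Path:
    return path.with_name(path.stem + ".annotations.tsv")


def write_annotations(annotations: Sequence[Annotation], sfreq: float, path: Path) -> None:
    rows = [
        {
            "onset_s": a.onset / sfreq,
            "duration_s": a.duration / sfreq,
            "session": a.key.session,
            "task": a.key.task,
            "movement": a.key.movement,
            "trial": a.trial,
        }
        for a in annotations
    ]
    pd.DataFrame(rows, columns=["onset_s", "duration_s", "session", "task", "movement", "trial"]).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_annotations(path: Path, sfreq: float) -> List[Annotation]:
    df = pd.read_csv(path, sep="\t")
    required = {"onset_s", "duration_s", "session", "task", "movement", "trial"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"annotation file {path} missing columns {sorted(missing)}")
    out = []
    for _, r in df.iterrows():
        out.append(
            Annotation(
                onset=int(round(r["onset_s"] * sfreq)),
                duration=int(round(r["duration_s"] * sfreq)),
                key=ConditionKey(str(r["session"]), str(r["task"]), str(r["movement"])),
                trial=int(r["trial"]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# delimited matrix


def _write_delimited(rec: Recording, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# sfreq_hz: {rec.sfreq:.17g}\n")
        fh.write("\t".join(str(c) for c in rec.channel_ids) + "\n")
        np.savetxt(fh, rec.data.T, fmt="%.17g", delimiter="\t")


def _read_delimited(path: Path, sfreq: Optional[float]) -> Tuple[np.ndarray, float, List[int]]:
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        lineno = 1
        if first.startswith("#"):
            m = re.search(r"sfreq_hz:\s*([0-9.eE+-]+)", first)
            if m:
                sfreq = float(m.group(1))
            header = fh.readline()
            lineno += 1
        else:
            header = first
        if not header.strip():
            raise FormatError(f"{path}: line {lineno}: missing channel-id header")
        try:
            channel_ids = [int(tok) for tok in header.strip().split("\t")]
        except ValueError as exc:
            raise FormatError(f"{path}: line {lineno}: non-numeric channel id ({exc})") from exc
        rows = []
        for line in fh:
            lineno += 1
            if not line.strip():
                continue
            toks = line.rstrip("\n").split("\t")
            if len(toks) != len(channel_ids):
                raise FormatError(
                    f"{path}: line {lineno}: expected {len(channel_ids)} values, got {len(toks)}"
                )
            try:
                rows.append([float(t) for t in toks])
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: non-numeric value ({exc})") from exc
    if sfreq is None:
        raise FormatError(f"{path}: sampling rate not declared (no '# sfreq_hz:' line)")
    if not rows:
        raise FormatError(f"{path}: no data rows")
    return np.asarray(rows, dtype=np.float64).T, float(sfreq), channel_ids


# ---------------------------------------------------------------------------
# EDF


def _edf_field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise FormatError(f"EDF header field {s!r} exceeds {width} ascii chars")
    return s.ljust(width).encode("ascii")


def _write_edf(rec: Recording, path: Path) -> None:
    sfreq_i = int(round(rec.sfreq))
    if abs(rec.sfreq - sfreq_i) > 1e-9 or sfreq_i <= 0:
        raise ParameterError("EDF writer requires an integer sampling rate")
    n_ch = rec.n_channels
    n = rec.n_samples
    n_records = int(np.ceil(n / sfreq_i))
    padded = np.zeros((n_ch, n_records * sfreq_i))
    padded[:, :n] = rec.data

    phys_min = np.floor(np.min(padded, axis=1)).astype(int)
    phys_max = np.ceil(np.max(padded, axis=1)).astype(int)
    flat = phys_max <= phys_min
    phys_min[flat] -= 1
    phys_max[flat] += 1

    header = b"".join(
        [
            _edf_field(0, 8),
            _edf_field("X X X X", 80),
            _edf_field("Startdate X X X X", 80),
            _edf_field("01.01.01", 8),
            _edf_field("00.00.00", 8),
            _edf_field(256 * (1 + n_ch), 8),
            _edf_field(f"MUERD_NS={n}", 44),  # true sample count (tail is zero-padded)
            _edf_field(n_records, 8),
            _edf_field(1, 8),
            _edf_field(n_ch, 4),
        ]
    )
    for fmt, width in [
        (lambda i: f"E{rec.channel_ids[i]}", 16),
        (lambda i: "", 80),
        (lambda i: "uV", 8),
        (lambda i: phys_min[i], 8),
        (lambda i: phys_max[i], 8),
        (lambda i: _EDF_DIG_MIN, 8),
        (lambda i: _EDF_DIG_MAX, 8),
        (lambda i: "", 80),
        (lambda i: sfreq_i, 8),
        (lambda i: "", 32),
    ]:
        header += b"".join(_edf_field(fmt(i), width) for i in range(n_ch))

    scale = (phys_max - phys_min) / (_EDF_DIG_MAX - _EDF_DIG_MIN)
    digital = np.round((padded - phys_min[:, None]) / scale[:, None] + _EDF_DIG_MIN)
    digital = np.clip(digital, _EDF_DIG_MIN, _EDF_DIG_MAX).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            fh.write(digital[:, r * sfreq_i : (r + 1) * sfreq_i].tobytes())


def _read_edf(path: Path) -> Tuple[np.ndarray, float, List[int]]:
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise FormatError(f"{path}: truncated EDF header")
        try:
            reserved = head[192:236].decode("ascii")
            n_records = int(head[236:244])
            record_dur = float(head[244:252])
            n_ch = int(head[252:256])
        except ValueError as exc:
            raise FormatError(f"{path}: malformed EDF header ({exc})") from exc
        sig = fh.read(256 * n_ch)
        if len(sig) < 256 * n_ch:
            raise FormatError(f"{path}: truncated EDF signal headers")

        def fields(offset: int, width: int) -> List[str]:
            base = offset * n_ch
            return [
                sig[base + i * width : base + (i + 1) * width].decode("ascii").strip()
                for i in range(n_ch)
            ]

        labels = fields(0, 16)
        dims = fields(16 + 80, 8)
        phys_min = np.array([float(v) for v in fields(16 + 80 + 8, 8)])
        phys_max = np.array([float(v) for v in fields(16 + 80 + 16, 8)])
        dig_min = np.array([float(v) for v in fields(16 + 80 + 24, 8)])
        dig_max = np.array([float(v) for v in fields(16 + 80 + 32, 8)])
        spr = [int(v) for v in fields(16 + 80 + 40 + 80, 8)]
        if len(set(spr)) != 1:
            raise FormatError(f"{path}: heterogeneous samples-per-record not supported")
        if any(d.lower() not in ("uv", "") for d in dims):
            raise FormatError(f"{path}: physical dimension must be uV, got {sorted(set(dims))}")
        raw = np.frombuffer(fh.read(), dtype="<i2")
    expected = n_records * n_ch * spr[0]
    if raw.size != expected:
        raise FormatError(f"{path}: expected {expected} samples, found {raw.size}")
    data = (
        raw.reshape(n_records, n_ch, spr[0]).transpose(1, 0, 2).reshape(n_ch, -1).astype(np.float64)
    )
    scale = (phys_max - phys_min) / (dig_max - dig_min)
    data = (data - dig_min[:, None]) * scale[:, None] + phys_min[:, None]
    m = re.search(r"MUERD_NS=(\d+)", reserved)
    if m:
        data = data[:, : int(m.group(1))]
    sfreq = spr[0] / record_dur
    channel_ids = []
    for i, lab in enumerate(labels):
        m2 = re.fullmatch(r"E?(\d+)", lab)
        channel_ids.append(int(m2.group(1)) if m2 else i + 1)
    return data, sfreq, channel_ids


# ---------------------------------------------------------------------------
# public API


def _infer_format(path: Path, fmt: Optional[str]) -> str:
    if fmt is not None:
        if fmt not in ("edf", "delimited"):
            raise ParameterError(f"unknown format {fmt!r}")
        return fmt
    return "edf" if path.suffix.lower() == ".edf" else "delimited"


def read_recording(
    path, format: Optional[str] = None, sfreq: Optional[float] = None
) -> Recording:
    """Read a continuous recording (and its annotation sidecar, if present)."""
    path = Path(path)
    if not path.exists():
        raise IOFailure(f"no such file: {path}")
    fmt = _infer_format(path, format)
    if fmt == "edf":
        data, sf, channel_ids = _read_edf(path)
    else:
        data, sf, channel_ids = _read_delimited(path, sfreq)
    annotations: List[Annotation] = []
    ann_path = _annotations_path(path)
    if ann_path.exists():
        annotations = read_annotations(ann_path, sf)
    return Recording(data, sf, channel_ids, annotations)


def write_recording(recording: Recording, path, format: Optional[str] = None) -> Path:
    """Write a recording plus its annotation sidecar; returns the data path."""
    path = Path(path)
    if recording.n_samples == 0:
        raise DegenerateDataError("refusing to write a recording with 0 samples")
    fmt = _infer_format(path, format)
    try:
        if fmt == "edf":
            _write_edf(recording, path)
        else:
            _write_delimited(recording, path)
        if recording.annotations:
            write_annotations(recording.annotations, recording.sfreq, _annotations_path(path))
    except OSError as exc:
        raise IOFailure(f"cannot write {path}: {exc}") from exc
    return path
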