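"""Recording and annotation I/O.

Recordings are plain multichannel time series at a fixed sampling rate
(200 Hz for the simulated rodent epidural EEG).  Two on-disk dialects are
supported:

* **EDF** — standard 16-bit European Data Format, one data record per
  second.  The codec here covers plain continuous EDF only (no EDF+
  annotations).
* **CSV** — one header row; column 0 is time (seconds) or a bare sample
  index, remaining columns are channels in microvolts.

Seizure annotations travel in a CSV sidecar with columns
``onset_s,offset_s,label``.
"""

from __future__ import annotations

import math
import struct
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Recording",
    "SeizureAnnotation",
    "AnnotatedRecord",
    "AnnotatedDataset",
    "read_recording",
    "write_recording",
    "read_annotations",
    "write_annotations",
    "clip_peri_ictal",
    "EDF_PHYSICAL_RANGE_UV",
]

#: Default EDF physical range (µV).  Typical rodent epidural EEG stays well
#: inside ±1000 µV, leaving headroom for movement artifacts.
EDF_PHYSICAL_RANGE_UV = 1000.0


@dataclass
class Recording:
    """A sampled EEG signal.

    Parameters
    ----------
    data
        Array of shape ``(n_channels, n_samples)`` in microvolts.
    fs
        Sampling rate in Hz (> 0).
    channel_labels
        One label per channel.
    start_time_s
        Seconds offset of the first sample relative to the parent
        recording (0 for freshly simulated or loaded data).
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str] = field(default_factory=list)
    start_time_s: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i}" for i in range(self.data.shape[0])]
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} channels"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def end_time_s(self) -> float:
        return self.start_time_s + self.duration_s

    def channel(self, which: int | str = 0) -> np.ndarray:
        """Return one channel as a 1-D array (by index or label)."""
        if isinstance(which, str):
            try:
                which = self.channel_labels.index(which)
            except ValueError:
                raise KeyError(
                    f"channel {which!r} not in {self.channel_labels}"
                ) from None
        return self.data[which]


@dataclass
class SeizureAnnotation:
    """Onset/offset of one seizure, in seconds on the recording's clock."""

    onset_s: float
    offset_s: float
    label: str = "seizure"

    def __post_init__(self) -> None:
        if not self.offset_s > self.onset_s:
            raise ValueError(
                f"offset ({self.offset_s}) must exceed onset ({self.onset_s})"
            )

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclass
class AnnotatedRecord:
    """One recording plus its seizure annotations and train/test tags."""

    recording: Recording
    annotations: list[SeizureAnnotation] = field(default_factory=list)
    tags: list[str] = field(default_factory=list)  # per annotation: train|test|none

    def __post_init__(self) -> None:
        if not self.tags:
            self.tags = ["none"] * len(self.annotations)
        if len(self.tags) != len(self.annotations):
            raise ValueError("one tag per annotation required")
        for ann in self.annotations:
            if ann.onset_s < self.recording.start_time_s - 1e-9 or (
                ann.offset_s > self.recording.end_time_s + 1e-9
            ):
                raise ValueError(
                    f"annotation [{ann.onset_s}, {ann.offset_s}] s outside recording "
                    f"span [{self.recording.start_time_s}, {self.recording.end_time_s}] s"
                )


@dataclass
class AnnotatedDataset:
    """A set of annotated recordings (peri-ictal clips and/or long records)."""

    records: list[AnnotatedRecord] = field(default_factory=list)

    def seizures(self, tag: str | None = None):
        """Yield ``(record, annotation)`` pairs, optionally filtered by tag."""
        for rec in self.records:
            for ann, t in zip(rec.annotations, rec.tags):
                if tag is None or t == tag:
                    yield rec, ann

    @property
    def n_seizures(self) -> int:
        return sum(len(r.annotations) for r in self.records)


# ---------------------------------------------------------------------------
# CSV recording dialect
# ---------------------------------------------------------------------------

def _read_csv_recording(path: Path, fs: float | None) -> Recording:
    try:
        # round_trip parsing keeps read∘write an exact identity
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"malformed CSV {path}: {exc}") from exc
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need a time/index column plus ≥1 channel column")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    first = str(df.columns[0]).lower()
    if fs is None:
        if first.startswith("time") and len(t) >= 2:
            dt = np.diff(t)
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9) or dt[0] <= 0:
                raise ValueError(f"{path}: time column is not uniformly sampled")
            fs = 1.0 / dt[0]
        else:
            raise ValueError(
                f"{path}: sampling rate not derivable from column {df.columns[0]!r}; "
                "pass fs explicitly (CLI: --fs)"
            )
    data = df.iloc[:, 1:].to_numpy(dtype=float).T
    start = float(t[0]) if first.startswith("time") else 0.0
    return Recording(data, float(fs), [str(c) for c in df.columns[1:]], start)


def _write_csv_recording(rec: Recording, path: Path) -> None:
    t = rec.start_time_s + np.arange(rec.n_samples) / rec.fs
    df = pd.DataFrame({"time_s": t})
    for lab, ch in zip(rec.channel_labels, rec.data):
        df[lab] = ch
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Minimal plain-EDF codec (16-bit, 1 s data records)
# ---------------------------------------------------------------------------

def _edf_field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def _write_edf(rec: Recording, path: Path,
               physical_range: float = EDF_PHYSICAL_RANGE_UV) -> None:
    fs = rec.fs
    spr = fs  # samples per 1 s data record
    if abs(spr - round(spr)) > 1e-9:
        raise ValueError(f"EDF writer requires an integer sampling rate, got {fs}")
    spr = int(round(spr))
    ns = rec.n_channels
    n_rec = math.ceil(rec.n_samples / spr)
    if n_rec * spr != rec.n_samples:
        warnings.warn(
            f"recording length {rec.n_samples} is not a whole number of 1 s EDF "
            "records; zero-padding the final record", stacklevel=2)
    pmin, pmax = -physical_range, physical_range
    dmin, dmax = -32768, 32767

    header = b"".join([
        _edf_field("0", 8),                       # version
        _edf_field("X X X X", 80),                # patient id (anonymous)
        _edf_field("Startdate X X X X", 80),      # recording id
        _edf_field("01.01.00", 8),                # start date (placeholder)
        _edf_field("00.00.00", 8),                # start time
        _edf_field(256 + 256 * ns, 8),            # header bytes
        _edf_field("", 44),                       # reserved
        _edf_field(n_rec, 8),
        _edf_field("1", 8),                       # record duration (s)
        _edf_field(ns, 4),
        b"".join(_edf_field(lab, 16) for lab in rec.channel_labels),
        b"".join(_edf_field("AgAgCl epidural", 80) for _ in range(ns)),
        b"".join(_edf_field("uV", 8) for _ in range(ns)),
        b"".join(_edf_field(f"{pmin:g}", 8) for _ in range(ns)),
        b"".join(_edf_field(f"{pmax:g}", 8) for _ in range(ns)),
        b"".join(_edf_field(dmin, 8) for _ in range(ns)),
        b"".join(_edf_field(dmax, 8) for _ in range(ns)),
        b"".join(_edf_field("", 80) for _ in range(ns)),  # prefiltering
        b"".join(_edf_field(spr, 8) for _ in range(ns)),
        b"".join(_edf_field("", 32) for _ in range(ns)),  # reserved
    ])

    gain = (dmax - dmin) / (pmax - pmin)
    padded = np.zeros((ns, n_rec * spr))
    padded[:, : rec.n_samples] = rec.data
    if padded.max() > pmax or padded.min() < pmin:
        warnings.warn(
            f"samples exceed the EDF physical range ±{physical_range} µV and "
            "will saturate (as a real amplifier would)", stacklevel=2)
        padded = np.clip(padded, pmin, pmax)
    digital = np.rint((padded - pmin) * gain + dmin).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            for c in range(ns):
                fh.write(digital[c, r * spr:(r + 1) * spr].tobytes())


def _read_edf(path: Path) -> Recording:
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise ValueError(f"{path}: truncated EDF header ({len(head)} bytes)")

        def f(off, width):
            return head[off:off + width].decode("ascii", "replace").strip()

        try:
            n_rec = int(f(236, 8))
            rec_dur = float(f(244, 8))
            ns = int(f(252, 4))
        except ValueError as exc:
            raise ValueError(f"{path}: malformed EDF header near byte 236: {exc}")
        sig = fh.read(256 * ns)
        if len(sig) < 256 * ns:
            raise ValueError(f"{path}: truncated EDF signal headers")

        def sfield(off, width):
            out = []
            for c in range(ns):
                raw = sig[off * ns + c * width: off * ns + (c + 1) * width]
                out.append(raw.decode("ascii", "replace").strip())
            return out

        labels = sfield(0, 16)
        pmin = np.array([float(v) for v in sfield(16 + 80 + 8, 8)])
        pmax = np.array([float(v) for v in sfield(16 + 80 + 8 + 8, 8)])
        dmin = np.array([float(v) for v in sfield(16 + 80 + 8 + 16, 8)])
        dmax = np.array([float(v) for v in sfield(16 + 80 + 8 + 24, 8)])
        spr = np.array([int(v) for v in sfield(16 + 80 + 8 + 32 + 80, 8)])

        payload = fh.read()

    total = int(n_rec * spr.sum() * 2)
    if len(payload) < total:
        raise ValueError(
            f"{path}: EDF payload truncated at byte {256 + 256 * ns + len(payload)}")
    raw = np.frombuffer(payload[:total], dtype="<i2")
    data = np.empty((ns, int(n_rec * spr[0])))
    if not np.all(spr == spr[0]):
        raise ValueError(f"{path}: per-channel sampling rates differ; unsupported")
    k = 0
    for r in range(n_rec):
        for c in range(ns):
            data[c, r * spr[c]:(r + 1) * spr[c]] = raw[k:k + spr[c]]
            k += spr[c]
    gain = (pmax - pmin) / (dmax - dmin)
    data = (data - dmin[:, None]) * gain[:, None] + pmin[:, None]
    fs = spr[0] / rec_dur
    return Recording(data, fs, labels)


# ---------------------------------------------------------------------------
# Public I/O surface
# ---------------------------------------------------------------------------

_FORMATS = ("edf", "csv")


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    fmt = fmt.lower()
    if fmt not in _FORMATS:
        raise ValueError(f"unsupported recording format {fmt!r}; use one of {_FORMATS}")
    return fmt


def read_recording(path, fmt: str | None = None, fs: float | None = None) -> Recording:
    """Read a recording from EDF or CSV.

    ``fs`` is only consulted for CSV files whose first column is a bare
    index rather than a time axis.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, fmt)
    if fmt == "edf":
        return _read_edf(path)
    return _read_csv_recording(path, fs)


def write_recording(rec: Recording, path, fmt: str | None = None,
                    physical_range: float = EDF_PHYSICAL_RANGE_UV) -> None:
    """Write a recording to EDF (16-bit) or CSV."""
    if not np.all(np.isfinite(rec.data)):
        raise ValueError("recording contains non-finite samples")
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "edf":
        _write_edf(rec, path, physical_range)
    else:
        _write_csv_recording(rec, path)


def read_annotations(path) -> list[SeizureAnnotation]:
    """Read a seizure annotation sidecar (CSV: onset_s, offset_s, label).

    Returns annotations sorted by onset; overlapping consecutive seizures
    are an error.
    """
    df = pd.read_csv(path)
    for col in ("onset_s", "offset_s"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    anns = []
    for i, row in df.iterrows():
        if not row["offset_s"] > row["onset_s"]:
            raise ValueError(
                f"{path} row {i}: offset_s ({row['offset_s']}) ≤ onset_s "
                f"({row['onset_s']})")
        anns.append(SeizureAnnotation(float(row["onset_s"]), float(row["offset_s"]),
                                      str(row.get("label", "seizure"))))
    anns.sort(key=lambda a: a.onset_s)
    for a, b in zip(anns, anns[1:]):
        if b.onset_s < a.offset_s:
            raise ValueError(
                f"{path}: seizures [{a.onset_s}, {a.offset_s}] and "
                f"[{b.onset_s}, {b.offset_s}] overlap")
    return anns


def write_annotations(anns: list[SeizureAnnotation], path) -> None:
    pd.DataFrame(
        {"onset_s": [a.onset_s for a in anns],
         "offset_s": [a.offset_s for a in anns],
         "label": [a.label for a in anns]}
    ).to_csv(path, index=False)


def clip_peri_ictal(rec: Recording, ann: SeizureAnnotation,
                    pre_s: float = 60.0, post_s: float = 60.0
                    ) -> tuple[Recording, SeizureAnnotation]:
    """Clip ``[onset - pre_s, offset + post_s]``, clamped to the recording.

    Returns the clip and the annotation re-expressed in clip-local time.
    Annotation seconds map to sample indices by rounding down (onset
    precision is visual; sub-sample precision is meaningless).
    """
    t0 = max(ann.onset_s - pre_s, rec.start_time_s)
    t1 = min(ann.offset_s + post_s, rec.end_time_s)
    i0 = int(math.floor((t0 - rec.start_time_s) * rec.fs))
    i1 = int(math.floor((t1 - rec.start_time_s) * rec.fs))
    i1 = min(i1, rec.n_samples)
    clip = Recording(rec.data[:, i0:i1].copy(), rec.fs,
                     list(rec.channel_labels), start_time_s=0.0)
    clock0 = rec.start_time_s + i0 / rec.fs
    local = SeizureAnnotation(ann.onset_s - clock0, ann.offset_s - clock0, ann.label)
    return clip, local
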