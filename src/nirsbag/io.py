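"""Reading and writing continuous fNIRS recordings and event lists.

On-disk dialect
---------------
A recording ``<name>`` is stored as two files:

``<name>.nirs.tsv``
    One row per sample, one column per channel, tab-separated, header row
    of channel ids, values with 17 significant digits.  An optional first
    column named ``time_s`` is accepted on read and checked against the
    sidecar's uniform sampling grid (jitter tolerance 1e-6 s); it is never
    written, because time is implicit: sample ``i`` lies at
    ``start_time + i / sampling_rate``.

``<name>.nirs.json``
    Sidecar with ``sampling_rate``, ``start_time``, ``sample_count`` and
    the ordered channel list.

Events are a two-column TSV ``<name>.events.tsv`` with header
``onset_s<TAB>label``.  All times are seconds, all concentrations µmol/L.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    DataError,
    FormatError,
    OrderingError,
    ParameterError,
    SamplingError,
)

SIGNAL_KINDS = ("od_wavelength_1", "od_wavelength_2", "hbo", "hbr")

#: minimal sampling rate: the analysis band extends to 0.09 Hz, so the
#: grid must at least satisfy Nyquist for that edge with headroom
MIN_SAMPLING_RATE = 0.2

_TIME_JITTER = 1e-6  # seconds


@dataclass(frozen=True)
class ChannelInfo:
    """Metadata for one measurement channel.

    Parameters
    ----------
    channel_id
        Unique name within a recording.
    signal_kind
        One of ``od_wavelength_1``, ``od_wavelength_2`` (dimensionless
        optical-density changes) or ``hbo``, ``hbr`` (chromophore
        concentration changes, µmol/L).
    source_id, detector_id
        Optode labels, optional.
    source_detector_distance_mm
        Geometric optode separation; 30 mm is the conventional default
        for adult prefrontal montages.
    """

    channel_id: str
    signal_kind: str
    source_id: str | None = None
    detector_id: str | None = None
    source_detector_distance_mm: float | None = 30.0

    def __post_init__(self) -> None:
        if self.signal_kind not in SIGNAL_KINDS:
            raise ParameterError(
                f"unknown signal_kind {self.signal_kind!r}; "
                f"expected one of {SIGNAL_KINDS}"
            )
        d = self.source_detector_distance_mm
        if d is not None and not d > 0:
            raise ParameterError(
                f"source_detector_distance_mm must be > 0, got {d}"
            )


@dataclass
class ContinuousRecording:
    """A uniformly sampled multichannel time series.

    ``data`` has shape ``(n_samples, n_channels)``; column order follows
    ``channels``.  Time is implicit on the grid
    ``start_time + arange(n_samples) / sampling_rate``.
    """

    sampling_rate: float
    channels: list[ChannelInfo]
    data: np.ndarray
    start_time: float = 0.0

    def __post_init__(self) -> None:
        if not self.sampling_rate > MIN_SAMPLING_RATE:
            raise SamplingError(
                f"sampling_rate must exceed {MIN_SAMPLING_RATE} Hz, "
                f"got {self.sampling_rate}"
            )
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise DataError(f"data must be 2-D, got shape {self.data.shape}")
        if self.data.shape[1] != len(self.channels):
            raise DataError(
                f"data has {self.data.shape[1]} columns but "
                f"{len(self.channels)} channels are declared"
            )
        ids = [c.channel_id for c in self.channels]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise DataError(f"duplicate channel_id(s): {dup}")
        bad = np.argwhere(~np.isfinite(self.data))
        if bad.size:
            r, c = bad[0]
            raise DataError(
                f"non-finite value at row {r}, channel "
                f"{self.channels[c].channel_id!r}"
            )

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def duration(self) -> float:
        """Length of the sampled interval in seconds."""
        return self.n_samples / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.sampling_rate

    @property
    def channel_ids(self) -> list[str]:
        return [c.channel_id for c in self.channels]

    def with_data(self, data: np.ndarray) -> "ContinuousRecording":
        """Copy of this recording with ``data`` replaced (same metadata)."""
        return replace(self, data=np.asarray(data, dtype=float))


@dataclass
class EventList:
    """Trial markers: onset times (seconds) with class labels."""

    onsets: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.labels = [str(x) for x in self.labels]
        if self.onsets.ndim != 1:
            raise DataError("onsets must be 1-D")
        if len(self.onsets) != len(self.labels):
            raise DataError(
                f"{len(self.onsets)} onsets but {len(self.labels)} labels"
            )
        if self.onsets.size and np.any(np.diff(self.onsets) < 0):
            i = int(np.argmax(np.diff(self.onsets) < 0))
            raise OrderingError(
                f"onsets not monotone non-decreasing at index {i + 1}"
            )

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def classes(self) -> list[str]:
        """Distinct labels in sorted order."""
        return sorted(set(self.labels))


# ---------------------------------------------------------------------------
# serialization


def _paths(path: str | Path) -> tuple[Path, Path]:
    """Resolve ``<base>[.nirs[.tsv|.json]]`` to the (tsv, json) pair."""
    p = Path(path)
    name = p.name
    for suffix in (".nirs.tsv", ".nirs.json", ".nirs"):
        if name.endswith(suffix):
            name = name[: -len(suffix)]
            break
    base = p.with_name(name)
    return (
        base.with_name(base.name + ".nirs.tsv"),
        base.with_name(base.name + ".nirs.json"),
    )


def write_recording(recording: ContinuousRecording, path: str | Path) -> None:
    """Write ``recording`` as the TSV + JSON-sidecar pair.

    Values are serialized with 17 significant digits so that
    :func:`read_recording` reproduces them exactly.
    """
    tsv, sidecar = _paths(path)
    header = "\t".join(recording.channel_ids)
    with open(tsv, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(header + "\n")
        for row in recording.data:
            fh.write("\t".join(f"{v:.17g}" for v in row) + "\n")
    meta = {
        "sampling_rate": recording.sampling_rate,
        "start_time": recording.start_time,
        "sample_count": recording.n_samples,
        "channels": [
            {
                "channel_id": c.channel_id,
                "signal_kind": c.signal_kind,
                "source_id": c.source_id,
                "detector_id": c.detector_id,
                "source_detector_distance_mm": c.source_detector_distance_mm,
            }
            for c in recording.channels
        ],
    }
    with open(sidecar, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(meta, fh, indent=1)
        fh.write("\n")


def read_recording(path: str | Path) -> ContinuousRecording:
    """Read a recording written by :func:`write_recording`.

    ``path`` may be the TSV, the sidecar, or the common basename.
    """
    tsv, sidecar = _paths(path)
    if not tsv.exists():
        raise FormatError(f"data file not found: {tsv}")
    if not sidecar.exists():
        raise FormatError(f"missing JSON sidecar: {sidecar}")
    with open(sidecar, encoding="utf-8") as fh:
        try:
            meta = json.load(fh)
        except json.JSONDecodeError as exc:
            raise FormatError(f"sidecar {sidecar} is not valid JSON: {exc}")
    for key in ("sampling_rate", "channels"):
        if key not in meta:
            raise FormatError(f"sidecar {sidecar} lacks required key {key!r}")
    channels = [
        ChannelInfo(
            channel_id=c["channel_id"],
            signal_kind=c["signal_kind"],
            source_id=c.get("source_id"),
            detector_id=c.get("detector_id"),
            source_detector_distance_mm=c.get("source_detector_distance_mm"),
        )
        for c in meta["channels"]
    ]
    table = pd.read_csv(tsv, sep="\t", header=0, dtype=float)
    fs = float(meta["sampling_rate"])
    start = float(meta.get("start_time", 0.0))
    if table.columns.size and table.columns[0] == "time_s":
        t = table["time_s"].to_numpy()
        expected = start + np.arange(len(t)) / fs
        if t.size and np.max(np.abs(t - expected)) > _TIME_JITTER:
            i = int(np.argmax(np.abs(t - expected)))
            raise SamplingError(
                f"timestamp at row {i} deviates from the uniform grid by "
                f"{abs(t[i] - expected[i]):.3g} s (> {_TIME_JITTER} s)"
            )
        table = table.drop(columns="time_s")
    expected_cols = [c.channel_id for c in channels]
    if list(table.columns) != expected_cols:
        raise FormatError(
            f"TSV columns {list(table.columns)} do not match sidecar "
            f"channels {expected_cols}"
        )
    data = table.to_numpy()
    if "sample_count" in meta and data.shape[0] != int(meta["sample_count"]):
        raise FormatError(
            f"TSV has {data.shape[0]} rows, sidecar declares "
            f"{meta['sample_count']}"
        )
    bad = np.argwhere(np.isnan(data))
    if bad.size:
        r, c = bad[0]
        raise DataError(
            f"NaN at row {r}, channel {channels[c].channel_id!r} in {tsv}"
        )
    return ContinuousRecording(
        sampling_rate=fs, channels=channels, data=data, start_time=start
    )


def write_events(events: EventList, path: str | Path) -> None:
    """Write an event list as ``onset_s<TAB>label`` TSV."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("onset_s\tlabel\n")
        for t, lab in zip(events.onsets, events.labels):
            fh.write(f"{t:.17g}\t{lab}\n")


def read_events(path: str | Path) -> EventList:
    """Read an event list; an empty (header-only or zero-byte) file is a
    valid empty list."""
    p = Path(path)
    if not p.exists():
        raise FormatError(f"event file not found: {p}")
    with open(p, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if lines and lines[0].split("\t")[:2] == ["onset_s", "label"]:
        lines = lines[1:]
    onsets, labels = [], []
    for i, ln in enumerate(lines):
        parts = ln.split("\t")
        if len(parts) != 2:
            raise FormatError(
                f"line {i + 1} of {p} has {len(parts)} fields, expected 2"
            )
        try:
            onsets.append(float(parts[0]))
        except ValueError:
            raise FormatError(f"non-numeric onset {parts[0]!r} at line {i + 1}")
        labels.append(parts[1])
    return EventList(onsets=np.asarray(onsets), labels=labels)
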