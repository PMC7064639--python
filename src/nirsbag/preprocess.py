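"""From optical densities to baseline-corrected hemodynamic epochs.

The chain mirrors standard fNIRS practice: optical-density changes are
converted to chromophore concentration changes with the modified
Beer–Lambert law (MBLL), band-pass filtered with a zero-phase Butterworth
filter to suppress cardiac/respiratory/Mayer-wave oscillations and drift,
cut into per-trial epochs around event onsets, and baseline-corrected
against the second preceding each onset.  Every step is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .errors import (
    BoundaryError,
    DataError,
    FilterSpecError,
    IntervalError,
    PairingError,
    ParameterError,
)
from .io import ChannelInfo, ContinuousRecording, EventList

# Default MBLL convention (the choice is a documented convention of this
# package, not a measured constant set): 760/850 nm optodes, specific
# extinction coefficients in 1/(mM*cm) for (HbO, HbR) per wavelength,
# differential pathlength factor 6.0 at both wavelengths, 3 cm geometric
# source-detector separation.
DEFAULT_WAVELENGTHS_NM = (760.0, 850.0)
DEFAULT_EXTINCTION = np.array(
    [
        [1.4866, 3.8437],  # 760 nm: (HbO, HbR)
        [2.5264, 1.7986],  # 850 nm: (HbO, HbR)
    ]
)
DEFAULT_DPF = (6.0, 6.0)
DEFAULT_DISTANCE_CM = 3.0

_CHROMO_SUFFIXES = ("_wl1", "_wl2", "_hbo", "_hbr")


@dataclass(frozen=True)
class MbllParameters:
    """Constants of the modified Beer–Lambert law.

    ``extinction`` is a 2x2 matrix indexed (wavelength, chromophore)
    with chromophore order (HbO, HbR), in 1/(mM*cm); ``dpf`` the
    differential pathlength factors per wavelength; ``distance_cm`` the
    geometric source-detector separation.
    """

    wavelengths_nm: tuple[float, float] = DEFAULT_WAVELENGTHS_NM
    extinction: np.ndarray = field(
        default_factory=lambda: DEFAULT_EXTINCTION.copy()
    )
    dpf: tuple[float, float] = DEFAULT_DPF
    distance_cm: float = DEFAULT_DISTANCE_CM

    def __post_init__(self) -> None:
        ext = np.asarray(self.extinction, dtype=float)
        object.__setattr__(self, "extinction", ext)
        if ext.shape != (2, 2):
            raise ParameterError(f"extinction must be 2x2, got {ext.shape}")
        if abs(np.linalg.det(ext)) <= 1e-12:
            raise ParameterError("extinction matrix is singular")
        if any(d <= 0 for d in self.dpf):
            raise ParameterError("DPF values must be > 0")
        if self.distance_cm <= 0:
            raise ParameterError("distance_cm must be > 0")

    @property
    def pathlength_matrix(self) -> np.ndarray:
        """The 2x2 system matrix M with ΔOD = M @ (ΔHbO, ΔHbR) in mM."""
        scale = self.distance_cm * np.asarray(self.dpf)
        return self.extinction * scale[:, None]


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass specification: Butterworth of ``order`` poles per pass,
    applied forward-backward (zero phase, 2x order effective)."""

    low_cut_hz: float = 0.01
    high_cut_hz: float = 0.09
    order: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.low_cut_hz < self.high_cut_hz:
            raise FilterSpecError(
                f"need 0 < low_cut < high_cut, got "
                f"({self.low_cut_hz}, {self.high_cut_hz})"
            )
        if self.order < 1:
            raise FilterSpecError("order must be >= 1")


@dataclass
class EpochSet:
    """Per-trial cutouts: ``data`` has shape (trials, samples, channels).

    ``window`` is in seconds relative to each event onset; sample ``j`` of
    an epoch lies at relative time ``window[0] + j / sampling_rate``.
    """

    data: np.ndarray
    labels: list[str]
    window: tuple[float, float]
    sampling_rate: float
    channels: list[ChannelInfo]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise DataError(f"epoch data must be 3-D, got {self.data.shape}")
        if self.data.shape[0] != len(self.labels):
            raise DataError(
                f"{self.data.shape[0]} epochs but {len(self.labels)} labels"
            )
        if self.data.shape[2] != len(self.channels):
            raise DataError("channel metadata does not match epoch data")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def rel_times(self) -> np.ndarray:
        """Onset-relative time of every epoch sample."""
        return self.window[0] + np.arange(self.n_samples) / self.sampling_rate


# ---------------------------------------------------------------------------
# channel pairing


def pairing_key(channel: ChannelInfo) -> str:
    """Key grouping the two wavelengths (or the two chromophores) of one
    physical source-detector channel.

    Uses (source_id, detector_id) when both are present, else the
    channel_id with a trailing ``_wl1/_wl2/_hbo/_hbr`` suffix removed.
    """
    if channel.source_id is not None and channel.detector_id is not None:
        return f"{channel.source_id}-{channel.detector_id}"
    cid = channel.channel_id
    low = cid.lower()
    for suf in _CHROMO_SUFFIXES:
        if low.endswith(suf):
            return cid[: -len(suf)]
    return cid


def paired_channels(
    channels: list[ChannelInfo], kinds: tuple[str, str]
) -> list[tuple[str, int, int]]:
    """Group ``channels`` into (key, index_of_kinds[0], index_of_kinds[1])
    triples, preserving first-appearance order of keys."""
    groups: dict[str, dict[str, int]] = {}
    order: list[str] = []
    for i, ch in enumerate(channels):
        if ch.signal_kind not in kinds:
            raise PairingError(
                f"channel {ch.channel_id!r} has kind {ch.signal_kind!r}; "
                f"expected one of {kinds}"
            )
        key = pairing_key(ch)
        if key not in groups:
            groups[key] = {}
            order.append(key)
        if ch.signal_kind in groups[key]:
            raise PairingError(
                f"duplicate {ch.signal_kind!r} channel for pair {key!r}"
            )
        groups[key][ch.signal_kind] = i
    out = []
    for key in order:
        g = groups[key]
        if set(g) != set(kinds):
            raise PairingError(
                f"channel pair {key!r} is incomplete: has {sorted(g)}, "
                f"needs both of {kinds}"
            )
        out.append((key, g[kinds[0]], g[kinds[1]]))
    return out


# ---------------------------------------------------------------------------
# operations


def mbll_convert(
    recording: ContinuousRecording, params: MbllParameters | None = None
) -> ContinuousRecording:
    """Convert optical-density changes to ΔHbO/ΔHbR (µmol/L).

    For each source-detector pair the 2x2 linear system

        ΔOD(λ_i) = d * DPF(λ_i) * [ε(λ_i,HbO) ΔHbO + ε(λ_i,HbR) ΔHbR]

    is solved at every sample; concentrations come out in mM and are
    scaled to µmol/L.  Output channels are named ``<pair>_HbO`` and
    ``<pair>_HbR``, interleaved per pair in input pair order.
    """
    params = params or MbllParameters()
    pairs = paired_channels(
        recording.channels, ("od_wavelength_1", "od_wavelength_2")
    )
    minv = np.linalg.inv(params.pathlength_matrix)
    out_channels: list[ChannelInfo] = []
    cols: list[np.ndarray] = []
    for key, i1, i2 in pairs:
        od = recording.data[:, [i1, i2]]  # samples x wavelengths
        hb_mm = od @ minv.T  # samples x (HbO, HbR)
        template = recording.channels[i1]
        base = pairing_key(template)
        for j, (kind, tag) in enumerate((("hbo", "HbO"), ("hbr", "HbR"))):
            out_channels.append(
                replace(
                    template,
                    channel_id=f"{base}_{tag}",
                    signal_kind=kind,
                )
            )
            cols.append(hb_mm[:, j] * 1000.0)  # mM -> µmol/L
    data = np.column_stack(cols) if cols else np.empty((recording.n_samples, 0))
    return ContinuousRecording(
        sampling_rate=recording.sampling_rate,
        channels=out_channels,
        data=data,
        start_time=recording.start_time,
    )


def bandpass_filter(
    recording: ContinuousRecording, spec: FilterSpec | None = None
) -> ContinuousRecording:
    """Zero-phase Butterworth band-pass, applied per channel.

    The filter runs forward and backward (``filtfilt``), doubling the
    effective order and cancelling phase delay.  Edges are handled by
    odd-symmetric extension of length ``3 * (order + 1)`` samples — fixed
    so results are bit-reproducible.
    """
    spec = spec or FilterSpec()
    nyq = recording.sampling_rate / 2.0
    if spec.high_cut_hz >= nyq:
        raise FilterSpecError(
            f"high_cut {spec.high_cut_hz} Hz >= Nyquist {nyq} Hz"
        )
    padlen = 3 * (spec.order + 1)
    if recording.n_samples <= padlen:
        raise DataError(
            f"recording too short to filter: {recording.n_samples} samples, "
            f"need > {padlen}"
        )
    sos = sps.butter(
        spec.order,
        [spec.low_cut_hz, spec.high_cut_hz],
        btype="bandpass",
        fs=recording.sampling_rate,
        output="sos",
    )
    filtered = sps.sosfiltfilt(
        sos, recording.data, axis=0, padtype="odd", padlen=padlen
    )
    return recording.with_data(filtered)


def segment_epochs(
    recording: ContinuousRecording,
    events: EventList,
    window: tuple[float, float] = (-1.0, 15.0),
) -> EpochSet:
    """Cut one epoch per event over onset-relative times in
    ``[window[0], window[1])``.

    Each onset is snapped to the nearest sample of the recording grid, so
    all epochs have exactly ``round((window[1]-window[0]) * fs)`` samples.
    """
    w0, w1 = float(window[0]), float(window[1])
    if not w1 > w0:
        raise IntervalError(f"window must satisfy w1 > w0, got {window}")
    fs = recording.sampling_rate
    n_epoch = int(round((w1 - w0) * fs))
    starts = []
    for i, onset in enumerate(events.onsets):
        onset_idx = int(round((onset - recording.start_time) * fs))
        start = onset_idx + int(round(w0 * fs))
        if start < 0 or start + n_epoch > recording.n_samples:
            raise BoundaryError(
                f"event {i} (onset {onset} s) needs samples "
                f"[{start}, {start + n_epoch}) outside the recording "
                f"[0, {recording.n_samples})"
            )
        starts.append(start)
    data = np.stack(
        [recording.data[s : s + n_epoch] for s in starts], axis=0
    ) if starts else np.empty((0, n_epoch, recording.n_channels))
    return EpochSet(
        data=data,
        labels=list(events.labels),
        window=(w0, w1),
        sampling_rate=fs,
        channels=list(recording.channels),
    )


def _interval_slice(
    epochs: EpochSet, interval: tuple[float, float]
) -> slice:
    """Sample slice of the half-open onset-relative ``interval``."""
    a, b = float(interval[0]), float(interval[1])
    w0, w1 = epochs.window
    if a < w0 - 1e-9 or b > w1 + 1e-9 or not b > a:
        raise IntervalError(
            f"interval {interval} not contained in epoch window "
            f"{epochs.window}"
        )
    fs = epochs.sampling_rate
    # count grid points with t in [a, b): sample j lies at w0 + j/fs
    tol = 1e-9
    i0 = max(int(np.ceil((a - w0) * fs - tol)), 0)
    i1 = min(int(np.ceil((b - w0) * fs - tol)), epochs.n_samples)
    if i1 <= i0:
        raise IntervalError(f"interval {interval} contains no samples")
    return slice(i0, i1)


def baseline_correct(
    epochs: EpochSet, interval: tuple[float, float] = (-1.0, 0.0)
) -> EpochSet:
    """Subtract, per trial and channel, the mean over the baseline
    ``interval`` (onset-relative, half-open).  Idempotent."""
    sl = _interval_slice(epochs, interval)
    baseline = epochs.data[:, sl, :].mean(axis=1, keepdims=True)
    return EpochSet(
        data=epochs.data - baseline,
        labels=list(epochs.labels),
        window=epochs.window,
        sampling_rate=epochs.sampling_rate,
        channels=list(epochs.channels),
    )
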