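"""Synthetic fNIRS sessions and Gaussian feature sets.

The session generator emulates the block designs typical of mental-task
fNIRS BCI studies: 10-s task periods separated by 13–18-s breaks, 30
trials per class in randomized order, ~9–16 channels sampled at
10–13 Hz.  Each trial evokes a canonical double-gamma hemodynamic
response scaled by a class- and channel-specific amplitude; ΔHbR is a
scaled, delayed mirror of ΔHbO (a stylized but standard convention).
Physiological noise — cardiac (~1.2 Hz), respiratory (~0.25 Hz),
Mayer waves (~0.1 Hz), slow drift and white noise — is added per channel
with seeded random phases.  Everything is deterministic given the seed.

The Gaussian feature generator is a harness for the classifier stack:
per-class multivariate normals with a shared covariance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigError, ParameterError
from .features import FeatureMatrix
from .io import ChannelInfo, ContinuousRecording, EventList
from .preprocess import MbllParameters, paired_channels, pairing_key


@dataclass(frozen=True)
class NoiseConfig:
    """Physiological noise amplitudes, µmol/L (sinusoid peak amplitude;
    ``drift`` and ``white`` are standard deviations)."""

    cardiac_hz: float = 1.2
    cardiac_amp: float = 0.4
    respiratory_hz: float = 0.25
    respiratory_amp: float = 0.4
    mayer_hz: float = 0.1
    mayer_amp: float = 0.3
    drift_sd: float = 0.5
    white_sd: float = 0.2


@dataclass(frozen=True)
class HrfConfig:
    """Shape of the canonical hemodynamic response."""

    peak_time_s: float = 6.0
    undershoot_ratio: float = 0.2
    hbr_ratio: float = -0.3
    hbr_delay_s: float = 1.0


@dataclass(frozen=True)
class SynthSessionConfig:
    """Design of one synthetic session.

    ``class_amplitudes`` maps each class to its per-channel ΔHbO peak
    amplitude (µmol/L).  The default assigns each class a distinct
    spatial pattern: channel c responds at ``amplitude`` for class k
    when ``c % n_classes == k`` and at 0.15 × amplitude otherwise —
    loosely mimicking lateralized/region-specific task activation.
    """

    n_channels: int = 9
    sampling_rate: float = 12.5
    classes: tuple[str, ...] = ("MA", "IS")
    trials_per_class: int = 30
    task_duration_s: float = 10.0
    iti_range_s: tuple[float, float] = (15.0, 17.0)
    amplitude: float = 0.15
    class_amplitudes: dict | None = None
    hrf: HrfConfig = field(default_factory=HrfConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    padding_s: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ConfigError("n_channels must be >= 1")
        if self.trials_per_class < 1:
            raise ConfigError("trials_per_class must be >= 1")
        if len(self.classes) < 2:
            raise ConfigError("need >= 2 classes")
        if self.iti_range_s[0] > self.iti_range_s[1]:
            raise ConfigError(f"bad iti_range {self.iti_range_s}")
        if self.task_duration_s <= 0:
            raise ConfigError("task_duration_s must be > 0")

    def amplitude_map(self) -> dict[str, np.ndarray]:
        """Per-class per-channel ΔHbO amplitudes (µmol/L)."""
        if self.class_amplitudes is not None:
            out = {}
            for c in self.classes:
                if c not in self.class_amplitudes:
                    raise ConfigError(f"class_amplitudes lacks class {c!r}")
                v = np.asarray(self.class_amplitudes[c], dtype=float)
                if v.shape == ():
                    v = np.full(self.n_channels, float(v))
                if v.shape != (self.n_channels,):
                    raise ConfigError(
                        f"amplitudes for {c!r} have shape {v.shape}, "
                        f"need ({self.n_channels},)"
                    )
                out[c] = v
            return out
        k = len(self.classes)
        ch = np.arange(self.n_channels)
        return {
            c: self.amplitude * np.where(ch % k == i, 1.0, 0.15)
            for i, c in enumerate(self.classes)
        }


def canonical_hrf(
    peak_time_s: float = 6.0,
    undershoot_ratio: float = 0.2,
    sampling_rate: float = 12.5,
    duration_s: float = 32.0,
) -> np.ndarray:
    """Double-gamma hemodynamic response kernel, unit peak amplitude.

    The positive lobe is a gamma density with shape 6 and scale
    ``peak_time_s / 5`` (mode exactly at ``peak_time_s``); the
    undershoot a gamma with shape 16 and the same scale, scaled to
    ``undershoot_ratio`` of the main peak.
    """
    if peak_time_s <= 0:
        raise ParameterError("peak_time_s must be > 0")
    if duration_s < 30.0:
        raise ParameterError(
            f"duration_s must cover the kernel support (>= 30 s), "
            f"got {duration_s}"
        )
    if undershoot_ratio < 0:
        raise ParameterError("undershoot_ratio must be >= 0")
    t = np.arange(0.0, duration_s, 1.0 / sampling_rate)
    shape1, shape2 = 6.0, 16.0
    scale = peak_time_s / (shape1 - 1.0)
    from scipy import stats as sst

    g1 = sst.gamma.pdf(t, shape1, scale=scale)
    g2 = sst.gamma.pdf(t, shape2, scale=scale)
    kernel = g1 / g1.max() - undershoot_ratio * g2 / g2.max()
    return kernel / kernel.max()


def generate_session(
    config: SynthSessionConfig | None = None,
) -> tuple[ContinuousRecording, EventList]:
    """Simulate one session: returns (hbo/hbr recording, event list).

    Trial order is a seeded shuffle of ``trials_per_class`` repeats of
    each class; inter-onset gaps are ``task_duration + U(iti_range)``.
    """
    cfg = config or SynthSessionConfig()
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.sampling_rate
    labels = [c for c in cfg.classes for _ in range(cfg.trials_per_class)]
    labels = [labels[i] for i in rng.permutation(len(labels))]
    n_trials = len(labels)
    gaps = cfg.task_duration_s + rng.uniform(
        cfg.iti_range_s[0], cfg.iti_range_s[1], size=n_trials - 1
    )
    onsets = cfg.padding_s + np.concatenate([[0.0], np.cumsum(gaps)])
    total_s = onsets[-1] + cfg.task_duration_s + cfg.padding_s
    n_samples = int(round(total_s * fs))
    t = np.arange(n_samples) / fs

    # neural boxcar per class, convolved with the HRF
    kernel = canonical_hrf(
        cfg.hrf.peak_time_s, cfg.hrf.undershoot_ratio, fs
    )
    amp = cfg.amplitude_map()
    box = {c: np.zeros(n_samples) for c in cfg.classes}
    task_samples = int(round(cfg.task_duration_s * fs))
    for onset, lab in zip(onsets, labels):
        i0 = int(round(onset * fs))
        i1 = min(i0 + task_samples, n_samples)
        box[lab][i0:i1] = 1.0
    # normalize so an isolated trial's response peaks at exactly 1.0,
    # making class amplitudes the per-trial peak ΔHbO in µmol/L
    single_peak = np.convolve(np.ones(task_samples), kernel).max()
    evoked = {
        c: np.convolve(box[c], kernel)[:n_samples] / single_peak
        for c in cfg.classes
    }

    delay = int(round(cfg.hrf.hbr_delay_s * fs))
    nz = cfg.noise
    channels: list[ChannelInfo] = []
    cols: list[np.ndarray] = []
    for ch in range(cfg.n_channels):
        hbo = np.zeros(n_samples)
        for c in cfg.classes:
            hbo += amp[c][ch] * evoked[c]
        hbr = cfg.hrf.hbr_ratio * np.roll(hbo, delay)
        hbr[:delay] = 0.0
        noise = np.zeros(n_samples)
        for freq, a in (
            (nz.cardiac_hz, nz.cardiac_amp),
            (nz.respiratory_hz, nz.respiratory_amp),
            (nz.mayer_hz, nz.mayer_amp),
        ):
            phase = rng.uniform(0, 2 * np.pi)
            noise += a * np.sin(2 * np.pi * freq * t + phase)
        if nz.drift_sd > 0:
            walk = np.cumsum(rng.standard_normal(n_samples))
            sd = walk.std()
            noise += nz.drift_sd * walk / (sd if sd > 0 else 1.0)
        if nz.white_sd > 0:
            noise += nz.white_sd * rng.standard_normal(n_samples)
        noise_hbr = np.zeros(n_samples)
        for freq, a in (
            (nz.cardiac_hz, nz.cardiac_amp),
            (nz.respiratory_hz, nz.respiratory_amp),
            (nz.mayer_hz, nz.mayer_amp),
        ):
            phase = rng.uniform(0, 2 * np.pi)
            noise_hbr += 0.4 * a * np.sin(2 * np.pi * freq * t + phase)
        if nz.drift_sd > 0:
            walk = np.cumsum(rng.standard_normal(n_samples))
            sd = walk.std()
            noise_hbr += 0.4 * nz.drift_sd * walk / (sd if sd > 0 else 1.0)
        if nz.white_sd > 0:
            noise_hbr += 0.4 * nz.white_sd * rng.standard_normal(n_samples)
        base = f"ch{ch + 1}"
        channels.append(
            ChannelInfo(
                channel_id=f"{base}_HbO",
                signal_kind="hbo",
                source_id=f"S{ch + 1}",
                detector_id=f"D{ch + 1}",
            )
        )
        cols.append(hbo + noise)
        channels.append(
            ChannelInfo(
                channel_id=f"{base}_HbR",
                signal_kind="hbr",
                source_id=f"S{ch + 1}",
                detector_id=f"D{ch + 1}",
            )
        )
        cols.append(hbr + noise_hbr)
    recording = ContinuousRecording(
        sampling_rate=fs,
        channels=channels,
        data=np.column_stack(cols),
        start_time=0.0,
    )
    events = EventList(onsets=onsets, labels=labels)
    return recording, events


def hb_to_optical_density(
    recording: ContinuousRecording, params: MbllParameters | None = None
) -> ContinuousRecording:
    """Forward modified Beer–Lambert model: ΔHbO/ΔHbR (µmol/L) to
    optical-density changes at the two wavelengths.

    Exact inverse of :func:`nirsbag.preprocess.mbll_convert` with the
    same parameters.
    """
    params = params or MbllParameters()
    pairs = paired_channels(recording.channels, ("hbo", "hbr"))
    m = params.pathlength_matrix
    channels: list[ChannelInfo] = []
    cols: list[np.ndarray] = []
    for key, i_hbo, i_hbr in pairs:
        hb_mm = recording.data[:, [i_hbo, i_hbr]] / 1000.0  # µmol/L -> mM
        od = hb_mm @ m.T
        template = recording.channels[i_hbo]
        base = pairing_key(template)
        for j, (kind, tag) in enumerate(
            (("od_wavelength_1", "wl1"), ("od_wavelength_2", "wl2"))
        ):
            channels.append(
                replace(template, channel_id=f"{base}_{tag}",
                        signal_kind=kind)
            )
            cols.append(od[:, j])
    return ContinuousRecording(
        sampling_rate=recording.sampling_rate,
        channels=channels,
        data=np.column_stack(cols),
        start_time=recording.start_time,
    )


# ---------------------------------------------------------------------------
# Gaussian feature harness


@dataclass(frozen=True)
class GaussianFeatureConfig:
    """Per-class multivariate normals with one shared covariance.

    ``class_means`` is (n_classes, n_features); ``covariance`` a matrix,
    a scalar (isotropic), or None for the identity.
    """

    class_means: np.ndarray
    n_per_class: int = 30
    covariance: np.ndarray | float | None = None
    class_names: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        means = np.atleast_2d(np.asarray(self.class_means, dtype=float))
        object.__setattr__(self, "class_means", means)
        if self.n_per_class < 1:
            raise ConfigError("n_per_class must be >= 1")
        if self.class_names is not None and len(self.class_names) != len(
            means
        ):
            raise ConfigError("class_names length mismatch")

    @property
    def n_features(self) -> int:
        return self.class_means.shape[1]

    def covariance_matrix(self) -> np.ndarray:
        d = self.n_features
        c = self.covariance
        if c is None:
            return np.eye(d)
        if np.isscalar(c):
            if c < 0:
                raise ParameterError("scalar covariance must be >= 0")
            return float(c) * np.eye(d)
        c = np.asarray(c, dtype=float)
        if c.shape != (d, d):
            raise ParameterError(
                f"covariance shape {c.shape} does not match d={d}"
            )
        if not np.allclose(c, c.T, atol=1e-10):
            raise ParameterError("covariance must be symmetric")
        w = np.linalg.eigvalsh(c)
        if w.min() < -1e-10 * max(1.0, w.max()):
            raise ParameterError("covariance must be positive semidefinite")
        return c


def generate_gaussian_features(
    config: GaussianFeatureConfig,
) -> FeatureMatrix:
    """Draw ``n_per_class`` samples per class from the configured
    Gaussians (seeded)."""
    cov = config.covariance_matrix()
    rng = np.random.default_rng(config.seed)
    k, d = config.class_means.shape
    names = (
        list(config.class_names)
        if config.class_names is not None
        else [f"class{i}" for i in range(k)]
    )
    chol = np.linalg.cholesky(
        cov + 1e-12 * np.eye(d) * max(1.0, np.trace(cov) / d)
    )
    rows, labels = [], []
    for i in range(k):
        z = rng.standard_normal((config.n_per_class, d))
        rows.append(config.class_means[i] + z @ chol.T)
        labels.extend([names[i]] * config.n_per_class)
    return FeatureMatrix(
        values=np.vstack(rows),
        labels=labels,
        feature_names=[f"f{j:03d}" for j in range(d)],
    )
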