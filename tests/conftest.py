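import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from nirsbag import (
    ChannelInfo,
    ContinuousRecording,
    EpochSet,
    GaussianFeatureConfig,
    generate_gaussian_features,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def hb_channels(n_pairs: int) -> list[ChannelInfo]:
    """n_pairs physical channels, each as an (HbO, HbR) column pair."""
    out = []
    for i in range(n_pairs):
        for kind, tag in (("hbo", "HbO"), ("hbr", "HbR")):
            out.append(
                ChannelInfo(
                    channel_id=f"ch{i + 1}_{tag}",
                    signal_kind=kind,
                    source_id=f"S{i + 1}",
                    detector_id=f"D{i + 1}",
                )
            )
    return out


def make_epochs(
    data: np.ndarray,
    labels,
    window=(-1.0, 15.0),
    fs=12.5,
    n_pairs=None,
) -> EpochSet:
    if n_pairs is None:
        n_pairs = data.shape[2] // 2
    return EpochSet(
        data=data,
        labels=list(labels),
        window=window,
        sampling_rate=fs,
        channels=hb_channels(n_pairs),
    )


def weak_gaussian_features(seed: int, delta: float = 0.25, d: int = 36,
                           n_per_class: int = 30):
    """The weak-separation binary condition used throughout: equal
    per-dimension mean offset, identity covariance (Bayes acc ~0.77)."""
    means = np.vstack([np.zeros(d), np.full(d, delta)])
    return generate_gaussian_features(
        GaussianFeatureConfig(
            class_means=means, n_per_class=n_per_class, seed=seed
        )
    )


@pytest.fixture
def small_recording() -> ContinuousRecording:
    """3 HbO channels, 125 samples at 12.5 Hz (10.0 s)."""
    rng = np.random.default_rng(11)
    channels = [
        ChannelInfo(channel_id=f"c{i}", signal_kind="hbo") for i in range(3)
    ]
    return ContinuousRecording(
        sampling_rate=12.5, channels=channels,
        data=rng.standard_normal((125, 3)),
    )


@pytest.fixture
def separable_blobs():
    """Three widely separated Gaussian blobs in 4-D."""
    means = np.array(
        [[0.0] * 4, [12.0] * 4, [-12.0, 12.0, -12.0, 12.0]]
    )
    return generate_gaussian_features(
        GaussianFeatureConfig(
            class_means=means, n_per_class=20,
            class_names=("A", "B", "C"), seed=5,
        )
    )
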