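"""Window-mean hemodynamic features.

One feature per (physical channel, chromophore, window): the temporal
mean of ΔHbO or ΔHbR over a late-task window.  With the defaults
``[5, 10)`` and ``[10, 15)`` s a 9-channel montage yields
9 x 2 chromophores x 2 windows = 36 features, a 16-channel montage 64.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError, FormatError
from .preprocess import EpochSet, _interval_slice, paired_channels

DEFAULT_WINDOWS: tuple[tuple[float, float], ...] = ((5.0, 10.0), (10.0, 15.0))


@dataclass
class FeatureMatrix:
    """Trials x features table with class labels.

    ``feature_names`` encode (channel pair, chromophore, window) as
    ``<pair>:<HbO|HbR>:[w0,w1)`` and fix the column order: channel-major,
    HbO before HbR, windows in the given order.
    """

    values: np.ndarray
    labels: list[str]
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataError(f"values must be 2-D, got {self.values.shape}")
        if self.values.shape[0] != len(self.labels):
            raise DataError(
                f"{self.values.shape[0]} rows but {len(self.labels)} labels"
            )
        if self.values.shape[1] != len(self.feature_names):
            raise DataError("feature_names do not match value columns")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise DataError("feature names must be unique")
        if not np.all(np.isfinite(self.values)):
            raise DataError("feature matrix contains non-finite values")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.labels))

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df["label"] = self.labels
        df.to_csv(path, sep="\t", index=False, float_format="%.17g")

    @classmethod
    def from_tsv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t")
        if "label" not in df.columns:
            raise FormatError(f"{path} lacks the trailing 'label' column")
        labels = df.pop("label").astype(str).tolist()
        return cls(
            values=df.to_numpy(dtype=float),
            labels=labels,
            feature_names=list(df.columns),
        )


def extract_features(
    epochs: EpochSet,
    windows: tuple[tuple[float, float], ...] = DEFAULT_WINDOWS,
) -> FeatureMatrix:
    """Temporal means of ΔHbO and ΔHbR per analysis window.

    Requires both chromophores for every physical channel; window
    half-openness and sample snapping follow the epoching convention.
    """
    pairs = paired_channels(epochs.channels, ("hbo", "hbr"))
    slices = [_interval_slice(epochs, w) for w in windows]
    cols: list[np.ndarray] = []
    names: list[str] = []
    for key, i_hbo, i_hbr in pairs:
        for tag, idx in (("HbO", i_hbo), ("HbR", i_hbr)):
            for (w0, w1), sl in zip(windows, slices):
                cols.append(epochs.data[:, sl, idx].mean(axis=1))
                names.append(f"{key}:{tag}:[{w0:g},{w1:g})")
    values = (
        np.column_stack(cols)
        if cols
        else np.empty((epochs.n_trials, 0))
    )
    return FeatureMatrix(
        values=values, labels=list(epochs.labels), feature_names=names
    )
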