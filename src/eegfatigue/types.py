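"""Core container types shared across the pipeline."""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np


@dataclass
class Recording:
    """One continuous multichannel signal.

    Attributes
    ----------
    data : ndarray, shape (channels, samples)
        Signal values (microvolt-scale arbitrary units).
    rate : float
        Sampling rate in samples per second.
    channel_names : list of str
        One identifier per channel, in row order.
    label : int or None
        Binary state label: 1 = fatigue, 0 = alert, None = unlabeled.
    subject_id : str
    """

    data: np.ndarray
    rate: float
    channel_names: Sequence[str]
    label: Optional[int] = None
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("recording data must be a 2-D (channels x samples) array")
        if self.rate <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.rate}")
        if self.data.shape[0] < 1 or self.data.shape[1] < 1:
            raise ValueError("recording needs at least one channel and one sample")
        self.channel_names = list(self.channel_names)
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} data rows"
            )
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"label must be 0, 1 or None, got {self.label!r}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return self.data.shape[1] / self.rate


@dataclass
class EpochSet:
    """Non-overlapping fixed-length windows cut from one or more recordings."""

    epochs: list  # of (channels, points) ndarrays, identical shapes
    labels: np.ndarray  # one binary label per epoch
    points_per_epoch: int
    rate: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.epochs) != len(self.labels):
            raise ValueError("one label per epoch required")
        for ep in self.epochs:
            if ep.shape[1] != self.points_per_epoch:
                raise ValueError("epoch length disagrees with points_per_epoch")
            if ep.shape != self.epochs[0].shape:
                raise ValueError("all epochs must share an identical shape")

    def __len__(self) -> int:
        return len(self.epochs)

    @property
    def n_channels(self) -> int:
        return self.epochs[0].shape[0] if self.epochs else 0

    def extend(self, other: "EpochSet") -> None:
        if other.epochs:
            if self.epochs and other.epochs[0].shape != self.epochs[0].shape:
                raise ValueError("incompatible epoch shapes")
            if other.rate != self.rate:
                raise ValueError("incompatible sampling rates")
        self.epochs = list(self.epochs) + list(other.epochs)
        self.labels = np.concatenate([self.labels, other.labels])


@dataclass
class FeatureSet:
    """Per-epoch flattened PCA score vectors plus normalization statistics.

    ``X`` has one row per epoch; ``d = channels * n_components`` with
    row-major (channel-major) flattening of the per-epoch score matrix.
    ``norm_stats`` is ``{"method": ..., "offset": [...], "scale": [...]}``
    fitted on training rows only, or None when normalization is off.
    """

    X: np.ndarray
    y: np.ndarray
    variance_ratios: np.ndarray
    norm_stats: Optional[dict] = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        self.variance_ratios = np.asarray(self.variance_ratios, dtype=float)
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y row counts differ")

    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def subset(self, idx) -> "FeatureSet":
        idx = np.asarray(idx)
        vr = (
            self.variance_ratios[idx]
            if self.variance_ratios.shape[0] == self.X.shape[0]
            else self.variance_ratios
        )
        return FeatureSet(self.X[idx], self.y[idx], vr, self.norm_stats, dict(self.params))
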