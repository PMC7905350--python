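"""Deterministic preprocessing: resample, band-pass, epoch, per-epoch PCA features.

The default pipeline mirrors a common offline EEG workflow: rational-factor
downsampling with built-in anti-alias filtering, zero-phase Butterworth
band-pass, segmentation into fixed non-overlapping windows, then a PCA fitted
independently on every epoch (channels as observations, time points as
variables) whose score matrix is flattened into one feature row per epoch.
"""
from __future__ import annotations

import warnings
from fractions import Fraction
from typing import Optional

import numpy as np
from scipy import signal as sps

from .types import EpochSet, FeatureSet, Recording


def resample(rec: Recording, target_rate: float) -> Recording:
    """Downsample a recording with polyphase anti-aliased rational resampling.

    Upsampling is rejected; ``target_rate == rec.rate`` is the identity.
    """
    if target_rate <= 0:
        raise ValueError(f"target rate must be positive, got {target_rate}")
    if target_rate > rec.rate:
        raise ValueError(
            f"upsampling requested ({rec.rate} -> {target_rate} Hz); only "
            "rate reduction is supported"
        )
    if target_rate == rec.rate:
        return Recording(rec.data.copy(), rec.rate, rec.channel_names, rec.label, rec.subject_id)
    frac = Fraction(target_rate / rec.rate).limit_denominator(10_000)
    up, down = frac.numerator, frac.denominator
    out = sps.resample_poly(rec.data, up, down, axis=1)
    return Recording(out, target_rate, rec.channel_names, rec.label, rec.subject_id)


def bandpass(
    rec: Recording,
    low_hz: float,
    high_hz: float,
    order: int = 4,
    zero_phase: bool = True,
) -> Recording:
    """Butterworth band-pass. Zero-phase (forward-backward) by default.

    Note the forward-backward pass doubles the effective roll-off of the
    stated ``order``.
    """
    nyq = rec.rate / 2.0
    if not (0 < low_hz < high_hz < nyq):
        raise ValueError(
            f"band edges must satisfy 0 < low < high < Nyquist ({nyq} Hz); "
            f"got ({low_hz}, {high_hz})"
        )
    if order < 1:
        raise ValueError("filter order must be >= 1")
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=rec.rate, output="sos")
    if zero_phase:
        out = sps.sosfiltfilt(sos, rec.data, axis=1)
    else:
        out = sps.sosfilt(sos, rec.data, axis=1)
    return Recording(out, rec.rate, rec.channel_names, rec.label, rec.subject_id)


def segment(rec: Recording, window_seconds: float) -> EpochSet:
    """Cut a recording into floor(duration/window) non-overlapping epochs.

    Windows are half-open ``[k*W, (k+1)*W)``; a trailing partial window is
    discarded; every epoch inherits the recording label.
    """
    pts = window_seconds * rec.rate
    if pts <= 0 or abs(pts - round(pts)) > 1e-9:
        raise ValueError(
            f"window_seconds * rate must be a positive integer, got {pts}"
        )
    pts = int(round(pts))
    n_epochs = rec.n_samples // pts
    if n_epochs == 0:
        warnings.warn(
            f"recording shorter than one {window_seconds}-s window; empty epoch set",
            stacklevel=2,
        )
    label = rec.label if rec.label is not None else 0
    epochs = [rec.data[:, k * pts : (k + 1) * pts].copy() for k in range(n_epochs)]
    return EpochSet(
        epochs=epochs,
        labels=np.full(n_epochs, label, dtype=int),
        points_per_epoch=pts,
        rate=rec.rate,
    )


def pca_epoch_features(epoch: np.ndarray, n_components: int):
    """PCA of a single epoch; channels are observations, time points variables.

    The epoch matrix is column-mean-centered (per time point across channels)
    and decomposed by SVD; scores are projections onto the top ``n_components``
    directions ordered by decreasing variance. Component signs are fixed by
    making each direction's largest-magnitude loading positive.

    Returns
    -------
    scores : ndarray, shape (channels, n_components)
    cum_fraction : float
        Kept-variance share of total variance (1.0 for a constant epoch).
    """
    epoch = np.asarray(epoch, dtype=float)
    n_ch = epoch.shape[0]
    if not (1 <= n_components <= n_ch - 1):
        raise ValueError(
            f"n_components must be in [1, channels-1] = [1, {n_ch - 1}], "
            f"got {n_components}"
        )
    centered = epoch - epoch.mean(axis=0, keepdims=True)
    total = float(np.sum(centered**2))
    if total == 0.0:
        warnings.warn("constant epoch: zero variance, returning zero scores", stacklevel=2)
        return np.zeros((n_ch, n_components)), 1.0
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    # sign convention: largest-|loading| entry of each direction positive
    for i in range(len(s)):
        j = np.argmax(np.abs(vt[i]))
        if vt[i, j] < 0:
            vt[i] = -vt[i]
            u[:, i] = -u[:, i]
    scores = u[:, :n_components] * s[:n_components]
    cum_fraction = float(np.sum(s[:n_components] ** 2) / total)
    return scores, cum_fraction


def _fit_norm_stats(X: np.ndarray, method: str) -> dict:
    if method == "minmax":
        lo, hi = X.min(axis=0), X.max(axis=0)
        offset = (hi + lo) / 2.0
        scale = (hi - lo) / 2.0
    elif method == "zscore":
        offset = X.mean(axis=0)
        scale = X.std(axis=0, ddof=0)
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    scale = np.where(scale == 0.0, 1.0, scale)
    return {"method": method, "offset": offset.tolist(), "scale": scale.tolist()}


def apply_norm_stats(X: np.ndarray, stats: dict) -> np.ndarray:
    offset = np.asarray(stats["offset"], dtype=float)
    scale = np.asarray(stats["scale"], dtype=float)
    if offset.shape[0] != X.shape[1]:
        raise ValueError(
            f"norm_stats dimension {offset.shape[0]} != feature dimension {X.shape[1]}"
        )
    return (X - offset) / scale


def build_features(
    epoch_set: EpochSet,
    n_components: int = 10,
    normalize: bool = True,
    norm_stats: Optional[dict] = None,
    method: str = "minmax",
) -> FeatureSet:
    """Map every epoch to a flattened PCA score row.

    Training mode (``normalize`` and ``norm_stats is None``) fits per-feature
    offset/scale on these rows; inference mode applies supplied stats without
    refitting.
    """
    if len(epoch_set) == 0:
        return FeatureSet(np.zeros((0, 0)), np.zeros(0, dtype=int), np.zeros(0), None, {})
    rows, fractions = [], []
    for ep in epoch_set.epochs:
        scores, frac = pca_epoch_features(ep, n_components)
        rows.append(scores.ravel(order="C"))
        fractions.append(frac)
    X = np.vstack(rows)
    stats = None
    if normalize:
        if norm_stats is None:
            stats = _fit_norm_stats(X, method)
        else:
            stats = norm_stats
        X = apply_norm_stats(X, stats)
    params = {
        "n_components": n_components,
        "channels": epoch_set.n_channels,
        "points_per_epoch": epoch_set.points_per_epoch,
        "rate": epoch_set.rate,
        "normalize": bool(normalize),
    }
    return FeatureSet(X, epoch_set.labels.copy(), np.asarray(fractions), stats, params)


def preprocess(
    rec: Recording,
    target_rate: float = 200.0,
    band=(1.0, 45.0),
    order: int = 4,
    window_seconds: float = 10.0,
    filter_first: bool = False,
    zero_phase: bool = True,
) -> EpochSet:
    """Resample, band-pass and segment one recording.

    Default order is downsample-then-filter; ``filter_first=True`` swaps the
    two stages (numerically safer when the band sits close to the target
    Nyquist).
    """
    if filter_first:
        rec = bandpass(rec, band[0], band[1], order, zero_phase)
        rec = resample(rec, target_rate)
    else:
        rec = resample(rec, target_rate)
        rec = bandpass(rec, band[0], band[1], order, zero_phase)
    return segment(rec, window_seconds)
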