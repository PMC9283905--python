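"""Epoch extraction and trial feature vectors for intention decoding.

Each keypress onset yields two 0.85 s windows (170 samples at 200 Hz): the
pre-movement window covering [-0.85, 0) s and the movement window covering
[0, 0.85) s, with the onset sample itself belonging to the movement window
so the two are disjoint. Three vectorizations are supported:

* ``F1A`` — "Cartesian" Fourier features over the full band: per channel the
  170-point DFT, DC as a real value and every other non-Nyquist bin as a
  (real, imaginary) pair, 169 values per channel, d = 3549.
* ``F1B`` — the same restricted to bins at or below 5 Hz (k = 0..4 at the
  200/170 Hz bin spacing), 9 values per channel, d = 189.
* ``F2``  — the raw time series flattened channel-major, d = 3570.

Every feature matrix carries a channel index map recording which columns
belong to which electrode; the downstream importance measure is defined on
those column groups.

PCA conditioning reduces dimensionality and then rescales so the *total*
variance of the transformed training data (trace of its covariance) equals
the number of retained components — one global scale, no per-dimension
whitening. This fixes the expected data range that the metric-learning and
SVM kernel-bandwidth grids assume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_array, check_is_fitted

from .data import CHANNELS_1020, Recording

logger = logging.getLogger(__name__)

__all__ = [
    "WINDOW_SAMPLES",
    "EpochSet",
    "FeatureMatrix",
    "extract_windows",
    "fourier_cartesian",
    "time_vectorize",
    "TotalVariancePCA",
]

WINDOW_SAMPLES = 170  # 0.85 s at 200 Hz


@dataclass
class EpochSet:
    """Per-trial windows: (n_trials, 21, 170) with labels and a window tag."""

    epochs: np.ndarray
    labels: np.ndarray
    window: str  # "pre" or "move"
    channels: tuple[str, ...] = CHANNELS_1020

    def __post_init__(self):
        self.epochs = np.asarray(self.epochs, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.epochs.ndim != 3 or self.epochs.shape[2] != WINDOW_SAMPLES:
            raise ValueError(
                f"epochs must be (n, n_ch, {WINDOW_SAMPLES}), got {self.epochs.shape}"
            )
        if self.window not in ("pre", "move"):
            raise ValueError(f"window must be 'pre' or 'move', got {self.window!r}")


@dataclass
class FeatureMatrix:
    """Vectorized trials with per-channel column bookkeeping.

    ``channel_index_map`` maps each channel name to the array of column
    indices carrying that channel's features; the blocks partition the
    columns.
    """

    X: np.ndarray
    labels: np.ndarray
    feature_kind: str  # "F1A", "F1B" or "F2"
    channel_index_map: dict[str, np.ndarray]

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        cols = np.concatenate(list(self.channel_index_map.values()))
        if sorted(cols) != list(range(self.X.shape[1])):
            raise ValueError("channel_index_map must partition the columns")

    @property
    def n_channels(self) -> int:
        return len(self.channel_index_map)


def extract_windows(rec: Recording, window: str) -> EpochSet:
    """Cut per-trial windows around each onset.

    The pre window takes samples ``[onset - 170, onset)`` and the move
    window ``[onset, onset + 170)``. Trials whose window would leave the
    recording are dropped (and logged); an empty result is an error.
    """
    if window not in ("pre", "move"):
        raise ValueError(f"window must be 'pre' or 'move', got {window!r}")
    T = rec.n_samples
    epochs, labels, dropped = [], [], 0
    for onset, lab in zip(rec.onsets, rec.labels):
        start = onset - WINDOW_SAMPLES if window == "pre" else onset
        stop = start + WINDOW_SAMPLES
        if start < 0 or stop > T:
            dropped += 1
            continue
        epochs.append(rec.signals[:, start:stop])
        labels.append(lab)
    if dropped:
        logger.info("extract_windows: dropped %d out-of-range trials", dropped)
    if not epochs:
        raise ValueError("no trial window fits inside the recording")
    return EpochSet(np.stack(epochs), np.asarray(labels), window)


def _block_map(per_channel: int, channels) -> dict[str, np.ndarray]:
    return {
        ch: np.arange(k * per_channel, (k + 1) * per_channel)
        for k, ch in enumerate(channels)
    }


def fourier_cartesian(ep: EpochSet, band: str = "0to5") -> FeatureMatrix:
    """Cartesian (real/imaginary interleaved) DFT features per channel.

    ``band='0to5'`` keeps bins k = 0..4 (at most 4.71 Hz); ``band='full'``
    keeps k = 0..84, excluding the Nyquist bin. DC contributes its real part
    only, so the per-channel counts are 9 and 169 respectively.
    """
    if band not in ("0to5", "full"):
        raise ValueError(f"band must be '0to5' or 'full', got {band!r}")
    n, n_ch, n_t = ep.epochs.shape
    k_max = 4 if band == "0to5" else n_t // 2 - 1
    spec = np.fft.rfft(ep.epochs, axis=2)[:, :, : k_max + 1]
    per_channel = 1 + 2 * k_max
    feats = np.empty((n, n_ch, per_channel))
    feats[:, :, 0] = spec[:, :, 0].real
    feats[:, :, 1::2] = spec[:, :, 1:].real
    feats[:, :, 2::2] = spec[:, :, 1:].imag
    kind = "F1B" if band == "0to5" else "F1A"
    return FeatureMatrix(
        feats.reshape(n, n_ch * per_channel),
        ep.labels,
        kind,
        _block_map(per_channel, ep.channels),
    )


def time_vectorize(ep: EpochSet) -> FeatureMatrix:
    """Flatten each trial channel-major into a d = n_ch * 170 vector."""
    n, n_ch, n_t = ep.epochs.shape
    return FeatureMatrix(
        ep.epochs.reshape(n, n_ch * n_t),
        ep.labels,
        "F2",
        _block_map(n_t, ep.channels),
    )


class TotalVariancePCA(TransformerMixin, BaseEstimator):
    """PCA with a single post-scale normalizing the total retained variance.

    After projecting onto the top ``n_components`` principal directions, one
    global factor ``scale_`` is applied so the trace of the transformed
    training covariance equals the number of components. Dimensions are not
    whitened individually — relative variances between components are kept.

    ``n_components='rank'`` retains every component with non-negligible
    variance (all non-zero-variance PCs).
    """

    def __init__(self, n_components=30):
        self.n_components = n_components

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        pca = PCA(n_components=None, svd_solver="full")
        pca.fit(X)
        tol = max(X.shape) * np.finfo(float).eps * max(pca.singular_values_, default=0)
        rank = int(np.sum(pca.singular_values_ > tol))
        if self.n_components == "rank":
            d_pc = rank
        else:
            d_pc = int(self.n_components)
            if d_pc < 1:
                raise ValueError("n_components must be at least 1")
            if d_pc > rank:
                raise ValueError(
                    f"n_components={d_pc} exceeds the data rank {rank}"
                )
        self.mean_ = pca.mean_
        self.components_ = pca.components_[:d_pc]
        var = pca.explained_variance_[:d_pc]  # ddof=1 variances
        total = float(np.sum(var))
        self.scale_ = float(np.sqrt(d_pc / total)) if total > 0 else 1.0
        self.n_components_ = d_pc
        self.rank_ = rank
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "components_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, expected {self.n_features_in_}"
            )
        return (X - self.mean_) @ self.components_.T * self.scale_

    @property
    def loading_matrix_(self) -> np.ndarray:
        """The composite map Q*s: original feature space -> conditioned PCs."""
        check_is_fitted(self, "components_")
        return self.components_.T * self.scale_
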