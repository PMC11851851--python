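"""Wavelet-statistical feature extraction.

Each epoch channel is decomposed with a multilevel discrete wavelet transform
(Daubechies-4, level 5 by default), giving one approximation band (A5) and
five detail bands (D5..D1).  A fixed set of statistics is computed per band
and the per-channel vectors are concatenated into one fixed-length feature
row per epoch, so the feature count is independent of epoch duration.

At a post-preprocessing rate of 500 Hz the bands approximately cover:
A5 0-7.8 Hz, D5 7.8-15.6 Hz, D4 15.6-31.2 Hz, D3 31.2-62.5 Hz,
D2 62.5-125 Hz, D1 125-250 Hz — so D5/D4 straddle the classical alpha and
beta rhythms where pain-related power differences are expected.

Statistics per band, in fixed order: zero-crossing rate, the 5th/25th/75th/
95th percentiles, mean, median, standard deviation, variance, and root mean
square (10 values; the percentile set is configurable).  The zero-crossing
rate is the fraction of adjacent-sample pairs with a strict sign change,
zeros counting as positive.  Standard deviation and variance are population
(ddof = 0) moments, so RMS^2 = mean^2 + variance holds exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import pywt

from .eeg_io import EpochSet
from .exceptions import ParameterError

#: Band names for a level-5 decomposition, coarsest first.
def band_names(level: int) -> list[str]:
    return [f"A{level}"] + [f"D{j}" for j in range(level, 0, -1)]


@dataclass
class FeatureConfig:
    """Feature-extraction settings.

    ``wavelet``/``level`` select the decomposition (db4, level 5 by default);
    ``mode`` is the signal-extension mode at the boundaries (symmetric
    padding — coefficient counts depend on it); ``percentiles`` is the set of
    percentile statistics computed per band.
    """

    wavelet: str = "db4"
    level: int = 5
    mode: str = "symmetric"
    percentiles: tuple[float, ...] = (5.0, 25.0, 75.0, 95.0)

    @property
    def stat_names(self) -> list[str]:
        return (
            ["zcr"]
            + [f"p{p:g}" for p in self.percentiles]
            + ["mean", "median", "sd", "var", "rms"]
        )

    @property
    def n_stats(self) -> int:
        return len(self.stat_names)


@dataclass
class WaveletBands:
    """Ordered multilevel DWT coefficients: approximation first, then details
    from coarsest (D<level>) to finest (D1)."""

    bands: list[np.ndarray]
    wavelet: str = "db4"
    level: int = 5
    mode: str = "symmetric"

    def __post_init__(self) -> None:
        if len(self.bands) != self.level + 1:
            raise ValueError(
                f"expected {self.level + 1} bands for level {self.level}, "
                f"got {len(self.bands)}"
            )

    @property
    def names(self) -> list[str]:
        return band_names(self.level)


def min_signal_length(wavelet: str = "db4", level: int = 5) -> int:
    """Shortest signal admitting a full ``level``-step decomposition."""
    flen = pywt.Wavelet(wavelet).dec_len
    return (flen - 1) * 2**level


def dwt_decompose(
    signal: np.ndarray, wavelet: str = "db4", level: int = 5, mode: str = "symmetric"
) -> WaveletBands:
    """Multilevel DWT of one channel; returns ``level + 1`` coefficient bands."""
    signal = np.asarray(signal, dtype=np.float64)
    if signal.ndim != 1:
        raise ParameterError("dwt_decompose expects a single-channel 1-D signal")
    minimum = min_signal_length(wavelet, level)
    if signal.size < minimum:
        raise ParameterError(
            f"signal of length {signal.size} too short for a level-{level} "
            f"{wavelet} decomposition (minimum {minimum} samples)"
        )
    coeffs = pywt.wavedec(signal, wavelet, mode=mode, level=level)
    return WaveletBands(list(coeffs), wavelet, level, mode)


def reconstruct(bands: WaveletBands, length: int | None = None) -> np.ndarray:
    """Inverse of :func:`dwt_decompose`; ``length`` trims boundary padding."""
    out = pywt.waverec(bands.bands, bands.wavelet, mode=bands.mode)
    return out[:length] if length is not None else out


def zero_crossing_rate(x: np.ndarray) -> float:
    """Fraction of adjacent pairs with a strict sign change (zeros positive)."""
    s = np.where(np.asarray(x) >= 0, 1, -1)
    return float(np.count_nonzero(s[1:] != s[:-1]) / (len(s) - 1))


def band_statistics(
    coeffs: np.ndarray, percentiles: Sequence[float] = (5.0, 25.0, 75.0, 95.0)
) -> np.ndarray:
    """Statistic vector for one coefficient band (fixed order, see module doc)."""
    c = np.asarray(coeffs, dtype=np.float64)
    if c.ndim != 1 or c.size < 2:
        raise ParameterError("band_statistics requires a 1-D array of length >= 2")
    pct = np.percentile(c, list(percentiles))  # linear interpolation
    mean = float(c.mean())
    var = float(c.var())  # population moment (ddof=0)
    return np.array(
        [zero_crossing_rate(c), *pct, mean, float(np.median(c)),
         float(np.sqrt(var)), var, float(np.sqrt(np.mean(c * c)))]
    )


@dataclass
class FeatureMatrix:
    """``samples x features`` table with unique feature names."""

    values: np.ndarray
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (samples x features)")
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length must match column count")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")
        if not np.isfinite(self.values).all():
            raise ValueError("feature matrix contains NaN/Inf")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.feature_names)


def feature_names_for(
    channel_names: Sequence[str], config: FeatureConfig
) -> list[str]:
    """Channel-major names ``<channel>__<band>__<statistic>``."""
    return [
        f"{ch}__{band}__{stat}"
        for ch in channel_names
        for band in band_names(config.level)
        for stat in config.stat_names
    ]


def channel_features(signal: np.ndarray, config: FeatureConfig) -> np.ndarray:
    """Per-band statistics of one channel, concatenated band-major."""
    bands = dwt_decompose(signal, config.wavelet, config.level, config.mode)
    return np.concatenate(
        [band_statistics(b, config.percentiles) for b in bands.bands]
    )


def extract_features(
    epochs: EpochSet, config: FeatureConfig | None = None
) -> FeatureMatrix:
    """One feature row per epoch: channels x bands x statistics, channel-major.

    The row order matches the epoch order and the column count is fixed by
    the channel count and configuration regardless of epoch durations.
    """
    config = config or FeatureConfig()
    if len(epochs) == 0:
        raise ParameterError("extract_features requires at least one epoch")
    n_ch = epochs.n_channels
    names = feature_names_for(
        epochs.channel_names or [f"ch{i:02d}" for i in range(n_ch)], config
    )
    minimum = min_signal_length(config.wavelet, config.level)
    rows = np.empty((len(epochs), len(names)))
    for i, ep in enumerate(epochs):
        if ep.signal.shape[1] < minimum:
            raise ParameterError(
                f"epoch {i} has {ep.signal.shape[1]} samples, below the "
                f"level-{config.level} minimum of {minimum}"
            )
        rows[i] = np.concatenate(
            [channel_features(ep.signal[ch], config) for ch in range(n_ch)]
        )
    return FeatureMatrix(rows, names)
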