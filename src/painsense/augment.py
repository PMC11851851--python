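"""Training-set augmentation: three signal transforms plus SMOTE balancing.

The transform stage produces, per training sample, two multiplicative
variants ``x * (1 +/- c_mult)``, one uniform-noise variant, and two
frequency-shifted variants built from the analytic signal (Fourier transform
with doubled positive frequencies, i.e. a Hilbert transform) multiplied by
``exp(+/- 2j*pi*c_freq*t)``.  Together with the originals this yields exactly
six rows per input sample.  SMOTE then balances class counts by interpolating
each minority sample toward one of its k nearest same-class neighbours.

Both stages are restricted to training partitions: callers can attach a
:class:`~painsense.evaluate.LeakageGuard` so that any test index reaching
augmentation raises.  Frequency shifting needs a time axis, so in the
feature-space mode ("feature") the row index is treated as a unit-spaced
axis; the signal-space mode ("signal"), operating on epoch signals before
feature extraction, is the default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import hilbert
from sklearn.neighbors import NearestNeighbors

from .eeg_io import Epoch, EpochSet
from .exceptions import ConfigurationError, LeakageError, ParameterError

logger = logging.getLogger(__name__)

#: Variant tags emitted per input sample, in order.
VARIANT_TAGS = ("original", "mult_plus", "mult_minus", "noise", "freq_minus", "freq_plus")


@dataclass
class AugmentationConfig:
    """Transform and balancing constants.

    ``c_mult`` is the multiplicative perturbation (0.05 -> +/-5%);
    ``c_noise`` controls the injected-noise level with two interpretations:
    ``target_sd`` (default) rescales the uniform noise so its realised
    standard deviation is ``c_noise * sigma(train)``; ``formula_literal``
    uses the noise as ``rand * sigma * c_noise`` directly.  ``c_freq`` is
    the spectral shift in Hz.  ``smote_k`` is the SMOTE neighbour count.
    """

    c_mult: float = 0.05
    c_noise: float = 0.02
    noise_mode: str = "target_sd"  # or "formula_literal"
    noise_sigma_scope: str = "partition"  # or "sample"
    c_freq: float = 0.2
    rand_range: tuple[float, float] = (-0.5, 0.5)
    smote_k: int = 5
    space: str = "signal"  # or "feature"
    enable_multiply: bool = True
    enable_noise: bool = True
    enable_freq: bool = True
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.c_mult < 1:
            raise ConfigurationError("c_mult must lie in [0, 1)")
        if self.c_freq < 0:
            raise ConfigurationError("c_freq must be >= 0")
        lo, hi = self.rand_range
        if not np.isclose(lo, -hi) or hi <= 0:
            raise ConfigurationError("rand_range must be symmetric about 0")
        if self.smote_k < 1:
            raise ConfigurationError("smote_k must be >= 1")
        if self.noise_mode not in ("target_sd", "formula_literal"):
            raise ConfigurationError(f"unknown noise_mode {self.noise_mode!r}")
        if self.space not in ("signal", "feature"):
            raise ConfigurationError(f"unknown augmentation space {self.space!r}")


# ---------------------------------------------------------------------------
# The three transform operators
# ---------------------------------------------------------------------------


def multiply(sample: np.ndarray, c_mult: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Return ``(sample * (1 + c), sample * (1 - c))``."""
    sample = np.asarray(sample, dtype=np.float64)
    return sample * (1.0 + c_mult), sample * (1.0 - c_mult)


def add_noise(
    sample: np.ndarray,
    config: AugmentationConfig,
    rng: np.random.Generator,
    sigma: float | None = None,
) -> np.ndarray:
    """Add bounded uniform noise scaled from the data's standard deviation.

    ``sigma`` is the reference standard deviation; it defaults to the
    sample's own (the caller passes the training-partition value when the
    prescribed scope is the whole partition).  A zero-variance sample is
    returned unchanged with a log message.
    """
    sample = np.asarray(sample, dtype=np.float64)
    if sigma is None:
        sigma = float(sample.std())
    if not np.isfinite(sigma):
        raise ParameterError("noise reference standard deviation is not finite")
    if sigma == 0:
        logger.info("zero-variance sample: noise scale 0, returned unchanged")
        return sample.copy()
    lo, hi = config.rand_range
    rand = rng.uniform(lo, hi, size=sample.shape)
    if config.noise_mode == "target_sd":
        uniform_sd = (hi - lo) / np.sqrt(12.0)
        scale = config.c_noise * sigma / uniform_sd
    else:  # formula_literal: rand * sigma * Cnoise
        scale = sigma * config.c_noise
    return sample + rand * scale


def freq_shift(
    signal: np.ndarray, c_freq: float, dt: float
) -> tuple[np.ndarray, np.ndarray]:
    """Shift a single-channel signal's spectrum by ``-c_freq`` and ``+c_freq`` Hz.

    The analytic signal (positive frequencies doubled) is multiplied by
    ``exp(+/- 2j*pi*c_freq*t)`` with ``t = n*dt``; the real part is returned
    as ``(variant_minus, variant_plus)``.
    """
    signal = np.asarray(signal, dtype=np.float64)
    if signal.ndim != 1 or signal.size < 4:
        raise ParameterError("freq_shift expects a 1-D signal of length >= 4")
    nyquist = 0.5 / dt
    if c_freq >= nyquist:
        raise ParameterError(f"c_freq {c_freq} Hz >= Nyquist {nyquist} Hz")
    analytic = hilbert(signal)
    t = np.arange(signal.size) * dt
    rot = np.exp(2j * np.pi * c_freq * t)
    return np.real(analytic / rot), np.real(analytic * rot)


def _sample_variants(
    sample: np.ndarray,
    config: AugmentationConfig,
    rng: np.random.Generator,
    sigma: float,
    dt: float,
) -> list[tuple[str, np.ndarray]]:
    """All enabled variants of one sample (1-D row or 2-D channels x time)."""
    sample = np.asarray(sample, dtype=np.float64)
    out: list[tuple[str, np.ndarray]] = [("original", sample.copy())]
    if config.enable_multiply:
        plus, minus = multiply(sample, config.c_mult)
        out += [("mult_plus", plus), ("mult_minus", minus)]
    if config.enable_noise:
        out.append(("noise", add_noise(sample, config, rng, sigma=sigma)))
    if config.enable_freq:
        rows = np.atleast_2d(sample)
        minus = np.empty_like(rows)
        plus = np.empty_like(rows)
        for ch in range(rows.shape[0]):
            minus[ch], plus[ch] = freq_shift(rows[ch], config.c_freq, dt)
        out += [
            ("freq_minus", minus.reshape(sample.shape)),
            ("freq_plus", plus.reshape(sample.shape)),
        ]
    return out


def transform_training_set(
    X: np.ndarray,
    y: np.ndarray,
    config: AugmentationConfig | None = None,
    dt: float | None = None,
    partition: str = "train",
    guard=None,
    indices: Sequence[int] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Expand a training array with the transform variants of every sample.

    ``X`` is ``(n, d)`` (rows are samples; the last axis is the transform
    axis).  Returns ``(X_aug, y_aug, provenance)`` with six rows per input
    when all operators are enabled, grouped per input sample in
    :data:`VARIANT_TAGS` order.  ``dt`` is the seconds-per-step of the
    transform axis (1.0 in feature space).  Calling this on a test partition
    raises :class:`LeakageError`, as does passing indices registered with a
    leakage guard.
    """
    config = config or AugmentationConfig()
    config.validate()
    if partition != "train":
        raise LeakageError(
            f"augmentation is restricted to training data (got partition={partition!r})"
        )
    if guard is not None:
        guard.check(indices if indices is not None else [])
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if X.shape[0] != len(y):
        raise ParameterError("X and y are misaligned")
    if dt is None:
        dt = 1.0
    rng = np.random.default_rng(config.seed)
    sigma = float(X.std()) if config.noise_sigma_scope == "partition" else None
    rows, labels, tags = [], [], []
    for i in range(X.shape[0]):
        s = sigma if sigma is not None else float(X[i].std())
        for tag, variant in _sample_variants(X[i], config, rng, s, dt):
            rows.append(variant)
            labels.append(y[i])
            tags.append(tag)
    return np.asarray(rows), np.asarray(labels), np.asarray(tags)


def augment_epochs(
    epochs: EpochSet,
    config: AugmentationConfig | None = None,
    guard=None,
    indices: Sequence[int] | None = None,
) -> tuple[EpochSet, np.ndarray]:
    """Signal-space transform of an epoch set (training partition only).

    Returns the expanded :class:`EpochSet` (six epochs per input, labels
    copied) and the provenance tag per output epoch.  The noise reference
    standard deviation is computed over all training-epoch samples.
    """
    config = config or AugmentationConfig()
    config.validate()
    if guard is not None:
        guard.check(indices if indices is not None else [])
    rng = np.random.default_rng(config.seed)
    sigma = epoch_population_sd(epochs)
    dt = 1.0 / epochs.fs
    out_epochs: list[Epoch] = []
    tags: list[str] = []
    for ep in epochs:
        for tag, variant in _sample_variants(ep.signal, config, rng, sigma, dt):
            out_epochs.append(Epoch(variant, ep.rating, ep.duration))
            tags.append(tag)
    return EpochSet(out_epochs, epochs.fs, epochs.channel_names), np.asarray(tags)


def epoch_variants(
    ep: Epoch,
    config: AugmentationConfig,
    sigma: float,
    fs: float,
    rng: np.random.Generator,
) -> list[tuple[str, Epoch]]:
    """Transform variants of a single epoch (used for per-fold assembly)."""
    return [
        (tag, Epoch(variant, ep.rating, ep.duration))
        for tag, variant in _sample_variants(ep.signal, config, rng, sigma, 1.0 / fs)
    ]


def epoch_population_sd(epochs: EpochSet) -> float:
    """Pooled standard deviation over every sample of every epoch."""
    total = sum(ep.signal.size for ep in epochs)
    if total == 0:
        return 0.0
    mean = sum(float(ep.signal.sum()) for ep in epochs) / total
    ss = sum(float(((ep.signal - mean) ** 2).sum()) for ep in epochs)
    return float(np.sqrt(ss / total))


# ---------------------------------------------------------------------------
# SMOTE balancing
# ---------------------------------------------------------------------------


def smote(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 5,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Balance class counts by synthetic-minority oversampling.

    Every class is brought up to the majority-class count.  Each synthetic
    point is ``x + u * (x_nbr - x)`` with ``u ~ U[0, 1]`` and ``x_nbr`` one
    of the ``k`` nearest same-class neighbours (Euclidean) of a randomly
    chosen minority sample.  Originals are preserved verbatim, synthetic
    rows appended; already-balanced input is returned unchanged.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if X.shape[0] != len(y):
        raise ParameterError("X and y are misaligned")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    classes, counts = np.unique(y, return_counts=True)
    target = counts.max()
    new_rows, new_labels = [], []
    for cls, count in zip(classes, counts):
        n_extra = int(target - count)
        if n_extra == 0:
            continue
        if count < 2:
            raise ParameterError(
                f"class {cls!r} has a single sample; SMOTE has no neighbour "
                "to interpolate toward"
            )
        kk = min(k, count - 1)
        if kk < k:
            logger.info(
                "class %r: reducing SMOTE k from %d to %d (class size %d)",
                cls, k, kk, count,
            )
        members = X[y == cls]
        nn = NearestNeighbors(n_neighbors=kk + 1).fit(members)
        _, nbr_idx = nn.kneighbors(members)  # column 0 is the point itself
        parents = rng.integers(0, count, size=n_extra)
        picks = rng.integers(1, kk + 1, size=n_extra)
        gaps = rng.random(n_extra)
        for p, j, u in zip(parents, picks, gaps):
            xp = members[p]
            xn = members[nbr_idx[p, j]]
            new_rows.append(xp + u * (xn - xp))
            new_labels.append(cls)
    if not new_rows:
        return X.copy(), y.copy()
    X_bal = np.vstack([X, np.asarray(new_rows)])
    y_bal = np.concatenate([y, np.asarray(new_labels)])
    return X_bal, y_bal
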