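"""Synthetic EEG generator with the statistical structure the pipeline assumes.

The generator emulates a pain-rating EEG session: ~1000 Hz sampling, tens of
channels, one ``Comment`` marker per trial carrying ``10000 + rating``, and
variable 8-12 s epochs.  Each epoch's signal is a sum of per-band sinusoids
(alpha ~10 Hz, beta ~20 Hz) with random phases whose amplitudes scale with
the trial's pain rating (the class-conditional band-power effect the
classifier is meant to recover), superimposed on pink-ish background noise,
a 50 Hz line-interference sinusoid, and a slow (<0.5 Hz) drift — each a
designed target for one preprocessing stage.  Inter-epoch gaps of one second
contain no oscillatory pain content, so epoching is unambiguous.

All randomness flows through explicit integer seeds; identical seeds give
bit-identical recordings.  This is deliberately not a biophysical forward
model: there is no volume conduction and no electrode geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import fft as spfft

from .eeg_io import EVENT_ID_OFFSET, EventTable, RawRecording
from .exceptions import ConfigurationError
from .features import FeatureMatrix

#: Centre frequency (Hz) and baseline amplitude (uV) of each injected rhythm.
BAND_DEFINITIONS: dict[str, tuple[float, float]] = {
    "alpha": (10.0, 4.0),
    "beta": (20.0, 2.0),
}

_GAP_SECONDS = 1.0  # silent guard interval between epochs
_LEAD_SECONDS = 1.0

_DEFAULT_CHANNELS_62 = [
    # 10-20-ish labels padded to a 62-channel analysis montage
    "Fp1", "Fp2", "AF3", "AF4", "AF7", "AF8", "Fz", "F1", "F2", "F3", "F4",
    "F5", "F6", "F7", "F8", "FC1", "FC2", "FC3", "FC4", "FC5", "FC6", "FT7",
    "FT8", "Cz", "C1", "C2", "C3", "C4", "C5", "C6", "T7", "T8", "CP1",
    "CP2", "CP3", "CP4", "CP5", "CP6", "TP7", "TP8", "Pz", "P1", "P2", "P3",
    "P4", "P5", "P6", "P7", "P8", "PO3", "PO4", "PO7", "PO8", "POz", "Oz",
    "O1", "O2", "FCz", "CPz", "AFz", "F9", "F10",
]


@dataclass
class SimulationConfig:
    """Conditions for one synthetic recording.

    ``band_effect`` maps a rhythm name (``alpha``/``beta``) to either a
    scalar slope ``g`` — the amplitude multiplier grows linearly from 1 at
    rating 1 to ``1 + g`` at rating 10 — or an explicit sequence of ten
    per-rating multipliers.  ``line_noise_amp`` (uV) sets the 50 Hz
    interference, ``drift_amp`` (uV) the sub-0.5 Hz drift, ``noise_sd`` (uV)
    the pink-ish background noise.
    """

    n_channels: int = 62
    fs: float = 1000.0
    n_events: int = 20
    rating_distribution: Sequence[float] = field(default_factory=lambda: [0.1] * 10)
    epoch_duration_range: tuple[float, float] = (8.0, 12.0)
    band_effect: Mapping[str, float | Sequence[float]] = field(
        default_factory=lambda: {"alpha": 1.0, "beta": 0.5}
    )
    line_noise_amp: float = 2.0
    drift_amp: float = 10.0
    noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_channels < 1:
            raise ConfigurationError("n_channels must be >= 1")
        if self.n_events < 1:
            raise ConfigurationError("n_events must be >= 1")
        p = np.asarray(self.rating_distribution, dtype=float)
        if p.shape != (10,) or (p < 0).any() or not np.isclose(p.sum(), 1.0):
            raise ConfigurationError(
                "rating_distribution must be 10 non-negative weights summing to 1"
            )
        lo, hi = self.epoch_duration_range
        if not (0 < lo <= hi):
            raise ConfigurationError(
                "epoch_duration_range must satisfy 0 < low <= high"
            )
        for name, effect in self.band_effect.items():
            if name not in BAND_DEFINITIONS:
                raise ConfigurationError(f"band_effect names unknown band {name!r}")
            if not np.isscalar(effect) and len(np.atleast_1d(effect)) != 10:
                raise ConfigurationError(
                    f"band_effect[{name!r}] must be a scalar or 10 per-rating values"
                )
        highest = max(
            [BAND_DEFINITIONS[b][0] for b in self.band_effect] + [50.0]
        )
        if self.fs <= 2 * highest:
            raise ConfigurationError(
                f"fs must exceed twice the highest injected frequency ({highest} Hz)"
            )
        for name in ("line_noise_amp", "drift_amp", "noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")


def _rating_gain(effect: float | Sequence[float], rating: int) -> float:
    """Amplitude multiplier for one rating under a band-effect setting."""
    if np.isscalar(effect):
        return 1.0 + float(effect) * (rating - 1) / 9.0
    return float(np.atleast_1d(effect)[rating - 1])


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-variance noise with a 1/f-ish spectrum (white below 1 Hz-bin)."""
    m = spfft.next_fast_len(n)  # awkward lengths make the FFT pathological
    white = rng.standard_normal(m)
    spec = spfft.rfft(white)
    freqs = np.fft.rfftfreq(m)
    scale = 1.0 / np.sqrt(np.maximum(freqs, freqs[1] if m > 1 else 1.0))
    out = spfft.irfft(spec * scale, m)[:n]
    sd = out.std()
    return out / sd if sd > 0 else out


def generate_recording(config: SimulationConfig) -> tuple[RawRecording, EventTable]:
    """Simulate one continuous recording and its ground-truth event table."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    fs = config.fs

    ratings = rng.choice(
        np.arange(1, 11), size=config.n_events, p=np.asarray(config.rating_distribution, float)
    )
    lo, hi = config.epoch_duration_range
    durations = rng.uniform(lo, hi, size=config.n_events)

    n_total = int(round(
        (_LEAD_SECONDS + float(np.sum(durations)) + _GAP_SECONDS * config.n_events) * fs
    ))
    data = np.zeros((config.n_channels, n_total), dtype=np.float32)
    t_all = np.arange(n_total, dtype=np.float64) / fs

    # Recording-wide nuisance components.
    for ch in range(config.n_channels):
        row = config.noise_sd * _pink_noise(rng, n_total)
        row += config.line_noise_amp * np.sin(
            2 * np.pi * 50.0 * t_all + rng.uniform(0, 2 * np.pi)
        )
        drift_f = rng.uniform(0.05, 0.3)
        row += config.drift_amp * np.sin(
            2 * np.pi * drift_f * t_all + rng.uniform(0, 2 * np.pi)
        )
        data[ch] += row.astype(np.float32)

    # Rating-conditional oscillations within epochs only.
    starts = np.empty(config.n_events, dtype=np.int64)
    cursor = int(round(_LEAD_SECONDS * fs))
    for i in range(config.n_events):
        starts[i] = cursor
        n_t = int(round(durations[i] * fs))
        t = np.arange(n_t, dtype=np.float64) / fs
        for band, effect in config.band_effect.items():
            freq, base_amp = BAND_DEFINITIONS[band]
            amp = base_amp * _rating_gain(effect, int(ratings[i]))
            phases = rng.uniform(0, 2 * np.pi, size=config.n_channels)
            burst = amp * np.sin(2 * np.pi * freq * t[None, :] + phases[:, None])
            data[:, cursor : cursor + n_t] += burst.astype(np.float32)
        cursor += n_t + int(round(_GAP_SECONDS * fs))

    names = (
        _DEFAULT_CHANNELS_62[: config.n_channels]
        if config.n_channels <= len(_DEFAULT_CHANNELS_62)
        else [f"ch{i:03d}" for i in range(config.n_channels)]
    )
    raw = RawRecording(data, fs, list(names))
    events = EventTable.from_ids(starts, EVENT_ID_OFFSET + ratings)
    return raw, events


def generate_feature_table(
    class_sizes: Sequence[int],
    n_features: int = 10,
    effect_size: float = 1.0,
    seed: int = 0,
) -> tuple[FeatureMatrix, np.ndarray]:
    """Gaussian feature table with class means separated along a random axis.

    Class ``c`` has mean ``c * effect_size * u`` for a random unit vector
    ``u``, so ``effect_size=0`` yields exchangeable classes.  Labels are the
    integer class indices, in block order.
    """
    sizes = [int(s) for s in class_sizes]
    if any(s < 1 for s in sizes):
        raise ConfigurationError("class_sizes must all be >= 1")
    if n_features < 1:
        raise ConfigurationError("n_features must be >= 1")
    rng = np.random.default_rng(seed)
    direction = rng.standard_normal(n_features)
    direction /= np.linalg.norm(direction)
    blocks, labels = [], []
    for c, size in enumerate(sizes):
        blocks.append(rng.standard_normal((size, n_features)) + c * effect_size * direction)
        labels.append(np.full(size, c, dtype=np.int64))
    values = np.vstack(blocks)
    names = [f"f{j:04d}" for j in range(n_features)]
    return FeatureMatrix(values, names), np.concatenate(labels)


# ---------------------------------------------------------------------------
# BrainVision-style triplet writer (mirrors eeg_io.read_brainvision)
# ---------------------------------------------------------------------------


def write_brainvision(
    raw: RawRecording,
    events: EventTable,
    directory: str | Path,
    stem: str = "recording",
) -> Path:
    """Serialise a recording to the minimal BrainVision dialect.

    Writes ``<stem>.vhdr`` (INI header), ``<stem>.eeg`` (multiplexed
    little-endian IEEE float32, microvolts) and ``<stem>.vmrk`` (``Comment``
    markers with 1-based sample positions).  Returns the header path.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    vhdr = directory / f"{stem}.vhdr"
    eeg = directory / f"{stem}.eeg"
    vmrk = directory / f"{stem}.vmrk"

    header = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg.name}",
        f"MarkerFile={vmrk.name}",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={raw.n_channels}",
        f"SamplingInterval={1e6 / raw.fs:.10g}",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "[Channel Infos]",
    ]
    header += [
        f"Ch{i + 1}={name},,1,µV" for i, name in enumerate(raw.channel_names)
    ]
    vhdr.write_text("\n".join(header) + "\n", encoding="utf-8")

    raw.data.T.astype("<f4").tofile(eeg)

    markers = [
        "Brain Vision Data Exchange Marker File, Version 1.0",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg.name}",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0",
    ]
    markers += [
        f"Mk{k + 2}=Comment,{int(events.event_id[k])},{int(events.sample_index[k]) + 1},1,0"
        for k in range(len(events))
    ]
    vmrk.write_text("\n".join(markers) + "\n", encoding="utf-8")
    return vhdr
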