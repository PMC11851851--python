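"""Reading EEG recordings, decoding pain-rating events, epoching and labelling.

The supported on-disk format is the BrainVision-style triplet: an INI-style
header (``.vhdr``) pointing at a binary multiplexed IEEE-float data file
(``.eeg``) and a marker file (``.vmrk``).  Pain trials are marked with
``Comment`` markers whose description is ``10000 + rating`` for a 1-10
self-reported pain rating.  A plain delimited-text fallback (one channel per
column plus a separate event table) is provided for small fixtures.

Ratings map onto two classification schemes:

* binary  — rating <= 5 is ``no_pain``, rating > 5 is ``pain``;
* ternary — rating <= 3 is ``low``, 4-6 is ``moderate``, > 6 is ``high``.
"""

from __future__ import annotations

import configparser
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    BoundsError,
    DecodeError,
    DomainError,
    EEGIOError,
    UnsupportedDialectError,
)

logger = logging.getLogger(__name__)

#: Offset added to a 1-10 pain rating to form a marker event id.
EVENT_ID_OFFSET = 10_000

BINARY_LABELS = ("no_pain", "pain")
TERNARY_LABELS = ("low", "moderate", "high")

# ---------------------------------------------------------------------------
# Core containers
# ---------------------------------------------------------------------------


@dataclass
class RawRecording:
    """A continuous multichannel EEG recording in microvolts.

    Attributes
    ----------
    data:
        ``(n_channels, n_samples)`` array, microvolts.
    fs:
        Sampling rate in Hz.  ``dt`` (seconds per sample) is ``1 / fs``.
    channel_names:
        One label per row of ``data``.
    montage:
        Optional mapping from channel name to (x, y, z) coordinates.
    """

    data: np.ndarray
    fs: float
    channel_names: list[str]
    montage: Mapping[str, tuple[float, float, float]] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} data rows"
            )
        if not np.isfinite(self.data).all():
            raise ValueError("recording contains NaN/Inf samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def dt(self) -> float:
        """Seconds per sample (the reciprocal of the sampling rate)."""
        return 1.0 / self.fs

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, **changes) -> "RawRecording":
        return replace(self, **changes)


@dataclass
class EventTable:
    """Ordered pain-event markers: sample index, event id, decoded rating."""

    sample_index: np.ndarray
    event_id: np.ndarray
    rating: np.ndarray

    def __post_init__(self) -> None:
        self.sample_index = np.asarray(self.sample_index, dtype=np.int64)
        self.event_id = np.asarray(self.event_id, dtype=np.int64)
        self.rating = np.asarray(self.rating, dtype=np.int64)
        n = len(self.sample_index)
        if len(self.event_id) != n or len(self.rating) != n:
            raise ValueError("event table columns have unequal lengths")
        if n > 1 and not (np.diff(self.sample_index) > 0).all():
            raise ValueError("sample_index must be strictly increasing")
        if not np.array_equal(self.rating, self.event_id - EVENT_ID_OFFSET):
            raise ValueError("rating must equal event_id - 10000")
        if n and ((self.rating < 1) | (self.rating > 10)).any():
            raise ValueError("ratings must lie in 1..10")

    @classmethod
    def from_ids(cls, sample_index: Sequence[int], event_id: Sequence[int]) -> "EventTable":
        ids = np.asarray(event_id, dtype=np.int64)
        ratings = np.array([decode_event(i) for i in ids], dtype=np.int64)
        return cls(np.asarray(sample_index), ids, ratings)

    def __len__(self) -> int:
        return len(self.sample_index)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_index": self.sample_index,
                "event_id": self.event_id,
                "rating": self.rating,
            }
        )


@dataclass
class Epoch:
    """One trial window: ``(n_channels, n_t)`` signal plus its pain rating."""

    signal: np.ndarray
    rating: int
    duration: float


@dataclass
class EpochSet:
    """Variable-length trial windows sharing channel count and sampling rate."""

    epochs: list[Epoch]
    fs: float
    channel_names: list[str] | None = None

    def __len__(self) -> int:
        return len(self.epochs)

    def __iter__(self) -> Iterator[Epoch]:
        return iter(self.epochs)

    def __getitem__(self, i) -> Epoch:
        return self.epochs[i]

    @property
    def ratings(self) -> np.ndarray:
        return np.array([e.rating for e in self.epochs], dtype=np.int64)

    @property
    def n_channels(self) -> int:
        return self.epochs[0].signal.shape[0] if self.epochs else 0

    def subset(self, indices: Sequence[int]) -> "EpochSet":
        return EpochSet([self.epochs[i] for i in indices], self.fs, self.channel_names)


@dataclass
class LabelVector:
    """Per-sample class labels under one scheme (``binary`` or ``ternary``)."""

    scheme: str
    values: np.ndarray

    _ALLOWED = {"binary": set(BINARY_LABELS), "ternary": set(TERNARY_LABELS)}

    def __post_init__(self) -> None:
        if self.scheme not in self._ALLOWED:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        self.values = np.asarray(self.values)
        bad = set(np.unique(self.values)) - self._ALLOWED[self.scheme]
        if bad:
            raise ValueError(f"labels {sorted(bad)} invalid for scheme {self.scheme!r}")

    def __len__(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# Event decoding and label mapping
# ---------------------------------------------------------------------------


def decode_event(event_id: int) -> int:
    """Decode a marker event id into a 1-10 pain rating.

    Pain markers carry ``10000 + rating``; e.g. id 10005 is a rating of 5.
    """
    rating = int(event_id) - EVENT_ID_OFFSET
    if not 1 <= rating <= 10:
        raise DecodeError(
            f"event id {event_id} does not encode a pain rating "
            f"(decoded value {rating} outside 1..10)"
        )
    return rating


def _check_rating(rating: int) -> int:
    r = int(rating)
    if not 1 <= r <= 10 or r != rating:
        raise DomainError(f"pain rating must be an integer in 1..10, got {rating!r}")
    return r


def label_binary(rating: int) -> str:
    """Binary scheme: ratings <= 5 are ``no_pain``, ratings > 5 are ``pain``."""
    return BINARY_LABELS[int(_check_rating(rating) > 5)]


def label_ternary(rating: int) -> str:
    """Ternary scheme: <=3 ``low``, 4-6 ``moderate``, >6 ``high``."""
    r = _check_rating(rating)
    if r <= 3:
        return TERNARY_LABELS[0]
    if r <= 6:
        return TERNARY_LABELS[1]
    return TERNARY_LABELS[2]


def make_labels(ratings: Sequence[int], scheme: str) -> LabelVector:
    """Map a rating vector onto a :class:`LabelVector` under one scheme."""
    mapper = {"binary": label_binary, "ternary": label_ternary}.get(scheme)
    if mapper is None:
        raise DomainError(f"unknown labelling scheme {scheme!r}")
    return LabelVector(scheme, np.array([mapper(r) for r in ratings]))


# ---------------------------------------------------------------------------
# Epoching
# ---------------------------------------------------------------------------


def epoch(
    raw: RawRecording,
    events: EventTable,
    max_duration: float = 12.0,
    min_duration: float = 8.0,
) -> EpochSet:
    """Cut one epoch per event from a continuous recording.

    Each epoch starts at its event's sample index and ends at the next event,
    at ``max_duration`` seconds, or at the end of the recording — whichever
    comes first (half-open window ``[start, end)``).  Epochs shorter than
    ``min_duration`` are dropped with a logged count; pass ``min_duration=0``
    to keep them.
    """
    if (events.sample_index >= raw.n_samples).any():
        bad = int(events.sample_index[events.sample_index >= raw.n_samples][0])
        raise BoundsError(
            f"event at sample {bad} beyond end of recording ({raw.n_samples} samples)"
        )
    starts = events.sample_index
    next_start = np.append(starts[1:], raw.n_samples)
    epochs: list[Epoch] = []
    n_short = 0
    for i in range(len(events)):
        start = int(starts[i])
        end = min(int(next_start[i]), start + int(round(max_duration * raw.fs)), raw.n_samples)
        dur = (end - start) / raw.fs
        if dur < min_duration:
            n_short += 1
            continue
        epochs.append(Epoch(raw.data[:, start:end], int(events.rating[i]), dur))
    if n_short:
        logger.info("dropped %d epochs shorter than %.3g s", n_short, min_duration)
    return EpochSet(epochs, raw.fs, list(raw.channel_names))


# ---------------------------------------------------------------------------
# BrainVision-style triplet reader
# ---------------------------------------------------------------------------


def _read_ini(path: Path) -> configparser.ConfigParser:
    """Parse an INI file, tolerating the BrainVision identification line."""
    text = path.read_text(encoding="utf-8", errors="replace")
    lines = text.splitlines()
    first_section = next((i for i, ln in enumerate(lines) if ln.lstrip().startswith("[")), 0)
    parser = configparser.ConfigParser(interpolation=None, strict=False)
    parser.optionxform = str  # keys are case-sensitive (Ch1 vs ch1)
    parser.read_string("\n".join(lines[first_section:]))
    return parser


def read_brainvision(
    header_path: str | Path,
    include: Sequence[str] | None = None,
) -> tuple[RawRecording, EventTable]:
    """Read a BrainVision-style triplet given the path of its ``.vhdr`` header.

    Parameters
    ----------
    header_path:
        Path to the ``.vhdr`` file; the data and marker files it references
        are resolved relative to its directory.
    include:
        Optional analysis montage: channels not in this list are dropped at
        load time with a logged list (recordings often carry miscellaneous or
        unused channels beyond the analysed montage).

    Returns the recording scaled to microvolts and the decoded pain-event
    table.  Only ``Comment`` markers carrying ``10000 + rating`` ids are kept
    as pain events; other marker types are ignored with a logged count.
    """
    header_path = Path(header_path)
    if not header_path.exists():
        raise EEGIOError(f"header file not found: {header_path}")
    hdr = _read_ini(header_path)
    try:
        common = hdr["Common Infos"]
        data_name = common["DataFile"]
        marker_name = common["MarkerFile"]
        n_channels = int(common["NumberOfChannels"])
        fs = 1e6 / float(common["SamplingInterval"])
    except KeyError as exc:
        raise EEGIOError(f"header {header_path.name} missing required key {exc}") from exc

    if common.get("DataFormat", "BINARY").upper() != "BINARY":
        raise UnsupportedDialectError(
            f"unsupported DataFormat {common.get('DataFormat')!r} (only BINARY)"
        )
    if common.get("DataOrientation", "MULTIPLEXED").upper() != "MULTIPLEXED":
        raise UnsupportedDialectError(
            f"unsupported DataOrientation {common.get('DataOrientation')!r}"
        )
    binary_format = hdr.get("Binary Infos", "BinaryFormat", fallback="IEEE_FLOAT_32")
    if binary_format.upper() != "IEEE_FLOAT_32":
        raise UnsupportedDialectError(
            f"unsupported BinaryFormat {binary_format!r} (only IEEE_FLOAT_32)"
        )

    data_path = header_path.parent / data_name
    marker_path = header_path.parent / marker_name
    for companion in (data_path, marker_path):
        if not companion.exists():
            raise EEGIOError(f"companion file not found: {companion}")

    # Channel metadata: Ch<k>=Name,Reference,Resolution,Unit
    names: list[str] = []
    resolutions: list[float] = []
    if hdr.has_section("Channel Infos"):
        for k in range(1, n_channels + 1):
            entry = hdr.get("Channel Infos", f"Ch{k}", fallback=f"ch{k:02d},,1,µV")
            parts = entry.split(",")
            names.append(parts[0] or f"ch{k:02d}")
            try:
                resolutions.append(float(parts[2]) if len(parts) > 2 and parts[2] else 1.0)
            except ValueError:
                resolutions.append(1.0)
    else:
        names = [f"ch{k:02d}" for k in range(1, n_channels + 1)]
        resolutions = [1.0] * n_channels

    flat = np.fromfile(data_path, dtype="<f4")
    if flat.size % n_channels:
        raise EEGIOError(
            f"data file {data_path.name} has {flat.size} values, not divisible "
            f"by the {n_channels} channels declared in the header"
        )
    data = flat.reshape(-1, n_channels).T.astype(np.float32)
    data *= np.asarray(resolutions, dtype=np.float32)[:, None]
    if not np.isfinite(data).all():
        raise EEGIOError(f"data file {data_path.name} contains non-finite samples")

    sample_index, event_id = _parse_markers(marker_path)
    raw = RawRecording(data, fs, names)
    if include is not None:
        keep = [i for i, nm in enumerate(names) if nm in set(include)]
        dropped = [nm for nm in names if nm not in set(include)]
        if dropped:
            logger.info("dropping %d channels outside montage: %s", len(dropped), dropped)
        raw = RawRecording(raw.data[keep], fs, [names[i] for i in keep])
    return raw, EventTable.from_ids(sample_index, event_id)


def _parse_markers(marker_path: Path) -> tuple[list[int], list[int]]:
    """Extract pain events from a ``.vmrk`` file.

    Marker lines read ``Mk<n>=<Type>,<Description>,<Position>,...`` with
    1-based sample positions; only ``Comment`` markers whose description is a
    valid pain id are returned (as 0-based indices).
    """
    mk = _read_ini(marker_path)
    if not mk.has_section("Marker Infos"):
        raise EEGIOError(f"marker file {marker_path.name} has no [Marker Infos] section")
    sample_index: list[int] = []
    event_id: list[int] = []
    n_other = 0
    for key, value in mk.items("Marker Infos"):
        if not key.startswith("Mk"):
            continue
        parts = value.split(",")
        if len(parts) < 3:
            raise EEGIOError(f"malformed marker line {key}={value!r} in {marker_path.name}")
        mtype, description, position = parts[0], parts[1], parts[2]
        if mtype.strip() != "Comment":
            n_other += 1
            continue
        try:
            eid = int(description)
            decode_event(eid)
        except (ValueError, DecodeError):
            n_other += 1
            continue
        sample_index.append(int(position) - 1)
        event_id.append(eid)
    if n_other:
        logger.info("ignored %d non-pain markers in %s", n_other, marker_path.name)
    order = np.argsort(sample_index, kind="stable")
    return [sample_index[i] for i in order], [event_id[i] for i in order]


# ---------------------------------------------------------------------------
# Delimited-text fallback (small fixtures)
# ---------------------------------------------------------------------------


def read_delimited(
    data_path: str | Path,
    events_path: str | Path,
    fs: float,
) -> tuple[RawRecording, EventTable]:
    """Read the plain-text fallback: CSV with one channel per column plus a
    separate event CSV with ``sample_index`` and ``event_id`` columns."""
    frame = pd.read_csv(data_path)
    data = frame.to_numpy(dtype=np.float64).T
    raw = RawRecording(data, fs, list(frame.columns))
    ev = pd.read_csv(events_path)
    table = EventTable.from_ids(ev["sample_index"].to_numpy(), ev["event_id"].to_numpy())
    return raw, table
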