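"""Core data containers and the on-disk session format.

A recording session couples two synchronized streams sampled at different
rates: multichannel EEG (plus an EOG reference channel) and multichannel
NIRS optical densities at three wavelengths.  Both streams share a wall
clock; event markers are stored per stream as sample indices in that
stream's own rate.

Time convention: seconds, task onset = 0, windows are half-open
``[start, end)``; sample ``k`` covers the interval ``[k/rate, (k+1)/rate)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np

__all__ = [
    "ChannelInfo",
    "EventMarker",
    "ContinuousRecording",
    "EpochSet",
    "HemoglobinSeries",
    "CLASSES",
    "write_recording",
    "read_recording",
    "write_session",
    "read_session",
    "export_events_tsv",
]

#: The three task classes: mental arithmetic, motor imagery, idle state.
CLASSES = ("MA", "MI", "IS")

_MODALITIES = ("EEG", "EOG", "NIRS")
_REGIONS = ("frontal", "central", "other")


@dataclass(frozen=True)
class ChannelInfo:
    """Metadata for one recorded channel.

    NIRS channels carry a source/detector pair and, for raw optical-density
    streams, the laser wavelength in nm; EEG/EOG channels carry neither.
    """

    name: str
    modality: str
    region: str = "other"
    source: int | None = None
    detector: int | None = None
    wavelength_nm: float | None = None

    def __post_init__(self) -> None:
        if self.modality not in _MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.region not in _REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        if self.modality == "NIRS":
            if self.source is None or self.detector is None:
                raise ValueError(
                    f"NIRS channel {self.name!r} needs source and detector indices"
                )
        elif self.source is not None or self.detector is not None:
            raise ValueError(
                f"{self.modality} channel {self.name!r} must not carry "
                "source/detector indices"
            )


@dataclass(frozen=True)
class EventMarker:
    """Task onset at ``onset_sample`` (in the carrying stream's rate)."""

    onset_sample: int
    class_label: str

    def __post_init__(self) -> None:
        if self.class_label not in CLASSES:
            raise ValueError(f"unknown class label {self.class_label!r}")


def _check_events(events: Sequence[EventMarker]) -> None:
    onsets = [e.onset_sample for e in events]
    if any(b <= a for a, b in zip(onsets, onsets[1:])):
        raise ValueError("event onset samples must be strictly increasing")


@dataclass
class ContinuousRecording:
    """A channels x samples time-series with rate, metadata and events.

    ``unit`` is one of ``uV`` (EEG), ``OD`` (optical density) or ``mM*cm``
    (hemoglobin concentration change times pathlength).
    """

    data: np.ndarray
    rate: float
    channels: list[ChannelInfo]
    events: list[EventMarker] = field(default_factory=list)
    unit: str = "uV"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.channels):
            raise ValueError(
                f"data has {self.data.shape[0]} rows but {len(self.channels)} "
                "channels are described"
            )
        names = [c.name for c in self.channels]
        if len(set(names)) != len(names):
            raise ValueError("channel names must be unique within a recording")
        if not self.rate > 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")
        _check_events(self.events)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    def channel_names(self) -> list[str]:
        return [c.name for c in self.channels]

    def pick(self, names: Sequence[str]) -> "ContinuousRecording":
        """Sub-recording restricted to the named channels, in given order."""
        index = {c.name: i for i, c in enumerate(self.channels)}
        missing = [n for n in names if n not in index]
        if missing:
            raise KeyError(f"channels not present: {missing}")
        rows = [index[n] for n in names]
        return ContinuousRecording(
            data=self.data[rows].copy(),
            rate=self.rate,
            channels=[self.channels[i] for i in rows],
            events=list(self.events),
            unit=self.unit,
        )


@dataclass
class EpochSet:
    """Trials x channels x time array cut around task onsets.

    ``time_axis`` is in seconds relative to onset, uniformly spaced at
    ``1/rate``; ``labels`` holds one class label per trial.
    """

    data: np.ndarray
    time_axis: np.ndarray
    labels: np.ndarray
    rate: float
    channels: list[ChannelInfo]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.time_axis = np.asarray(self.time_axis, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be 3-D (trials x channels x time)")
        if self.data.shape[0] != len(self.labels):
            raise ValueError("labels length must equal trial count")
        if self.data.shape[2] != len(self.time_axis):
            raise ValueError("time axis length must equal sample count")
        if len(self.time_axis) > 1:
            dt = np.diff(self.time_axis)
            if not np.allclose(dt, 1.0 / self.rate, rtol=0, atol=1e-9):
                raise ValueError("time axis must be uniformly spaced at 1/rate")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def time_mask(self, start_s: float, end_s: float) -> np.ndarray:
        """Boolean mask over the time axis for the half-open [start, end)."""
        return (self.time_axis >= start_s - 1e-9) & (self.time_axis < end_s - 1e-9)

    def select_trials(self, idx: np.ndarray) -> "EpochSet":
        return EpochSet(
            data=self.data[idx],
            time_axis=self.time_axis,
            labels=self.labels[idx],
            rate=self.rate,
            channels=self.channels,
        )


@dataclass
class HemoglobinSeries:
    """Per-channel (HbR, HbO) concentration-change traces in mM*cm.

    ``data`` has shape (n_channels, 2, n_samples) with chromophore axis
    fixed as (HbR, HbO) everywhere.
    """

    data: np.ndarray
    rate: float
    channel_names: list[str]
    events: list[EventMarker] = field(default_factory=list)

    CHROMOPHORES = ("HbR", "HbO")

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3 or self.data.shape[1] != 2:
            raise ValueError("data must be (n_channels, 2, n_samples)")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError("channel_names length must match data")
        _check_events(self.events)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def as_recording(self) -> ContinuousRecording:
        """Flatten to a 2*n_channels recording, channel-major then chromophore."""
        chans = []
        for name in self.channel_names:
            for chromo in self.CHROMOPHORES:
                chans.append(
                    ChannelInfo(
                        name=f"{name}:{chromo}",
                        modality="NIRS",
                        region="frontal",
                        source=0,
                        detector=0,
                    )
                )
        flat = self.data.reshape(self.n_channels * 2, self.n_samples)
        return ContinuousRecording(
            data=flat, rate=self.rate, channels=chans, events=list(self.events),
            unit="mM*cm",
        )


# ---------------------------------------------------------------------------
# HDF5 session container
# ---------------------------------------------------------------------------

_CHANNEL_DTYPE = np.dtype(
    [
        ("name", "S32"),
        ("modality", "S8"),
        ("region", "S8"),
        ("source", "i8"),
        ("detector", "i8"),
        ("wavelength_nm", "f8"),
    ]
)
_EVENT_DTYPE = np.dtype([("onset_sample", "i8"), ("class_label", "S8")])


def _channels_to_table(channels: Sequence[ChannelInfo]) -> np.ndarray:
    table = np.empty(len(channels), dtype=_CHANNEL_DTYPE)
    for i, c in enumerate(channels):
        table[i] = (
            c.name.encode(),
            c.modality.encode(),
            c.region.encode(),
            -1 if c.source is None else c.source,
            -1 if c.detector is None else c.detector,
            np.nan if c.wavelength_nm is None else c.wavelength_nm,
        )
    return table


def _channels_from_table(table: np.ndarray) -> list[ChannelInfo]:
    out = []
    for row in table:
        wl = float(row["wavelength_nm"])
        out.append(
            ChannelInfo(
                name=row["name"].decode(),
                modality=row["modality"].decode(),
                region=row["region"].decode(),
                source=None if row["source"] < 0 else int(row["source"]),
                detector=None if row["detector"] < 0 else int(row["detector"]),
                wavelength_nm=None if np.isnan(wl) else wl,
            )
        )
    return out


def _write_to_group(grp: h5py.Group, rec: ContinuousRecording) -> None:
    grp.create_dataset("data", data=rec.data)
    grp.attrs["rate"] = float(rec.rate)
    grp.attrs["unit"] = rec.unit
    grp.create_dataset("channels", data=_channels_to_table(rec.channels))
    events = np.empty(len(rec.events), dtype=_EVENT_DTYPE)
    for i, e in enumerate(rec.events):
        events[i] = (e.onset_sample, e.class_label.encode())
    grp.create_dataset("events", data=events)


def _read_from_group(grp: h5py.Group) -> ContinuousRecording:
    for key in ("data", "channels", "events"):
        if key not in grp:
            raise ValueError(f"malformed container: missing field '{key}'")
    for attr in ("rate", "unit"):
        if attr not in grp.attrs:
            raise ValueError(f"malformed container: missing attribute '{attr}'")
    events = [
        EventMarker(int(r["onset_sample"]), r["class_label"].decode())
        for r in grp["events"][()]
    ]
    return ContinuousRecording(
        data=grp["data"][()],
        rate=float(grp.attrs["rate"]),
        channels=_channels_from_table(grp["channels"][()]),
        events=events,
        unit=str(grp.attrs["unit"]),
    )


def write_recording(rec: ContinuousRecording, path: str | Path,
                    group: str = "/") -> None:
    """Write a single recording to ``path`` (HDF5), under ``group``."""
    with h5py.File(path, "a") as f:
        if group != "/" and group in f:
            del f[group]
        grp = f if group == "/" else f.create_group(group)
        _write_to_group(grp, rec)


def read_recording(path: str | Path, group: str = "/") -> ContinuousRecording:
    """Read a recording written by :func:`write_recording`; exact round-trip."""
    with h5py.File(path, "r") as f:
        if group != "/" and group not in f:
            raise ValueError(f"malformed container: missing group '{group}'")
        return _read_from_group(f if group == "/" else f[group])


def write_session(path: str | Path, eeg: ContinuousRecording,
                  nirs: ContinuousRecording) -> None:
    """Write one synchronized EEG+NIRS session to a single HDF5 file."""
    path = Path(path)
    if path.exists():
        path.unlink()
    write_recording(eeg, path, group="eeg")
    write_recording(nirs, path, group="nirs")


def read_session(path: str | Path) -> tuple[ContinuousRecording, ContinuousRecording]:
    return read_recording(path, group="eeg"), read_recording(path, group="nirs")


def export_events_tsv(rec: ContinuousRecording, path: str | Path) -> None:
    """Export events as tab-separated text (onset_seconds, class_label)."""
    with open(path, "w") as f:
        f.write("onset_seconds\tclass_label\n")
        for e in rec.events:
            f.write(f"{e.onset_sample / rec.rate:.6f}\t{e.class_label}\n")


def rescale_events(events: Sequence[EventMarker], old_rate: float,
                   new_rate: float) -> list[EventMarker]:
    """Map event onsets to a new sampling rate (nearest sample, ties toward 0)."""
    factor = new_rate / old_rate
    out = []
    for e in events:
        x = e.onset_sample * factor
        rounded = int(np.sign(x) * np.ceil(abs(x) - 0.5))
        out.append(EventMarker(rounded, e.class_label))
    return out
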