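"""Shared data model for RSVP EEG recordings, epochs and cohorts, plus container I/O.

Conventions
-----------
* Sample indexing is 0-based; epoch windows are half-open ``[start, end)`` in
  milliseconds relative to the event trigger.
* Epoch tensors are trial-major, channel-major: ``(n_trials, n_channels, n_samples)``.
* Amplitudes are in microvolts.

Containers are single HDF5 files that round-trip every object bit-exactly
(data arrays keep their dtype on disk; float32 is the recommended interchange
dtype and what the simulator emits).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "FormatError",
    "Event",
    "RawRecording",
    "EpochedRecording",
    "CohortIndex",
    "write_container",
    "read_container",
    "read_events_csv",
    "write_events_csv",
    "n_window_samples",
]


class ValidationError(ValueError):
    """An object violates one of its structural invariants (names the field)."""


class FormatError(IOError):
    """A container file is missing, truncated or not in the expected layout."""


def n_window_samples(window_ms: tuple[float, float], sample_rate: float) -> int:
    """Number of samples spanned by a half-open ``[start, end)`` ms window."""
    start, end = window_ms
    return int(round((end - start) / 1000.0 * sample_rate))


@dataclass(frozen=True)
class Event:
    """A single stimulus presentation.

    Parameters
    ----------
    onset_sample : int
        0-based sample index into the continuous recording.
    label : int
        1 for target, 0 for non-target.
    sequence_index : int
        Index of the stimulus sequence the event belongs to.
    """

    onset_sample: int
    label: int
    sequence_index: int = 0

    def __post_init__(self) -> None:
        if self.onset_sample < 0:
            raise ValidationError(f"Event.onset_sample must be >= 0, got {self.onset_sample}")
        if self.label not in (0, 1):
            raise ValidationError(f"Event.label must be 0 or 1, got {self.label}")


@dataclass
class RawRecording:
    """Continuous multi-channel EEG for one (subject, session, block)."""

    subject_id: str
    session_id: str
    block_id: str
    sample_rate: float
    channel_labels: list[str]
    data: np.ndarray  # (n_channels, n_samples), microvolts
    events: list[Event]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValidationError("RawRecording.data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.channel_labels):
            raise ValidationError(
                f"RawRecording.data has {self.data.shape[0]} rows but "
                f"{len(self.channel_labels)} channel_labels"
            )
        if self.sample_rate <= 0:
            raise ValidationError(f"RawRecording.sample_rate must be > 0, got {self.sample_rate}")
        n = self.data.shape[1]
        bad = [e for e in self.events if e.onset_sample >= n]
        if bad:
            raise ValidationError(
                f"RawRecording.events: {len(bad)} onsets >= sample count {n} "
                f"(first offender at sample {bad[0].onset_sample})"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RawRecording):
            return NotImplemented
        return (
            self.subject_id == other.subject_id
            and self.session_id == other.session_id
            and self.block_id == other.block_id
            and self.sample_rate == other.sample_rate
            and self.channel_labels == other.channel_labels
            and self.data.dtype == other.data.dtype
            and np.array_equal(self.data, other.data)
            and self.events == other.events
        )


@dataclass
class EpochedRecording:
    """Per-trial EEG epochs for one (subject, session, block).

    ``data`` has shape ``(n_trials, n_channels, n_samples)`` with
    ``n_samples == round((end - start) / 1000 * sample_rate)`` for the
    half-open window ``window_ms = (start, end)`` in ms relative to trigger.
    """

    subject_id: str
    session_id: str
    block_id: str
    data: np.ndarray
    labels: np.ndarray
    sample_rate: float
    window_ms: tuple[float, float]
    channel_labels: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.data.ndim != 3:
            raise ValidationError("EpochedRecording.data must be 3-D (trials x channels x samples)")
        if len(self.labels) != self.data.shape[0]:
            raise ValidationError(
                f"EpochedRecording.labels has length {len(self.labels)} but data has "
                f"{self.data.shape[0]} trials"
            )
        if self.labels.size and not np.isin(self.labels, (0, 1)).all():
            raise ValidationError("EpochedRecording.labels must be in {0, 1}")
        if self.data.shape[1] != len(self.channel_labels):
            raise ValidationError(
                f"EpochedRecording.data has {self.data.shape[1]} channels but "
                f"{len(self.channel_labels)} channel_labels"
            )
        expect = n_window_samples(tuple(self.window_ms), self.sample_rate)
        if self.data.shape[2] != expect:
            raise ValidationError(
                f"EpochedRecording.window_ms {self.window_ms} at {self.sample_rate} Hz "
                f"implies {expect} samples, data has {self.data.shape[2]}"
            )
        self.window_ms = (float(self.window_ms[0]), float(self.window_ms[1]))

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EpochedRecording):
            return NotImplemented
        return (
            self.subject_id == other.subject_id
            and self.session_id == other.session_id
            and self.block_id == other.block_id
            and self.sample_rate == other.sample_rate
            and self.window_ms == other.window_ms
            and self.channel_labels == other.channel_labels
            and self.data.dtype == other.data.dtype
            and np.array_equal(self.data, other.data)
            and np.array_equal(self.labels, other.labels)
        )


@dataclass
class CohortIndex:
    """An ordered cohort of members with their epoched recordings.

    ``recordings`` maps ``(member_id, session_id, block_id)`` to an
    :class:`EpochedRecording`.  Within one (session, block) every member must
    be present and all recordings must agree on sample rate, window and trial
    count (simultaneous pseudo-collaboration: one shared stimulus schedule).
    """

    members: list[str]
    recordings: dict[tuple[str, str, str], EpochedRecording] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.members)) != len(self.members):
            raise ValidationError("CohortIndex.members must be unique")
        by_sb: dict[tuple[str, str], list[EpochedRecording]] = {}
        for (m, s, b), rec in self.recordings.items():
            if m not in self.members:
                raise ValidationError(f"CohortIndex.recordings references unknown member {m!r}")
            by_sb.setdefault((s, b), []).append(rec)
        for (s, b), recs in by_sb.items():
            if len(recs) != len(self.members):
                raise ValidationError(
                    f"CohortIndex: (session={s!r}, block={b!r}) has {len(recs)} recordings "
                    f"for {len(self.members)} members"
                )
            ref = recs[0]
            for rec in recs[1:]:
                if (
                    rec.sample_rate != ref.sample_rate
                    or rec.window_ms != ref.window_ms
                    or rec.n_trials != ref.n_trials
                ):
                    raise ValidationError(
                        f"CohortIndex: recordings disagree on sample_rate/window_ms/trials "
                        f"within (session={s!r}, block={b!r})"
                    )

    def block(self, session_id: str, block_id: str) -> dict[str, EpochedRecording]:
        """All members' recordings for one (session, block), in member order."""
        out = {}
        for m in self.members:
            key = (m, session_id, block_id)
            if key not in self.recordings:
                raise KeyError(f"no recording for member={m!r} session={session_id!r} block={block_id!r}")
            out[m] = self.recordings[key]
        return out

    @property
    def sessions(self) -> list[str]:
        return sorted({s for (_, s, _) in self.recordings})

    @property
    def blocks(self) -> list[str]:
        return sorted({b for (_, _, b) in self.recordings})

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CohortIndex):
            return NotImplemented
        return self.members == other.members and self.recordings == other.recordings


# ---------------------------------------------------------------------------
# Container I/O (HDF5)
# ---------------------------------------------------------------------------

_FORMAT = "cobci-container"
_VERSION = 1


def _write_events(grp: h5py.Group, events: Sequence[Event]) -> None:
    grp.create_dataset("event_onsets", data=np.array([e.onset_sample for e in events], dtype=np.int64))
    grp.create_dataset("event_labels", data=np.array([e.label for e in events], dtype=np.int8))
    grp.create_dataset("event_sequences", data=np.array([e.sequence_index for e in events], dtype=np.int64))


def _read_events(grp: h5py.Group) -> list[Event]:
    onsets = grp["event_onsets"][()]
    labels = grp["event_labels"][()]
    seqs = grp["event_sequences"][()]
    return [Event(int(o), int(l), int(s)) for o, l, s in zip(onsets, labels, seqs)]


def _write_raw(grp: h5py.Group, rec: RawRecording) -> None:
    grp.attrs["kind"] = "raw"
    grp.attrs["subject_id"] = rec.subject_id
    grp.attrs["session_id"] = rec.session_id
    grp.attrs["block_id"] = rec.block_id
    grp.attrs["sample_rate"] = rec.sample_rate
    grp.attrs["channel_labels"] = [str(c) for c in rec.channel_labels]
    grp.create_dataset("data", data=rec.data)
    _write_events(grp, rec.events)


def _read_raw(grp: h5py.Group) -> RawRecording:
    return RawRecording(
        subject_id=str(grp.attrs["subject_id"]),
        session_id=str(grp.attrs["session_id"]),
        block_id=str(grp.attrs["block_id"]),
        sample_rate=float(grp.attrs["sample_rate"]),
        channel_labels=[str(c) for c in grp.attrs["channel_labels"]],
        data=grp["data"][()],
        events=_read_events(grp),
    )


def _write_epochs(grp: h5py.Group, rec: EpochedRecording) -> None:
    grp.attrs["kind"] = "epochs"
    grp.attrs["subject_id"] = rec.subject_id
    grp.attrs["session_id"] = rec.session_id
    grp.attrs["block_id"] = rec.block_id
    grp.attrs["sample_rate"] = rec.sample_rate
    grp.attrs["window_ms"] = list(rec.window_ms)
    grp.attrs["channel_labels"] = [str(c) for c in rec.channel_labels]
    grp.create_dataset("data", data=rec.data)
    grp.create_dataset("labels", data=rec.labels)


def _read_epochs(grp: h5py.Group) -> EpochedRecording:
    return EpochedRecording(
        subject_id=str(grp.attrs["subject_id"]),
        session_id=str(grp.attrs["session_id"]),
        block_id=str(grp.attrs["block_id"]),
        data=grp["data"][()],
        labels=grp["labels"][()],
        sample_rate=float(grp.attrs["sample_rate"]),
        window_ms=tuple(grp.attrs["window_ms"]),
        channel_labels=[str(c) for c in grp.attrs["channel_labels"]],
    )


def write_container(obj: RawRecording | EpochedRecording | CohortIndex, path: str | Path) -> Path:
    """Write a recording or cohort to a self-describing HDF5 container.

    Validation runs on construction, so any object reaching this point is
    structurally sound; ``read_container(write_container(x)) == x`` bit-exactly.
    """
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["format"] = _FORMAT
        f.attrs["version"] = _VERSION
        if isinstance(obj, RawRecording):
            f.attrs["container_type"] = "raw"
            _write_raw(f, obj)
        elif isinstance(obj, EpochedRecording):
            f.attrs["container_type"] = "epochs"
            _write_epochs(f, obj)
        elif isinstance(obj, CohortIndex):
            f.attrs["container_type"] = "cohort"
            f.attrs["members"] = [str(m) for m in obj.members]
            recs = f.create_group("recordings")
            for i, ((m, s, b), rec) in enumerate(sorted(obj.recordings.items())):
                g = recs.create_group(f"rec{i:04d}")
                _write_epochs(g, rec)
                g.attrs["member_id"] = m
                g.attrs["session_id"] = s
                g.attrs["block_id"] = b
        else:
            raise TypeError(f"cannot write object of type {type(obj).__name__}")
    return path


def read_container(path: str | Path) -> RawRecording | EpochedRecording | CohortIndex:
    """Read a container written by :func:`write_container`, re-validating invariants."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such container: {path}")
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise FormatError(f"{path} is not a readable HDF5 container: {exc}") from exc
    with f:
        if f.attrs.get("format") != _FORMAT:
            raise FormatError(f"{path}: missing or foreign 'format' attribute")
        ctype = f.attrs.get("container_type")
        try:
            if ctype == "raw":
                return _read_raw(f)
            if ctype == "epochs":
                return _read_epochs(f)
            if ctype == "cohort":
                members = [str(m) for m in f.attrs["members"]]
                recordings = {}
                for name in sorted(f["recordings"]):
                    g = f["recordings"][name]
                    rec = _read_epochs(g)
                    key = (str(g.attrs["member_id"]), str(g.attrs["session_id"]), str(g.attrs["block_id"]))
                    recordings[key] = rec
                return CohortIndex(members=members, recordings=recordings)
        except KeyError as exc:
            raise FormatError(f"{path}: container is missing key {exc}") from exc
        raise FormatError(f"{path}: unknown container_type {ctype!r}")


# ---------------------------------------------------------------------------
# Events CSV  (header: onset_ms,label,sequence)
# ---------------------------------------------------------------------------

def write_events_csv(events: Sequence[Event], sample_rate: float, path: str | Path) -> Path:
    """Export events as CSV with onsets in milliseconds."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "onset_ms": [e.onset_sample / sample_rate * 1000.0 for e in events],
            "label": [e.label for e in events],
            "sequence": [e.sequence_index for e in events],
        }
    )
    df.to_csv(path, index=False)
    return path


def read_events_csv(path: str | Path, sample_rate: float) -> list[Event]:
    """Import an ``onset_ms,label,sequence`` CSV, converting onsets to samples."""
    df = pd.read_csv(path)
    required = {"onset_ms", "label", "sequence"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: events CSV must have columns {sorted(required)}")
    return [
        Event(int(round(row.onset_ms / 1000.0 * sample_rate)), int(row.label), int(row.sequence))
        for row in df.itertuples()
    ]
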