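"""Ingestion of MIDI scale performances.

Reads Standard MIDI Files, segments the note stream into candidate two-octave
scale runs, validates them against the expected C-major pitch sequence, and
maps pitches to scale ranks.

Direction is stored body-centered: for the right hand an ascending
(keyboard-order) scale is an *outward* movement, for the left hand ascending
is *inward*.  All per-note vectors downstream are indexed by temporal order
(the order in which the notes were struck), not keyboard order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .smf import RawNote, read_smf

log = logging.getLogger(__name__)

HANDS = ("left", "right")
DIRECTIONS = ("inward", "outward")

#: pitch classes of the C-major scale
_MAJOR_PCS = (0, 2, 4, 5, 7, 9, 11)


class DomainError(ValueError):
    """Raised when an operation's precondition is violated."""


@dataclass(frozen=True)
class NoteEvent:
    """One keystroke: pitch plus onset/offset in ms from file start."""

    pitch: int
    onset: float
    offset: float
    velocity: int = 64

    def __post_init__(self) -> None:
        if not 0 <= self.pitch <= 127:
            raise DomainError(f"pitch {self.pitch} outside MIDI range")
        if self.onset < 0 or self.offset <= self.onset:
            raise DomainError("need offset > onset >= 0")
        if not 1 <= self.velocity <= 127:
            raise DomainError(f"velocity {self.velocity} outside 1-127")


@dataclass(frozen=True)
class ScaleSpec:
    """Two-octave C-major scale task: C3 to C5, 15 notes at 8 notes/s."""

    start_pitch: int = 48
    end_pitch: int = 72
    tempo_bpm: float = 120.0
    notes_per_beat: int = 4

    @property
    def nominal_ioi(self) -> float:
        """Nominal inter-onset interval in ms (125 ms at 120 BPM, 4/beat)."""
        return 60_000.0 / (self.tempo_bpm * self.notes_per_beat)

    @property
    def pitches(self) -> tuple[int, ...]:
        """Scale tones from start to end inclusive, ascending keyboard order."""
        return tuple(
            p for p in range(self.start_pitch, self.end_pitch + 1) if p % 12 in _MAJOR_PCS
        )

    @property
    def n_notes(self) -> int:
        return len(self.pitches)


def pitch_to_rank(pitch: int, spec: ScaleSpec | None = None) -> int:
    """Rank of a scale tone counted from the starting C (C3=0 ... C5=14).

    The rank is keyboard-order position in the scale, independent of playing
    direction.
    """
    spec = spec or ScaleSpec()
    pitches = spec.pitches
    if pitch not in pitches:
        raise DomainError(f"pitch {pitch} is not a scale tone in [{spec.start_pitch}, {spec.end_pitch}]")
    return pitches.index(pitch)


def expected_pitch_sequence(spec: ScaleSpec, hand: str, direction: str) -> tuple[int, ...]:
    """Pitches in playing order for a hand and body-centered direction.

    Right hand outward and left hand inward sound ascending; the other two
    combinations sound descending.
    """
    if hand not in HANDS:
        raise DomainError(f"unknown hand {hand!r}")
    if direction not in DIRECTIONS:
        raise DomainError(f"unknown direction {direction!r}")
    ascending = (hand == "right") == (direction == "outward")
    pitches = spec.pitches
    return pitches if ascending else tuple(reversed(pitches))


def keyboard_direction(hand: str, direction: str) -> str:
    """Map body-centered (hand, direction) to 'ascending'/'descending'."""
    ascending = (hand == "right") == (direction == "outward")
    return "ascending" if ascending else "descending"


@dataclass(frozen=True)
class ScaleRun:
    """One validated 15-note scale run.

    ``notes`` are in temporal (playing) order.  ``ranks`` are the temporal
    indices 0..14; ``scale_ranks`` give each note's keyboard-order rank, which
    runs 14..0 for descending-sounding runs.
    """

    notes: tuple[NoteEvent, ...]
    hand: str
    direction: str
    session: str = ""
    spec: ScaleSpec = field(default_factory=ScaleSpec)

    def __post_init__(self) -> None:
        if len(self.notes) != self.spec.n_notes:
            raise DomainError(f"a scale run has {self.spec.n_notes} notes, got {len(self.notes)}")
        expected = expected_pitch_sequence(self.spec, self.hand, self.direction)
        got = tuple(n.pitch for n in self.notes)
        if got != expected:
            raise DomainError("pitch sequence does not match the scale for this hand/direction")
        onsets = [n.onset for n in self.notes]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise DomainError("onsets must be strictly increasing")

    @property
    def onsets(self) -> tuple[float, ...]:
        return tuple(n.onset for n in self.notes)

    @property
    def ranks(self) -> tuple[int, ...]:
        """Temporal indices 0..14, the regressor for the deviation fit."""
        return tuple(range(len(self.notes)))

    @property
    def scale_ranks(self) -> tuple[int, ...]:
        """Keyboard-order rank of each note in playing order."""
        return tuple(pitch_to_rank(n.pitch, self.spec) for n in self.notes)


@dataclass(frozen=True)
class Rejection:
    """A candidate run that failed validation, with the reason."""

    start_index: int
    n_notes: int
    reason: str


def read_midi_notes(source: str | bytes) -> list[NoteEvent]:
    """Read an SMF file (path or bytes) into onset-sorted NoteEvents.

    Velocity is carried through but unused by the timing pipeline.
    """
    raw: list[RawNote] = read_smf(source)
    return [NoteEvent(pitch=n.pitch, onset=n.onset_ms, offset=n.offset_ms, velocity=n.velocity) for n in raw]


def _classify_rejection(segment: tuple[int, ...], expected: tuple[int, ...]) -> str:
    """Best-effort reason for a stretch of notes that is not a valid run."""
    n = len(expected)
    if len(segment) == n + 1:
        for drop in range(len(segment)):
            if segment[:drop] + segment[drop + 1 :] == expected:
                return "surplus note"
    if len(segment) == n - 1:
        for drop in range(n):
            if expected[:drop] + expected[drop + 1 :] == segment:
                return "missing note"
    if len(segment) == n:
        return "wrong pitch"
    if len(segment) < n:
        return "incomplete run"
    return "wrong pitch"


def segment_runs(
    events: list[NoteEvent],
    spec: ScaleSpec,
    hand: str,
    direction: str,
) -> tuple[list[ScaleRun], list[Rejection]]:
    """Scan a note stream for correctly performed scale runs.

    A run is accepted where a window of ``spec.n_notes`` consecutive events
    exactly reproduces the expected pitch sequence for the hand/direction.
    Matches never overlap.  A window whose neighbour repeats the run's first
    or last pitch is rejected as containing a surplus note: a doubled
    boundary keystroke means the run was not cleanly performed.  Stretches
    between accepted runs are logged as rejected candidates with a reason
    (wrong pitch / surplus note / missing note / incomplete run).
    """
    expected = expected_pitch_sequence(spec, hand, direction)
    n = len(expected)
    pitches = tuple(e.pitch for e in events)
    runs: list[ScaleRun] = []
    rejections: list[Rejection] = []

    def flush(start: int, stop: int) -> None:
        if stop > start:
            reason = _classify_rejection(pitches[start:stop], expected)
            rejections.append(Rejection(start, stop - start, reason))
            log.info("rejected %d note(s) at %d: %s", stop - start, start, reason)

    i = 0
    seg_start = 0
    while i + n <= len(events):
        if pitches[i : i + n] != expected:
            i += 1
            continue
        if i > 0 and pitches[i - 1] == expected[0]:
            # doubled starting keystroke: the candidate was not cleanly begun
            flush(seg_start, i - 1)
            rejections.append(Rejection(i - 1, n + 1, "surplus note"))
            log.info("rejected candidate at %d: surplus (doubled) starting note", i - 1)
            i += n
            seg_start = i
            continue
        if i + n < len(pitches) and pitches[i + n] == expected[-1]:
            flush(seg_start, i)
            rejections.append(Rejection(i, n + 1, "surplus note"))
            log.info("rejected candidate at %d: surplus (doubled) final note", i)
            i += n + 1
            seg_start = i
            continue
        flush(seg_start, i)
        runs.append(
            ScaleRun(notes=tuple(events[i : i + n]), hand=hand, direction=direction, spec=spec)
        )
        i += n
        seg_start = i
    flush(seg_start, len(events))
    return runs, rejections


def extract_valid_runs(
    events: list[NoteEvent],
    spec: ScaleSpec | None = None,
    hand: str = "right",
    direction: str = "outward",
    session: str = "",
) -> list[ScaleRun]:
    """Return the correctly performed scale runs in an onset-sorted stream.

    Invalid candidates (wrong pitch, surplus note) are rejected and logged,
    never fatal.
    """
    spec = spec or ScaleSpec()
    if any(b.onset < a.onset for a, b in zip(events, events[1:])):
        raise DomainError("events must be sorted by onset")
    runs, _ = segment_runs(events, spec, hand, direction)
    if session:
        runs = [
            ScaleRun(notes=r.notes, hand=r.hand, direction=r.direction, session=session, spec=spec)
            for r in runs
        ]
    return runs
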