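"""Rendering deviation traces to stimulus MIDI and the recognition set.

A stimulus scale is rendered on the nominal 125 ms grid (eight notes per
second at 120 BPM) with each note shifted by its trace deviation multiplied
by a magnification factor: factor 0 is perfectly isochronous, factor 1 the
scale as actually played, factor 5 exaggerates every deviation fivefold while
keeping the overall tempo intact.  Two high-pitched metronome clicks (MIDI
note 96, 500 ms apart) precede each scale as a tempo reference; all notes
have a fixed 137.5 ms duration and fixed velocity, which removes loudness and
articulation cues.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .fingerprint import DeviationTrace, N_NOTES
from .ingest import DomainError, ScaleSpec, expected_pitch_sequence
from .smf import RawNote, write_smf

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class StimulusSpec:
    """Rendering parameters for one stimulus scale (optionally one of a pair)."""

    trace: DeviationTrace
    factor: float = 1.0
    tempo_bpm: float = 120.0
    notes_per_beat: int = 4
    note_duration: float = 137.5
    metronome_pitch: int = 96
    n_metronome: int = 2
    velocity: int = 64
    pair_gap: float = 3500.0  # onset-to-onset gap between the two scales of a pair
    scale: ScaleSpec = field(default_factory=ScaleSpec)

    def __post_init__(self) -> None:
        if self.factor < 0:
            raise DomainError("magnification factor must be non-negative")
        if self.note_duration <= 0:
            raise DomainError("note duration must be positive")

    @property
    def ioi(self) -> float:
        """Nominal inter-onset interval, 125 ms at the default tempo."""
        return 60_000.0 / (self.tempo_bpm * self.notes_per_beat)

    @property
    def click_interval(self) -> float:
        """Metronome click spacing: one beat, 500 ms at 120 BPM."""
        return 60_000.0 / self.tempo_bpm


def magnify_trace(trace: DeviationTrace, factor: float) -> DeviationTrace:
    """Scale every deviation by ``factor`` (0 = isochronous, 1 = veridical)."""
    if factor < 0:
        raise DomainError("magnification factor must be non-negative")
    return replace(trace, values=tuple(factor * v for v in trace.values))


def _scale_notes(spec: StimulusSpec, trace: DeviationTrace, start_ms: float) -> list[RawNote]:
    """Clicks plus the 15 scale notes for one scale starting at ``start_ms``."""
    notes: list[RawNote] = []
    click = spec.click_interval
    lead_in = spec.n_metronome * click  # first scale note continues the click pulse
    for i in range(spec.n_metronome):
        t = start_ms + i * click
        notes.append(
            RawNote(pitch=spec.metronome_pitch, onset_ms=t, offset_ms=t + spec.note_duration,
                    velocity=spec.velocity)
        )
    pitches = expected_pitch_sequence(spec.scale, trace.hand, trace.direction)
    dev = spec.factor * trace.as_array()
    onsets = start_ms + lead_in + np.arange(N_NOTES) * spec.ioi + dev
    if np.any(np.diff(onsets) <= 0):
        log.warning("magnified deviations make onsets non-monotonic; rendering as specified")
    for pitch, onset in zip(pitches, onsets):
        notes.append(
            RawNote(pitch=pitch, onset_ms=float(onset), offset_ms=float(onset) + spec.note_duration,
                    velocity=spec.velocity)
        )
    return notes


def render_stimulus(
    spec: StimulusSpec,
    second_trace: DeviationTrace | None = None,
    path: str | None = None,
) -> bytes:
    """Render one scale (or a pair) to a format-0 SMF; returns the bytes.

    The first scale's first note lands one click interval after the last
    metronome click.  If ``second_trace`` is given, the second scale's first
    note starts ``pair_gap`` ms (3.5 s) after the first scale's first note,
    again preceded by its own two clicks, and is magnified by the same
    factor.
    """
    notes = _scale_notes(spec, spec.trace, start_ms=0.0)
    if second_trace is not None:
        # both scales carry the same lead-in, so shifting the second scale's
        # click block by pair_gap puts its first note pair_gap after the first
        notes += _scale_notes(spec, second_trace, start_ms=spec.pair_gap)
    tempo_us = round(60_000_000 / spec.tempo_bpm)
    return write_smf(notes, path, tempo_us=tempo_us)


@dataclass(frozen=True)
class ScalePair:
    """One row of the recognition-stimulus table: two traces and the truth."""

    label: str
    first: DeviationTrace
    followup: DeviationTrace
    truth: str  # "self" or "other"

    def __post_init__(self) -> None:
        if self.truth not in ("self", "other"):
            raise DomainError(f"truth must be self/other, got {self.truth!r}")


@dataclass(frozen=True)
class Trial:
    """One recognition trial: which pair, magnification, order, and block."""

    block: int
    index: int  # position within the full 144-trial sequence
    pair: str
    factor: float
    order: str  # "first-followup" or "followup-first"
    truth: str


def build_recognition_set(
    pairs: list[ScalePair],
    seed: int | np.random.Generator = 0,
    factors: tuple[float, float] = (1.0, 5.0),
    repeats: int = 6,
    block_size: int = 36,
) -> list[Trial]:
    """The 144-trial recognition sequence: 6 pairs x 2 factors x 2 orders x 6.

    The 24 distinct stimuli are each repeated ``repeats`` times, shuffled by
    ``seed``, and partitioned into blocks of ``block_size`` (4 blocks of 36).
    """
    if len(pairs) != 6:
        raise DomainError(f"the recognition set takes exactly 6 pairs, got {len(pairs)}")
    distinct = [
        (p.label, factor, order, p.truth)
        for p in pairs
        for factor in factors
        for order in ("first-followup", "followup-first")
    ]
    sequence = distinct * repeats
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm = rng.permutation(len(sequence))
    n_total = len(sequence)
    if n_total % block_size:
        raise DomainError(f"{n_total} trials do not divide into blocks of {block_size}")
    trials = []
    for idx, j in enumerate(perm):
        label, factor, order, truth = sequence[j]
        trials.append(
            Trial(block=idx // block_size, index=idx, pair=label, factor=factor,
                  order=order, truth=truth)
        )
    return trials


def trace_unevenness(trace: DeviationTrace, base_ioi: float = 125.0) -> float:
    """Unevenness (sample SD of the 14 IKIs) of the scale a trace renders.

    The nominal grid contributes a constant to every interval, so this equals
    the SD of the successive differences of the deviations alone.
    """
    onsets = np.arange(N_NOTES) * base_ioi + trace.as_array()
    return float(np.std(np.diff(onsets), ddof=1))


def factor_to_unevenness(factor: float, base_trace: DeviationTrace, base_ioi: float = 125.0) -> float:
    """Unevenness (ms) of ``base_trace`` magnified by ``factor``.

    Linear in the factor: the value at factor f is f times the value at
    factor 1, because magnification scales every IKI deviation equally.
    """
    if factor < 0:
        raise DomainError("magnification factor must be non-negative")
    return trace_unevenness(magnify_trace(base_trace, factor), base_ioi)
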