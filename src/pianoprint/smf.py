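"""Minimal Standard MIDI File (SMF) reader/writer.

Supports format 0 and 1 files with PPQ (ticks-per-quarter-note) time
division.  The reader honors every ``set_tempo`` meta event when converting
ticks to milliseconds; the writer emits a single-track format-0 file with one
tempo event at time zero, which is all the stimulus renderer needs.

Only note on/off and tempo events are interpreted; everything else is parsed
(so running status and variable-length quantities stay in sync) and skipped.
"""

from __future__ import annotations

import logging
import struct
from dataclasses import dataclass
from typing import BinaryIO

log = logging.getLogger(__name__)

DEFAULT_TEMPO_US = 500_000  # microseconds per quarter note (120 BPM)
DEFAULT_PPQ = 480


class SMFError(ValueError):
    """Raised for files that cannot be parsed as SMF format 0/1."""


@dataclass(frozen=True)
class RawNote:
    """A matched note-on/note-off pair with times already in ms."""

    pitch: int
    onset_ms: float
    offset_ms: float
    velocity: int = 64
    channel: int = 0


# ---------------------------------------------------------------------------
# reading


def _read_varlen(data: bytes, pos: int) -> tuple[int, int]:
    value = 0
    for _ in range(4):
        if pos >= len(data):
            raise SMFError("truncated variable-length quantity")
        byte = data[pos]
        pos += 1
        value = (value << 7) | (byte & 0x7F)
        if not byte & 0x80:
            return value, pos
    raise SMFError("variable-length quantity longer than 4 bytes")


def _parse_track(data: bytes) -> tuple[list[tuple[int, int, int, int, int]], list[tuple[int, int]]]:
    """Return (note events, tempo events) from one MTrk chunk body.

    Note events are (abs_tick, kind, channel, pitch, velocity) with kind 1 for
    note-on and 0 for note-off; tempo events are (abs_tick, us_per_beat).
    """
    events: list[tuple[int, int, int, int, int]] = []
    tempi: list[tuple[int, int]] = []
    pos = 0
    tick = 0
    status = 0
    while pos < len(data):
        delta, pos = _read_varlen(data, pos)
        tick += delta
        if pos >= len(data):
            raise SMFError("truncated track")
        byte = data[pos]
        if byte & 0x80:
            status = byte
            pos += 1
        elif status == 0:
            raise SMFError("data byte with no running status")
        kind = status & 0xF0
        channel = status & 0x0F
        if kind in (0x80, 0x90):
            pitch, vel = data[pos], data[pos + 1]
            pos += 2
            on = 1 if (kind == 0x90 and vel > 0) else 0
            events.append((tick, on, channel, pitch, vel))
        elif kind in (0xA0, 0xB0, 0xE0):
            pos += 2
        elif kind in (0xC0, 0xD0):
            pos += 1
        elif status == 0xFF:
            meta = data[pos]
            pos += 1
            length, pos = _read_varlen(data, pos)
            payload = data[pos : pos + length]
            pos += length
            if meta == 0x51:
                if length != 3:
                    raise SMFError("malformed set_tempo event")
                tempi.append((tick, int.from_bytes(payload, "big")))
            elif meta == 0x2F:
                break
            status = 0  # meta events cancel running status
        elif status in (0xF0, 0xF7):
            length, pos = _read_varlen(data, pos)
            pos += length
            status = 0
        else:
            raise SMFError(f"unhandled status byte 0x{status:02x}")
    return events, tempi


class _TempoMap:
    """Piecewise-constant tempo map: absolute tick -> absolute ms."""

    def __init__(self, tempi: list[tuple[int, int]], ppq: int):
        tempi = sorted(tempi)
        if not tempi or tempi[0][0] > 0:
            tempi = [(0, DEFAULT_TEMPO_US)] + tempi
        self._ticks = [t for t, _ in tempi]
        self._us = [u for _, u in tempi]
        self._ms_at: list[float] = [0.0]
        for i in range(1, len(self._ticks)):
            span = self._ticks[i] - self._ticks[i - 1]
            self._ms_at.append(self._ms_at[-1] + span * self._us[i - 1] / (ppq * 1000.0))
        self._ppq = ppq

    def to_ms(self, tick: int) -> float:
        # linear scan is fine: real files carry a handful of tempo events
        i = 0
        for j, t in enumerate(self._ticks):
            if t <= tick:
                i = j
            else:
                break
        return self._ms_at[i] + (tick - self._ticks[i]) * self._us[i] / (self._ppq * 1000.0)


def read_smf(source: str | bytes | BinaryIO) -> list[RawNote]:
    """Parse an SMF format 0/1 file into matched notes with ms times.

    ``source`` may be a path, raw bytes, or a binary file object.  Note-ons
    are matched to the next note-off of the same (channel, pitch); a note-on
    left dangling at end of file is dropped with a warning.
    """
    if isinstance(source, bytes):
        data = source
    elif isinstance(source, str):
        with open(source, "rb") as fh:
            data = fh.read()
    else:
        data = source.read()

    if len(data) < 14 or data[:4] != b"MThd":
        raise SMFError("not a Standard MIDI File (missing MThd)")
    hlen, fmt, ntrks, division = struct.unpack(">IHHH", data[4:14])
    if hlen < 6:
        raise SMFError("malformed header chunk")
    if fmt not in (0, 1):
        raise SMFError(f"unsupported SMF format {fmt}")
    if division & 0x8000:
        raise SMFError("SMPTE time division is not supported")
    ppq = division

    pos = 8 + hlen
    all_events: list[tuple[int, int, int, int, int]] = []
    all_tempi: list[tuple[int, int]] = []
    tracks_seen = 0
    while pos + 8 <= len(data) and tracks_seen < ntrks:
        chunk_id = data[pos : pos + 4]
        (clen,) = struct.unpack(">I", data[pos + 4 : pos + 8])
        body = data[pos + 8 : pos + 8 + clen]
        pos += 8 + clen
        if chunk_id != b"MTrk":
            continue  # alien chunks are skipped per the SMF spec
        tracks_seen += 1
        events, tempi = _parse_track(body)
        all_events.extend(events)
        all_tempi.extend(tempi)  # format 1: tempo map lives in track 0 but applies globally

    tmap = _TempoMap(all_tempi, ppq)
    # stable sort: note-offs before note-ons at the same tick so re-struck
    # pitches pair correctly
    all_events.sort(key=lambda e: (e[0], e[1]))

    notes: list[RawNote] = []
    open_notes: dict[tuple[int, int], tuple[int, int]] = {}
    for tick, on, channel, pitch, vel in all_events:
        key = (channel, pitch)
        if on:
            if key in open_notes:
                log.warning("note-on for already-sounding pitch %d; dropping earlier one", pitch)
            open_notes[key] = (tick, vel)
        else:
            if key not in open_notes:
                continue  # stray note-off
            on_tick, on_vel = open_notes.pop(key)
            notes.append(
                RawNote(
                    pitch=pitch,
                    onset_ms=tmap.to_ms(on_tick),
                    offset_ms=tmap.to_ms(tick),
                    velocity=on_vel,
                    channel=channel,
                )
            )
    for (channel, pitch), (on_tick, _) in open_notes.items():
        log.warning("dangling note-on (pitch %d, tick %d) dropped", pitch, on_tick)
    notes.sort(key=lambda n: (n.onset_ms, n.pitch))
    return notes


# ---------------------------------------------------------------------------
# writing


def _varlen(value: int) -> bytes:
    if value < 0:
        raise ValueError("negative delta time")
    out = [value & 0x7F]
    value >>= 7
    while value:
        out.append(0x80 | (value & 0x7F))
        value >>= 7
    return bytes(reversed(out))


def write_smf(
    notes: list[RawNote],
    path: str | None = None,
    *,
    ppq: int = DEFAULT_PPQ,
    tempo_us: int = DEFAULT_TEMPO_US,
) -> bytes:
    """Serialize notes to a format-0 SMF; returns the bytes, optionally saving.

    Millisecond times are quantized to the tick grid (about 1.04 ms per tick
    at 480 PPQ / 120 BPM), which bounds the round-trip error below 1 ms.
    """
    ms_per_tick = tempo_us / (ppq * 1000.0)
    raw: list[tuple[int, int, int, int, int]] = []
    for n in notes:
        if n.offset_ms <= n.onset_ms:
            raise ValueError("note offset must follow onset")
        on_tick = round(n.onset_ms / ms_per_tick)
        off_tick = max(on_tick + 1, round(n.offset_ms / ms_per_tick))
        raw.append((on_tick, 1, n.channel, n.pitch, n.velocity))
        raw.append((off_tick, 0, n.channel, n.pitch, 0))
    raw.sort(key=lambda e: (e[0], e[1]))

    body = bytearray()
    body += b"\x00\xff\x51\x03" + tempo_us.to_bytes(3, "big")
    prev_tick = 0
    for tick, on, channel, pitch, vel in raw:
        body += _varlen(tick - prev_tick)
        prev_tick = tick
        status = (0x90 if on else 0x80) | channel
        body += bytes((status, pitch, vel))
    body += b"\x00\xff\x2f\x00"

    out = bytearray()
    out += b"MThd" + struct.pack(">IHHH", 6, 0, 1, ppq)
    out += b"MTrk" + struct.pack(">I", len(body)) + bytes(body)
    data = bytes(out)
    if path is not None:
        with open(path, "wb") as fh:
            fh.write(data)
    return data
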