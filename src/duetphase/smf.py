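"""Minimal Standard MIDI File (SMF) reader/writer.

Covers the subset of SMF the pipeline needs: format 0 and 1 files, note-on /
note-off channel events, set-tempo meta events, running status, and variable
length quantities.  Times are converted between seconds and ticks through the
file's tempo map (all tempo events are applied globally, as is conventional
for format-1 files).
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence


class MidiParseError(ValueError):
    """Malformed SMF content; carries the byte offset of the failure."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (byte offset {offset})")
        self.offset = offset


@dataclass(frozen=True)
class NoteEvent:
    """A sounding note extracted from an SMF: onset in seconds."""

    onset_s: float
    pitch: int
    velocity: int


def _read_varlen(data: bytes, pos: int) -> tuple[int, int]:
    value = 0
    for _ in range(4):
        if pos >= len(data):
            raise MidiParseError("truncated variable-length quantity", pos)
        byte = data[pos]
        pos += 1
        value = (value << 7) | (byte & 0x7F)
        if not byte & 0x80:
            return value, pos
    raise MidiParseError("variable-length quantity longer than 4 bytes", pos)


def _encode_varlen(value: int) -> bytes:
    if value < 0:
        raise ValueError("negative delta time")
    chunks = [value & 0x7F]
    value >>= 7
    while value:
        chunks.append((value & 0x7F) | 0x80)
        value >>= 7
    return bytes(reversed(chunks))


def _parse_track(data: bytes, start: int, length: int):
    """Yield (tick, kind, payload) from one MTrk chunk.

    kind is "on", "off" or "tempo"; payload is (pitch, velocity) or
    microseconds-per-quarter.  Running status is honoured.
    """
    pos = start
    end = start + length
    tick = 0
    status = None
    while pos < end:
        delta, pos = _read_varlen(data, pos)
        tick += delta
        if pos >= end:
            raise MidiParseError("event truncated", pos)
        byte = data[pos]
        if byte >= 0x80:
            status = byte
            pos += 1
        elif status is None:
            raise MidiParseError("running status without prior status byte", pos)
        if status == 0xFF:  # meta
            if pos + 1 > end:
                raise MidiParseError("meta event truncated", pos)
            meta_type = data[pos]
            pos += 1
            meta_len, pos = _read_varlen(data, pos)
            if pos + meta_len > end:
                raise MidiParseError("meta payload truncated", pos)
            payload = data[pos : pos + meta_len]
            pos += meta_len
            if meta_type == 0x51:
                if meta_len != 3:
                    raise MidiParseError("set-tempo meta must be 3 bytes", pos)
                yield tick, "tempo", int.from_bytes(payload, "big")
            elif meta_type == 0x2F:
                return
        elif status in (0xF0, 0xF7):  # sysex
            sys_len, pos = _read_varlen(data, pos)
            pos += sys_len
        else:
            kind = status & 0xF0
            n_data = 1 if kind in (0xC0, 0xD0) else 2
            if pos + n_data > end:
                raise MidiParseError("channel event truncated", pos)
            d = data[pos : pos + n_data]
            pos += n_data
            if kind == 0x90:
                yield tick, ("on" if d[1] > 0 else "off"), (d[0], d[1])
            elif kind == 0x80:
                yield tick, "off", (d[0], d[1])


def read_notes(path: str | Path) -> list[NoteEvent]:
    """Parse an SMF (format 0 or 1) into note onsets in absolute seconds.

    Note-on events with velocity 0 follow the common dialect and count as
    note-offs, not onsets.  Tempo meta events from all tracks form one global
    tempo map; the default 120 quarter-notes/min applies before the first.
    """
    data = Path(path).read_bytes()
    if len(data) < 14 or data[:4] != b"MThd":
        raise MidiParseError("missing MThd header", 0)
    header_len = struct.unpack(">I", data[4:8])[0]
    fmt, n_tracks, division = struct.unpack(">HHH", data[8:14])
    if fmt not in (0, 1):
        raise MidiParseError(f"unsupported SMF format {fmt}", 8)
    if division & 0x8000:
        raise MidiParseError("SMPTE time division not supported", 12)
    tpq = division
    pos = 8 + header_len

    tempo_events: list[tuple[int, int]] = []
    note_ons: list[tuple[int, int, int]] = []
    for _ in range(n_tracks):
        if pos + 8 > len(data):
            raise MidiParseError("truncated track header", pos)
        if data[pos : pos + 4] != b"MTrk":
            raise MidiParseError("expected MTrk chunk", pos)
        track_len = struct.unpack(">I", data[pos + 4 : pos + 8])[0]
        for tick, kind, payload in _parse_track(data, pos + 8, track_len):
            if kind == "tempo":
                tempo_events.append((tick, payload))
            elif kind == "on":
                note_ons.append((tick, payload[0], payload[1]))
        pos += 8 + track_len

    tempo_events.sort()
    note_ons.sort()

    # piecewise-constant tempo map: tick -> seconds
    def tick_to_seconds(tick: int) -> float:
        seconds = 0.0
        last_tick = 0
        us_per_q = 500_000
        for ev_tick, ev_us in tempo_events:
            if ev_tick >= tick:
                break
            seconds += (ev_tick - last_tick) * us_per_q / (tpq * 1e6)
            last_tick = ev_tick
            us_per_q = ev_us
        seconds += (tick - last_tick) * us_per_q / (tpq * 1e6)
        return seconds

    return [NoteEvent(tick_to_seconds(t), p, v) for t, p, v in note_ons]


def write_notes(
    path: str | Path,
    onsets_s: Sequence[float],
    pitches: Sequence[int],
    velocities: Sequence[int],
    *,
    us_per_quarter: int = 500_000,
    ticks_per_quarter: int = 480,
    note_duration_s: float = 0.08,
) -> None:
    """Write onsets as a format-1 SMF: tempo track plus one note track."""
    if not (len(onsets_s) == len(pitches) == len(velocities)):
        raise ValueError("onsets, pitches and velocities must have equal length")

    def to_tick(t: float) -> int:
        return round(t * ticks_per_quarter * 1e6 / us_per_quarter)

    tempo_track = (
        b"\x00\xff\x51\x03"
        + us_per_quarter.to_bytes(3, "big")
        + b"\x00\xff\x2f\x00"
    )

    events: list[tuple[int, int, bytes]] = []  # (tick, order, message)
    for t, pitch, vel in zip(onsets_s, pitches, velocities):
        on_tick = to_tick(t)
        off_tick = max(on_tick + 1, to_tick(t + note_duration_s))
        events.append((on_tick, 1, bytes([0x90, pitch & 0x7F, max(1, min(127, vel))])))
        events.append((off_tick, 0, bytes([0x80, pitch & 0x7F, 0])))
    events.sort(key=lambda e: (e[0], e[1]))

    note_track = bytearray()
    last_tick = 0
    for tick, _, msg in events:
        note_track += _encode_varlen(tick - last_tick) + msg
        last_tick = tick
    note_track += b"\x00\xff\x2f\x00"

    def chunk(tag: bytes, body: bytes) -> bytes:
        return tag + struct.pack(">I", len(body)) + body

    header = struct.pack(">HHH", 1, 2, ticks_per_quarter)
    out = chunk(b"MThd", header) + chunk(b"MTrk", tempo_track) + chunk(
        b"MTrk", bytes(note_track)
    )
    try:
        Path(path).write_bytes(out)
    except OSError as exc:
        raise OSError(f"cannot write MIDI file {path}: {exc}") from exc
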