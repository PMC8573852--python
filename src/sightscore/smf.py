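"""Minimal Standard MIDI File (SMF) codec.

Supports what performance recordings of this kind need: format 0/1 files,
note-on/note-off events with running status, set-tempo meta events, and
tick -> millisecond conversion through the file's tempo map.  Everything
else (controllers, sysex, other meta events) is parsed and skipped.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field

__all__ = ["SmfNote", "read_smf", "write_smf"]

_DEFAULT_TEMPO_US = 500000  # microseconds per quarter note (120 bpm)


@dataclass
class SmfNote:
    onset_ms: float
    pitch: int
    duration_ms: float
    velocity: int = 64


@dataclass
class _Parser:
    data: bytes
    pos: int = 0

    def u8(self) -> int:
        b = self.data[self.pos]
        self.pos += 1
        return b

    def take(self, n: int) -> bytes:
        chunk = self.data[self.pos : self.pos + n]
        if len(chunk) < n:
            raise ValueError(f"truncated MIDI data at byte {self.pos}")
        self.pos += n
        return chunk

    def vlq(self) -> int:
        """Variable-length quantity."""
        value = 0
        for _ in range(4):
            b = self.u8()
            value = (value << 7) | (b & 0x7F)
            if not b & 0x80:
                return value
        raise ValueError(f"malformed variable-length quantity at byte {self.pos}")


def _parse_track(data: bytes) -> list[tuple[int, int, int, int]]:
    """Raw events as (abs_tick, status, data1, data2); meta tempo as status 0xFF51."""
    p = _Parser(data)
    events = []
    tick = 0
    status = 0
    while p.pos < len(data):
        tick += p.vlq()
        b = p.u8()
        if b == 0xFF:  # meta
            meta_type = p.u8()
            length = p.vlq()
            payload = p.take(length)
            if meta_type == 0x51 and length == 3:
                tempo = (payload[0] << 16) | (payload[1] << 8) | payload[2]
                events.append((tick, 0xFF51, tempo, 0))
            elif meta_type == 0x2F:
                break
            continue
        if b in (0xF0, 0xF7):  # sysex
            p.take(p.vlq())
            continue
        if b & 0x80:
            status = b
            d1 = p.u8()
        else:  # running status
            if not status:
                raise ValueError(f"data byte without status at byte {p.pos - 1}")
            d1 = b
        kind = status & 0xF0
        d2 = p.u8() if kind not in (0xC0, 0xD0) else 0
        if kind in (0x80, 0x90):
            events.append((tick, status, d1, d2))
    return events


def read_smf(path) -> tuple[list[SmfNote], float]:
    """Read an SMF; return (notes with ms times via the tempo map, ppq).

    Overlapping note-ons on the same pitch close the earlier note at the
    later onset.  A note-on left open at end of track is closed at the last
    event tick.
    """
    import warnings

    with open(path, "rb") as fh:
        data = fh.read()
    if data[:4] != b"MThd":
        raise ValueError(f"{path}: not a Standard MIDI File (bad header at byte 0)")
    hlen, fmt, ntracks, division = struct.unpack(">IHHH", data[4:14])
    if division & 0x8000:
        raise ValueError(f"{path}: SMPTE time division is not supported")
    ppq = division

    pos = 8 + hlen
    events: list[tuple[int, int, int, int]] = []
    for _ in range(ntracks):
        if data[pos : pos + 4] != b"MTrk":
            raise ValueError(f"{path}: expected MTrk chunk at byte {pos}")
        (tlen,) = struct.unpack(">I", data[pos + 4 : pos + 8])
        events.extend(_parse_track(data[pos + 8 : pos + 8 + tlen]))
        pos += 8 + tlen
    events.sort(key=lambda e: e[0])

    # Tempo map: piecewise-linear tick -> ms.
    tempo_changes = [(0, _DEFAULT_TEMPO_US)]
    for tick, status, d1, _ in events:
        if status == 0xFF51:
            tempo_changes.append((tick, d1))

    def tick_to_ms(tick: int) -> float:
        ms = 0.0
        prev_tick, tempo = tempo_changes[0]
        for t, new_tempo in tempo_changes[1:]:
            if t >= tick:
                break
            ms += (t - prev_tick) * tempo / (ppq * 1000.0)
            prev_tick, tempo = t, new_tempo
        return ms + (tick - prev_tick) * tempo / (ppq * 1000.0)

    notes: list[SmfNote] = []
    open_notes: dict[int, tuple[int, int]] = {}  # pitch -> (tick, velocity)
    last_tick = events[-1][0] if events else 0
    for tick, status, pitch, vel in events:
        kind = status & 0xF0
        if kind == 0x90 and vel > 0:
            if pitch in open_notes:
                warnings.warn(
                    f"overlapping note-on for pitch {pitch}; closing earlier note",
                    stacklevel=2,
                )
                _close(notes, open_notes, pitch, tick, tick_to_ms)
            open_notes[pitch] = (tick, vel)
        elif kind == 0x80 or (kind == 0x90 and vel == 0):
            if pitch in open_notes:
                _close(notes, open_notes, pitch, tick, tick_to_ms)
    for pitch in list(open_notes):
        warnings.warn(f"note-on without note-off for pitch {pitch}", stacklevel=2)
        _close(notes, open_notes, pitch, last_tick, tick_to_ms)
    notes.sort(key=lambda n: (n.onset_ms, n.pitch))
    return notes, float(ppq)


def _close(notes, open_notes, pitch, end_tick, tick_to_ms) -> None:
    on_tick, vel = open_notes.pop(pitch)
    onset = tick_to_ms(on_tick)
    dur = tick_to_ms(end_tick) - onset
    notes.append(SmfNote(onset, pitch, max(dur, 1e-6), vel))


def _vlq_bytes(value: int) -> bytes:
    out = [value & 0x7F]
    value >>= 7
    while value:
        out.append(0x80 | (value & 0x7F))
        value >>= 7
    return bytes(reversed(out))


def write_smf(path, notes: list[SmfNote], tempo_bpm: float, ppq: int = 480) -> None:
    """Write a format-0 SMF with a single set-tempo event at tick 0."""
    tempo_us = round(60_000_000 / tempo_bpm)
    ms_per_tick = tempo_us / (ppq * 1000.0)

    msgs: list[tuple[int, bytes]] = [(0, bytes([0xFF, 0x51, 0x03]) + tempo_us.to_bytes(3, "big"))]
    for n in notes:
        on = round(n.onset_ms / ms_per_tick)
        off = round((n.onset_ms + n.duration_ms) / ms_per_tick)
        off = max(off, on + 1)
        msgs.append((on, bytes([0x90, n.pitch, max(1, min(127, int(n.velocity)))])))
        msgs.append((off, bytes([0x80, n.pitch, 0])))
    msgs.sort(key=lambda m: (m[0], m[1][0] != 0xFF, m[1][0] == 0x90))

    track = bytearray()
    prev = 0
    for tick, payload in msgs:
        track += _vlq_bytes(tick - prev) + payload
        prev = tick
    track += _vlq_bytes(0) + bytes([0xFF, 0x2F, 0x00])

    with open(path, "wb") as fh:
        fh.write(b"MThd" + struct.pack(">IHHH", 6, 0, 1, ppq))
        fh.write(b"MTrk" + struct.pack(">I", len(track)) + bytes(track))
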