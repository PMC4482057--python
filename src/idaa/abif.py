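"""Reading and writing ABIF (.fsa) fragment-analysis trace containers.

ABIF is the big-endian tagged binary container produced by Applied
Biosystems capillary electrophoresis instruments.  A file starts with the
4-byte magic ``ABIF`` and a version word, followed by a single directory
pointer entry; the directory itself is a table of 28-byte records, one per
tag, each naming a 4-character tag, a tag number, an element type, and the
location of its payload (payloads of four bytes or fewer are stored inline
in the offset field).

Only the tag subset relevant to fragment analysis is interpreted:

* ``DATA1``–``DATA4`` and ``DATA105`` — raw per-scan fluorescence of the
  dye channels (16-bit signed integers);
* ``DyeN1``–``DyeN5`` — dye names;
* ``SMPL1`` — sample name;
* everything else is retained as opaque metadata so traces survive a
  read/write round trip.

The writer emits minimal, valid version-101 files (header, payload,
directory last) that are readable both by :func:`read_abif` and by
third-party ABIF readers.
"""

from __future__ import annotations

import struct
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import AbifCorruptionError, AbifFormatError, IntensityRangeError, ParameterError

MAGIC = b"ABIF"
VERSION = 101
HEADER_SIZE = 128
DIR_ENTRY = struct.Struct(">4sihhiiii")  # name, number, type, size, count, datasize, offset, handle

# ABIF element type codes
_TYPE_BYTE = 1
_TYPE_CHAR = 2
_TYPE_SHORT = 4
_TYPE_LONG = 5
_TYPE_PSTRING = 18
_TYPE_CSTRING = 19

_ELEM_SIZE = {_TYPE_BYTE: 1, _TYPE_CHAR: 1, _TYPE_SHORT: 2, _TYPE_LONG: 4,
              _TYPE_PSTRING: 1, _TYPE_CSTRING: 1}

#: DATA tag numbers holding raw channel signal, in channel order.
CHANNEL_DATA_TAGS = (1, 2, 3, 4, 105)

INT16_MIN, INT16_MAX = -32768, 32767


@dataclass
class Channel:
    """One dye channel: a name and one intensity per scan."""

    dye_name: str
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.int32)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Channel):
            return NotImplemented
        return self.dye_name == other.dye_name and np.array_equal(self.intensities, other.intensities)


@dataclass
class Trace:
    """A multi-channel electropherogram with instrument metadata.

    Invariants: every channel has ``scan_count`` intensities, intensities fit
    in a signed 16-bit word, and dye names are unique.
    """

    sample_name: str = ""
    channels: list[Channel] = field(default_factory=list)
    metadata: dict[str, object] = field(default_factory=dict)

    @property
    def scan_count(self) -> int:
        return len(self.channels[0].intensities) if self.channels else 0

    def validate(self) -> None:
        n = self.scan_count
        names = [c.dye_name for c in self.channels]
        if len(set(names)) != len(names):
            raise ParameterError(f"duplicate dye names in trace: {names}")
        for c in self.channels:
            if len(c.intensities) != n:
                raise ParameterError("channels differ in length")
            if c.intensities.size and (
                c.intensities.min() < INT16_MIN or c.intensities.max() > INT16_MAX
            ):
                raise IntensityRangeError(
                    f"channel {c.dye_name!r} intensities exceed signed 16-bit range"
                )

    def channel_by_dye(self, fragment: str) -> int:
        """Index of the first channel whose dye name contains *fragment* (case-insensitive)."""
        frag = fragment.upper()
        for i, c in enumerate(self.channels):
            if frag in c.dye_name.upper():
                return i
        raise ParameterError(
            f"no channel with dye matching {fragment!r}; dyes present: "
            f"{[c.dye_name for c in self.channels]}"
        )


def _decode(name: str, number: int, etype: int, count: int, raw: bytes) -> object:
    if etype == _TYPE_BYTE:
        return raw
    if etype == _TYPE_CHAR:
        return raw.decode("latin-1")
    if etype == _TYPE_SHORT:
        vals = struct.unpack(f">{count}h", raw)
        return vals[0] if count == 1 else tuple(vals)
    if etype == _TYPE_LONG:
        vals = struct.unpack(f">{count}i", raw)
        return vals[0] if count == 1 else tuple(vals)
    if etype == _TYPE_PSTRING:
        return raw[1 : 1 + raw[0]].decode("latin-1") if raw else ""
    if etype == _TYPE_CSTRING:
        return raw.rstrip(b"\x00").decode("latin-1")
    warnings.warn(
        f"ABIF tag {name}{number}: element type {etype} not interpreted; kept as raw bytes",
        stacklevel=3,
    )
    return raw


def _read_entries(buf: bytes, path: str) -> list[tuple[str, int, int, int, int, bytes]]:
    """Parse header + directory; return (name, number, etype, count, datasize, raw)."""
    if len(buf) < 6 or buf[:4] != MAGIC:
        raise AbifFormatError(f"{path}: missing ABIF magic signature")
    if len(buf) < 6 + DIR_ENTRY.size:
        raise AbifCorruptionError(f"{path}: truncated header (no tdir entry)")
    _, _, _, _, n_entries, dir_size, dir_off, _ = DIR_ENTRY.unpack_from(buf, 6)
    if dir_off + n_entries * DIR_ENTRY.size > len(buf):
        raise AbifCorruptionError(f"{path}: directory truncated (tag tdir)")
    out = []
    for i in range(n_entries):
        off = dir_off + i * DIR_ENTRY.size
        name_b, number, etype, esize, count, datasize, data_off, _ = DIR_ENTRY.unpack_from(buf, off)
        name = name_b.decode("latin-1")
        if datasize <= 4:
            raw = buf[off + 20 : off + 24][:datasize]
        else:
            if data_off + datasize > len(buf):
                raise AbifCorruptionError(f"{path}: data block truncated (tag {name}{number})")
            raw = buf[data_off : data_off + datasize]
        out.append((name, number, etype, count, datasize, raw))
    return out


def read_abif(path) -> Trace:
    """Read an ABIF file into a :class:`Trace`.

    All DATA channels present (DATA1–DATA4 and DATA105) are loaded in
    ascending tag-number order; dye names come from the DyeN tags and the
    sample name from SMPL1.  Every other tag is kept in ``metadata``.
    """
    with open(path, "rb") as fh:
        buf = fh.read()
    entries = _read_entries(buf, str(path))

    data: dict[int, np.ndarray] = {}
    dyes: dict[int, str] = {}
    sample_name = ""
    metadata: dict[str, object] = {}
    for name, number, etype, count, datasize, raw in entries:
        if name == "DATA" and number in CHANNEL_DATA_TAGS:
            if etype != _TYPE_SHORT:
                raise AbifCorruptionError(f"DATA{number}: expected short elements, got type {etype}")
            if len(raw) != 2 * count:
                raise AbifCorruptionError(f"DATA{number}: data block truncated")
            data[number] = np.frombuffer(raw, dtype=">i2").astype(np.int32)
        elif name == "DyeN":
            dyes[number] = str(_decode(name, number, etype, count, raw))
        elif name == "SMPL" and number == 1:
            sample_name = str(_decode(name, number, etype, count, raw))
        else:
            metadata[f"{name}{number}"] = _decode(name, number, etype, count, raw)

    channels = []
    for i, tag in enumerate(sorted(data)):
        dye_number = CHANNEL_DATA_TAGS.index(tag) + 1
        channels.append(Channel(dyes.get(dye_number, f"dye{dye_number}"), data[tag]))
        del i
    return Trace(sample_name=sample_name, channels=channels, metadata=metadata)


def list_tags(path) -> list[tuple[str, int, int, int]]:
    """Directory listing: ``(tag_name, tag_number, element_type, element_count)`` per record."""
    with open(path, "rb") as fh:
        buf = fh.read()
    return [(name, number, etype, count)
            for name, number, etype, count, _, _ in _read_entries(buf, str(path))]


def _encode(value: object) -> tuple[int, int, bytes]:
    """Encode a metadata value -> (element_type, count, payload)."""
    if isinstance(value, bytes):
        return _TYPE_BYTE, len(value), value
    if isinstance(value, bool):
        raise ParameterError("boolean metadata not representable in ABIF")
    if isinstance(value, (int, np.integer)):
        return _TYPE_LONG, 1, struct.pack(">i", int(value))
    if isinstance(value, tuple):
        return _TYPE_LONG, len(value), struct.pack(f">{len(value)}i", *value)
    if isinstance(value, str):
        b = value.encode("latin-1")
        if len(b) > 255:
            raise ParameterError("string metadata longer than 255 bytes")
        return _TYPE_PSTRING, len(b) + 1, bytes([len(b)]) + b
    raise ParameterError(f"cannot encode metadata value of type {type(value).__name__}")


def write_abif(trace: Trace, path) -> None:
    """Write *trace* as a minimal valid ABIF file (version 101, directory last)."""
    trace.validate()
    if len(trace.channels) > len(CHANNEL_DATA_TAGS):
        raise ParameterError(f"at most {len(CHANNEL_DATA_TAGS)} channels supported")

    records: list[tuple[bytes, int, int, int, bytes]] = []  # name, number, etype, count, payload
    for i, ch in enumerate(trace.channels):
        payload = ch.intensities.astype(">i2").tobytes()
        records.append((b"DATA", CHANNEL_DATA_TAGS[i], _TYPE_SHORT, len(ch.intensities), payload))
    for i, ch in enumerate(trace.channels):
        etype, count, payload = _encode(ch.dye_name)
        records.append((b"DyeN", i + 1, etype, count, payload))
    if trace.sample_name:
        etype, count, payload = _encode(trace.sample_name)
        records.append((b"SMPL", 1, etype, count, payload))
    for key, value in trace.metadata.items():
        name, number = key[:4].encode("latin-1"), int(key[4:])
        if isinstance(value, bytes):
            etype, count, payload = _TYPE_BYTE, len(value), value
        else:
            etype, count, payload = _encode(value)
        records.append((name, number, etype, count, payload))

    blob = bytearray()
    entries = bytearray()
    offset = HEADER_SIZE
    for name, number, etype, count, payload in records:
        datasize = len(payload)
        if datasize <= 4:
            data_off_bytes = payload.ljust(4, b"\x00")
            entry = DIR_ENTRY.pack(name, number, etype, _ELEM_SIZE.get(etype, 1),
                                   count, datasize, 0, 0)
            # splice inline payload into the offset field (bytes 20..24)
            entry = entry[:20] + data_off_bytes + entry[24:]
        else:
            entry = DIR_ENTRY.pack(name, number, etype, _ELEM_SIZE.get(etype, 1),
                                   count, datasize, offset, 0)
            blob += payload
            offset += datasize
        entries += entry

    dir_offset = HEADER_SIZE + len(blob)
    tdir = DIR_ENTRY.pack(b"tdir", 1, 1023, DIR_ENTRY.size, len(records),
                          len(entries), dir_offset, 0)
    header = MAGIC + struct.pack(">h", VERSION) + tdir
    header = header.ljust(HEADER_SIZE, b"\x00")
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(blob)
        fh.write(entries)
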