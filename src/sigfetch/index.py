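"""Read-ID index: maps every read ID to its byte extent in the container.

The index is the single source of truth for remote access — a client
fetches the header extent and per-read extents it records, and never
scans the remote file.  Layout (FORMAT.md): magic, version, header
extent length, entry count, then packed ``(id_length, id, offset,
length)`` entries in file order, little-endian throughout.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field

from .container import ContainerReader
from .errors import DuplicateReadIdError, FormatError

INDEX_MAGIC = b"SIGFIDX1"
INDEX_VERSION = 1

INDEX_SUFFIX = ".idx"


@dataclass
class ReadIndex:
    """In-memory index: constant-time lookup per read ID, file order kept."""

    header_extent_length: int
    entries: dict[str, tuple[int, int]] = field(default_factory=dict)

    @property
    def header_extent(self) -> tuple[int, int]:
        """(offset, length) of the serialized header — always offset 0."""
        return (0, self.header_extent_length)

    @property
    def n_entries(self) -> int:
        return len(self.entries)

    def lookup(self, read_id: str) -> tuple[int, int] | None:
        """Return ``(byte_offset, byte_length)``, or None if absent.

        Absence is a signal, not an error; the caller decides severity.
        """
        return self.entries.get(read_id)

    def list_read_ids(self) -> list[str]:
        """All read IDs in file order (insertion order of the entries)."""
        return list(self.entries)


def build_index(container_path) -> ReadIndex:
    """Scan a local container and index every record's byte extent."""
    with ContainerReader(container_path) as reader:
        index = ReadIndex(header_extent_length=reader.header_byte_length)
        for offset, length, rec in reader.iter_with_extents():
            if rec.read_id in index.entries:
                raise DuplicateReadIdError(
                    f"duplicate read_id {rec.read_id!r} in container"
                )
            index.entries[rec.read_id] = (offset, length)
    return index


def write_index(index: ReadIndex, destination) -> None:
    with open(destination, "wb") as fh:
        fh.write(INDEX_MAGIC)
        fh.write(struct.pack("<B", INDEX_VERSION))
        fh.write(struct.pack("<Q", index.header_extent_length))
        fh.write(struct.pack("<Q", index.n_entries))
        for read_id, (offset, length) in index.entries.items():
            rid = read_id.encode()
            fh.write(struct.pack("<H", len(rid)))
            fh.write(rid)
            fh.write(struct.pack("<QQ", offset, length))


def load_index(source) -> ReadIndex:
    """Load an index file; O(n) load, constant-time lookups afterwards."""
    if hasattr(source, "read"):
        buf = source.read()
    else:
        with open(source, "rb") as fh:
            buf = fh.read()
    return parse_index(buf)


def parse_index(buf: bytes) -> ReadIndex:
    if len(buf) < 25 or buf[:8] != INDEX_MAGIC:
        raise FormatError("bad magic: not a sigfetch index")
    (version,) = struct.unpack_from("<B", buf, 8)
    if version != INDEX_VERSION:
        raise FormatError(f"unsupported index version {version}")
    header_len, n_entries = struct.unpack_from("<QQ", buf, 9)
    index = ReadIndex(header_extent_length=header_len)
    pos = 25
    for i in range(n_entries):
        if pos + 2 > len(buf):
            raise FormatError(f"truncated index at entry {i}")
        (rid_len,) = struct.unpack_from("<H", buf, pos)
        pos += 2
        if pos + rid_len + 16 > len(buf):
            raise FormatError(f"truncated index at entry {i}")
        read_id = buf[pos : pos + rid_len].decode()
        pos += rid_len
        offset, length = struct.unpack_from("<QQ", buf, pos)
        pos += 16
        index.entries[read_id] = (offset, length)
    if pos != len(buf):
        raise FormatError("trailing bytes after last index entry")
    return index


def default_index_path(container_path: str) -> str:
    """Conventional sidecar location: ``<container>.idx``."""
    return str(container_path) + INDEX_SUFFIX
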