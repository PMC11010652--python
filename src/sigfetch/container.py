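"""Binary signal container: header, per-record encoding, file I/O.

One container file holds a run header (acquisition metadata shared by one
or more read groups plus a schema for typed per-read auxiliary fields)
followed by one framed record per sequenced read.  Records carry the raw
16-bit signal and the per-read scaling needed to convert it to
picoamperes.  Every record is independently decodable from its byte
extent alone — the property that makes remote byte-range access work.

The byte-exact layout is documented in FORMAT.md at the repository root.
All integers are little-endian.
"""

from __future__ import annotations

import enum
import struct
import zlib
from dataclasses import dataclass, field
from typing import BinaryIO, Iterable, Iterator, Sequence

import numpy as np

from .codec import svb_zd_compress, svb_zd_decompress
from .errors import (
    CorruptRecordError,
    DuplicateReadIdError,
    EncodingError,
    FormatError,
)

MAGIC = b"SIGFET01"
EOF_MARKER = 0xFFFFFFFF
FORMAT_VERSION = (1, 0)

_INT16_MIN, _INT16_MAX = -(2**15), 2**15 - 1


class RecordCompression(enum.IntEnum):
    """Whole-record compression applied after field serialization."""

    NONE = 0
    ZLIB = 1


class SignalCompression(enum.IntEnum):
    """Compression of the raw-signal block inside a record."""

    NONE = 0
    SVB_ZD = 1


class AuxType(enum.IntEnum):
    """Type codes for auxiliary per-read fields."""

    INT8 = 0
    INT16 = 1
    INT32 = 2
    INT64 = 3
    UINT8 = 4
    UINT16 = 5
    UINT32 = 6
    UINT64 = 7
    FLOAT32 = 8
    FLOAT64 = 9
    STRING = 10
    ARRAY_INT16 = 11
    ARRAY_FLOAT64 = 12


_SCALAR_FMT = {
    AuxType.INT8: "<b",
    AuxType.INT16: "<h",
    AuxType.INT32: "<i",
    AuxType.INT64: "<q",
    AuxType.UINT8: "<B",
    AuxType.UINT16: "<H",
    AuxType.UINT32: "<I",
    AuxType.UINT64: "<Q",
    AuxType.FLOAT32: "<f",
    AuxType.FLOAT64: "<d",
}


@dataclass
class RunHeader:
    """File-level metadata shared by every record.

    Parameters
    ----------
    version
        Free-form run/software version tag stored in the file.
    num_read_groups
        Number of read groups; every record names its group by index.
    attributes
        One ordered ``{key: value}`` string mapping per read group.
    aux_schema
        Ordered ``(name, AuxType)`` pairs; every record carries exactly
        one value per schema entry, in order.
    record_compression, signal_compression
        The two independently switchable compression layers.
    """

    version: str = "1.0"
    num_read_groups: int = 1
    attributes: list[dict[str, str]] = field(default_factory=lambda: [{}])
    aux_schema: list[tuple[str, AuxType]] = field(default_factory=list)
    record_compression: RecordCompression = RecordCompression.ZLIB
    signal_compression: SignalCompression = SignalCompression.SVB_ZD

    def validate(self) -> None:
        if self.num_read_groups < 1:
            raise EncodingError("num_read_groups must be >= 1")
        if len(self.attributes) != self.num_read_groups:
            raise EncodingError(
                "attributes must hold one mapping per read group "
                f"({len(self.attributes)} maps for {self.num_read_groups} groups)"
            )
        names = [name for name, _ in self.aux_schema]
        if any(not n for n in names):
            raise EncodingError("aux field names must be non-empty")
        if len(set(names)) != len(names):
            raise EncodingError("aux field names must be unique")

    def serialize(self) -> bytes:
        """Serialize to the full on-disk header (magic + length + body)."""
        self.validate()
        out = bytearray()
        out += struct.pack("<BB", *FORMAT_VERSION)
        vtag = self.version.encode()
        out += struct.pack("<H", len(vtag)) + vtag
        out += struct.pack(
            "<BB", int(self.record_compression), int(self.signal_compression)
        )
        out += struct.pack("<I", self.num_read_groups)
        out += struct.pack("<I", len(self.aux_schema))
        for name, code in self.aux_schema:
            nb = name.encode()
            out += struct.pack("<H", len(nb)) + nb + struct.pack("<B", int(code))
        for attrs in self.attributes:
            out += struct.pack("<I", len(attrs))
            for k, v in attrs.items():
                kb, vb = k.encode(), v.encode()
                out += struct.pack("<H", len(kb)) + kb
                out += struct.pack("<I", len(vb)) + vb
        return MAGIC + struct.pack("<Q", len(out)) + bytes(out)

    @property
    def byte_length(self) -> int:
        """Total serialized header length (the header's byte extent)."""
        return len(self.serialize())


def parse_header(buf: bytes) -> RunHeader:
    """Parse a serialized header; ``buf`` must start at byte 0 of the file
    and contain at least the full header extent (trailing bytes ignored)."""
    if len(buf) < 16:
        raise FormatError("file too short for a container header")
    if buf[:8] != MAGIC:
        raise FormatError("bad magic: not a sigfetch container")
    (body_len,) = struct.unpack_from("<Q", buf, 8)
    if len(buf) < 16 + body_len:
        raise FormatError("truncated container header")
    cur = _Cursor(buf[16 : 16 + body_len], what="header")
    major, minor = cur.unpack("<BB", "format version")
    if major != FORMAT_VERSION[0]:
        raise FormatError(f"unsupported container version {major}.{minor}")
    version = cur.take(cur.unpack("<H", "version tag length")[0], "version tag").decode()
    rec_c, sig_c = cur.unpack("<BB", "compression enums")
    try:
        record_compression = RecordCompression(rec_c)
        signal_compression = SignalCompression(sig_c)
    except ValueError as exc:
        raise FormatError(f"unknown compression code: {exc}") from None
    (n_groups,) = cur.unpack("<I", "read group count")
    (n_aux,) = cur.unpack("<I", "aux schema count")
    aux_schema = []
    for _ in range(n_aux):
        (nlen,) = cur.unpack("<H", "aux name length")
        name = cur.take(nlen, "aux name").decode()
        (code,) = cur.unpack("<B", "aux type code")
        try:
            aux_schema.append((name, AuxType(code)))
        except ValueError:
            raise FormatError(f"unknown aux type code {code}") from None
    attributes = []
    for _ in range(n_groups):
        (n_attrs,) = cur.unpack("<I", "attribute count")
        attrs: dict[str, str] = {}
        for _ in range(n_attrs):
            (klen,) = cur.unpack("<H", "attribute key length")
            key = cur.take(klen, "attribute key").decode()
            (vlen,) = cur.unpack("<I", "attribute value length")
            attrs[key] = cur.take(vlen, "attribute value").decode()
        attributes.append(attrs)
    header = RunHeader(
        version=version,
        num_read_groups=n_groups,
        attributes=attributes,
        aux_schema=aux_schema,
        record_compression=record_compression,
        signal_compression=signal_compression,
    )
    header.validate()
    return header


@dataclass
class ReadRecord:
    """One sequenced read: identity, signal scaling, raw signal, aux values.

    ``to_picoamperes`` applies the standard per-read scaling
    ``pA = (sample + offset) * range / digitisation``.
    """

    read_id: str
    read_group: int = 0
    digitisation: float = 8192.0
    offset: float = 0.0
    range: float = 1500.0
    sampling_rate: float = 5000.0
    raw_signal: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int16))
    aux_values: tuple = ()

    def __post_init__(self) -> None:
        self.raw_signal = np.asarray(self.raw_signal, dtype=np.int16)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ReadRecord):
            return NotImplemented
        return (
            self.read_id == other.read_id
            and self.read_group == other.read_group
            and self.digitisation == other.digitisation
            and self.offset == other.offset
            and self.range == other.range
            and self.sampling_rate == other.sampling_rate
            and np.array_equal(self.raw_signal, other.raw_signal)
            and _aux_equal(self.aux_values, other.aux_values)
        )

    @property
    def n_samples(self) -> int:
        return int(self.raw_signal.size)

    def to_picoamperes(self) -> np.ndarray:
        return to_picoamperes(self)


def _aux_equal(a, b) -> bool:
    if len(a) != len(b):
        return False
    for x, y in zip(a, b):
        if isinstance(x, np.ndarray) or isinstance(y, np.ndarray):
            if not np.array_equal(np.asarray(x), np.asarray(y)):
                return False
        elif x != y:
            return False
    return True


def to_picoamperes(record: ReadRecord) -> np.ndarray:
    """Convert raw ADC samples to picoamperes: ``(s + offset) * range / digitisation``."""
    if record.digitisation <= 0:
        raise EncodingError("digitisation must be positive")
    return (
        (record.raw_signal.astype(np.float64) + record.offset)
        * record.range
        / record.digitisation
    )


class _Cursor:
    """Sequential reader over a byte buffer; overruns raise
    :class:`CorruptRecordError` naming the field being read."""

    def __init__(self, buf: bytes, what: str = "record"):
        self.buf = buf
        self.pos = 0
        self.what = what

    def take(self, n: int, fieldname: str) -> bytes:
        if self.pos + n > len(self.buf):
            raise CorruptRecordError(
                f"{self.what} overrun while reading {fieldname}"
            )
        out = self.buf[self.pos : self.pos + n]
        self.pos += n
        return out

    def unpack(self, fmt: str, fieldname: str):
        return struct.unpack(fmt, self.take(struct.calcsize(fmt), fieldname))

    def done(self) -> bool:
        return self.pos == len(self.buf)


def _encode_aux(value, code: AuxType) -> bytes:
    if code in _SCALAR_FMT:
        try:
            return struct.pack(_SCALAR_FMT[code], value)
        except struct.error as exc:
            raise EncodingError(f"aux value {value!r} invalid for {code.name}: {exc}")
    if code is AuxType.STRING:
        b = str(value).encode()
        return struct.pack("<I", len(b)) + b
    if code is AuxType.ARRAY_INT16:
        arr = np.asarray(value, dtype="<i2")
        return struct.pack("<Q", arr.size) + arr.tobytes()
    if code is AuxType.ARRAY_FLOAT64:
        arr = np.asarray(value, dtype="<f8")
        return struct.pack("<Q", arr.size) + arr.tobytes()
    raise EncodingError(f"unsupported aux type {code!r}")


def _decode_aux(cur: _Cursor, name: str, code: AuxType):
    label = f"aux field {name!r}"
    if code in _SCALAR_FMT:
        return cur.unpack(_SCALAR_FMT[code], label)[0]
    if code is AuxType.STRING:
        (n,) = cur.unpack("<I", label)
        return cur.take(n, label).decode()
    if code is AuxType.ARRAY_INT16:
        (n,) = cur.unpack("<Q", label)
        return np.frombuffer(cur.take(2 * n, label), dtype="<i2").copy()
    if code is AuxType.ARRAY_FLOAT64:
        (n,) = cur.unpack("<Q", label)
        return np.frombuffer(cur.take(8 * n, label), dtype="<f8").copy()
    raise CorruptRecordError(f"unsupported aux type for {label}")


def encode_record(record: ReadRecord, header: RunHeader) -> bytes:
    """Serialize one record under ``header``'s schema and compression.

    Deterministic: identical inputs yield identical bytes.  The result is
    the *unframed* record body; :func:`write_file` prefixes the 4-byte
    length that makes it self-delimiting.
    """
    if not (0 <= record.read_group < header.num_read_groups):
        raise EncodingError(
            f"read_group {record.read_group} out of range for "
            f"{header.num_read_groups} read group(s)"
        )
    if record.digitisation <= 0:
        raise EncodingError("digitisation must be positive")
    if record.sampling_rate <= 0:
        raise EncodingError("sampling_rate must be positive")
    if len(record.aux_values) != len(header.aux_schema):
        raise EncodingError(
            f"record has {len(record.aux_values)} aux values, header schema "
            f"expects {len(header.aux_schema)}"
        )
    rid = record.read_id.encode()
    if not rid:
        raise EncodingError("read_id must be non-empty")

    signal = np.asarray(record.raw_signal, dtype=np.int16)
    if header.signal_compression is SignalCompression.SVB_ZD:
        sig_payload = svb_zd_compress(signal)
    else:
        sig_payload = signal.astype("<i2").tobytes()

    body = bytearray()
    body += struct.pack("<H", len(rid)) + rid
    body += struct.pack("<I", record.read_group)
    body += struct.pack(
        "<dddd",
        record.digitisation,
        record.offset,
        record.range,
        record.sampling_rate,
    )
    body += struct.pack("<Q", signal.size)
    body += struct.pack("<I", len(sig_payload)) + sig_payload
    for value, (name, code) in zip(record.aux_values, header.aux_schema):
        body += _encode_aux(value, code)

    if header.record_compression is RecordCompression.ZLIB:
        return zlib.compress(bytes(body), level=6)
    return bytes(body)


def decode_record(payload: bytes, header: RunHeader) -> ReadRecord:
    """Exact inverse of :func:`encode_record`; trailing bytes are an error."""
    if header.record_compression is RecordCompression.ZLIB:
        try:
            payload = zlib.decompress(payload)
        except zlib.error as exc:
            raise CorruptRecordError(f"record decompression failed: {exc}") from None
    cur = _Cursor(payload)
    (rid_len,) = cur.unpack("<H", "read_id length")
    read_id = cur.take(rid_len, "read_id").decode()
    (read_group,) = cur.unpack("<I", "read_group")
    digitisation, offset, range_, sampling_rate = cur.unpack(
        "<dddd", "signal scaling"
    )
    (n_samples,) = cur.unpack("<Q", "sample count")
    (sig_len,) = cur.unpack("<I", "signal payload length")
    sig_payload = cur.take(sig_len, "signal payload")
    if header.signal_compression is SignalCompression.SVB_ZD:
        signal = svb_zd_decompress(sig_payload, n_samples)
    else:
        if sig_len != 2 * n_samples:
            raise CorruptRecordError("raw signal payload length mismatch")
        signal = np.frombuffer(sig_payload, dtype="<i2").copy()
    aux_values = tuple(
        _decode_aux(cur, name, code) for name, code in header.aux_schema
    )
    if not cur.done():
        raise CorruptRecordError(
            f"trailing bytes after last field ({len(payload) - cur.pos} extra)"
        )
    return ReadRecord(
        read_id=read_id,
        read_group=read_group,
        digitisation=digitisation,
        offset=offset,
        range=range_,
        sampling_rate=sampling_rate,
        raw_signal=signal,
        aux_values=aux_values,
    )


def decode_framed_record(buf: bytes, header: RunHeader) -> ReadRecord:
    """Decode one length-framed record exactly as stored at its indexed
    byte extent: 4-byte length prefix + body, nothing else."""
    if len(buf) < 4:
        raise CorruptRecordError("framed record shorter than its length prefix")
    (length,) = struct.unpack_from("<I", buf)
    if length == EOF_MARKER:
        raise CorruptRecordError("end-of-file marker where a record was expected")
    if len(buf) != 4 + length:
        raise CorruptRecordError(
            f"framed record is {len(buf)} bytes, frame declares {4 + length}"
        )
    return decode_record(buf[4:], header)


@dataclass(frozen=True)
class FileSummary:
    """What :func:`write_file` wrote: exactly the extents an index needs."""

    n_records: int
    header_byte_length: int
    entries: tuple  # ((read_id, byte_offset, byte_length), ...)


def write_file(
    header: RunHeader, records: Iterable[ReadRecord], destination
) -> FileSummary:
    """Write a container file; returns per-record byte extents.

    Layout: serialized header, then for each record a ``u32`` body length
    followed by the body, then the 4-byte end-of-file marker.  Duplicate
    read IDs abort before any byte is written.
    """
    records = list(records)
    ids = [r.read_id for r in records]
    if len(set(ids)) != len(ids):
        seen, dup = set(), None
        for i in ids:
            if i in seen:
                dup = i
                break
            seen.add(i)
        raise DuplicateReadIdError(f"duplicate read_id {dup!r}")

    head = header.serialize()
    entries = []
    with open(destination, "wb") as fh:
        fh.write(head)
        pos = len(head)
        for rec in records:
            body = encode_record(rec, header)
            frame = struct.pack("<I", len(body)) + body
            fh.write(frame)
            entries.append((rec.read_id, pos, len(frame)))
            pos += len(frame)
        fh.write(struct.pack("<I", EOF_MARKER))
    return FileSummary(
        n_records=len(records),
        header_byte_length=len(head),
        entries=tuple(entries),
    )


class ContainerReader:
    """Streaming reader over a container file.

    Iterating yields records in file order without loading the whole file.
    Use as a context manager, or call :meth:`close`.
    """

    def __init__(self, source):
        if hasattr(source, "read"):
            self._fh: BinaryIO = source
            self._owns = False
        else:
            self._fh = open(source, "rb")
            self._owns = True
        prefix = self._fh.read(16)
        if len(prefix) < 16 or prefix[:8] != MAGIC:
            self.close()
            raise FormatError("bad magic: not a sigfetch container")
        (body_len,) = struct.unpack_from("<Q", prefix, 8)
        body = self._fh.read(body_len)
        if len(body) < body_len:
            self.close()
            raise FormatError("truncated container header")
        self.header = parse_header(prefix + body)
        self.header_byte_length = 16 + body_len
        self._data_start = 16 + body_len

    def __enter__(self) -> "ContainerReader":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    def close(self) -> None:
        if self._owns:
            self._fh.close()

    def __iter__(self) -> Iterator[ReadRecord]:
        for _, _, rec in self.iter_with_extents():
            yield rec

    def iter_with_extents(self) -> Iterator[tuple[int, int, ReadRecord]]:
        """Yield ``(byte_offset, byte_length, record)`` in file order."""
        self._fh.seek(self._data_start)
        pos = self._data_start
        ordinal = 0
        while True:
            prefix = self._fh.read(4)
            if len(prefix) < 4:
                raise CorruptRecordError(
                    f"unexpected end of file before record {ordinal} "
                    "(missing end-of-file marker)"
                )
            (length,) = struct.unpack("<I", prefix)
            if length == EOF_MARKER:
                if self._fh.read(1):
                    raise CorruptRecordError("trailing bytes after end-of-file marker")
                return
            body = self._fh.read(length)
            if len(body) < length:
                raise CorruptRecordError(f"record {ordinal} truncated")
            try:
                rec = decode_record(body, self.header)
            except CorruptRecordError as exc:
                raise CorruptRecordError(f"record {ordinal}: {exc}") from None
            yield pos, 4 + length, rec
            pos += 4 + length
            ordinal += 1


def read_file(source) -> tuple[RunHeader, Iterator[ReadRecord]]:
    """Open a container; returns the header and a streaming record iterator."""
    reader = ContainerReader(source)

    def _gen():
        with reader:
            yield from reader

    return reader.header, _gen()


def read_all(source) -> tuple[RunHeader, list[ReadRecord]]:
    """Convenience: header plus all records as a list."""
    header, it = read_file(source)
    return header, list(it)
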