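# sigfetch container and index file formats

Byte-exact specification of the two binary files sigfetch reads and
writes.  All integers are **little-endian**.  `u8/u16/u32/u64` are
unsigned, `i16/i32/i64` signed, `f64` IEEE-754 double.  Strings are
UTF-8, never NUL-terminated, always length-prefixed.

This is a documented dialect of the community SLOW5/BLOW5 idea — a
simple record-per-read binary container with a sidecar read-ID index —
not a byte-compatible implementation of the published BLOW5 layout.

## Container file (conventionally `*.sfc`)

```
file     := header record* eof_marker
eof_marker := u32 0xFFFFFFFF
```

### Header

```
magic      : 8 bytes  = "SIGFET01"
body_len   : u64        length of body (bytes after this field)
body       :
  format_major : u8   = 1
  format_minor : u8   = 0
  version_len  : u16
  version      : version_len bytes      # free-form run/software tag
  record_compression : u8               # 0 = none, 1 = zlib
  signal_compression : u8               # 0 = none, 1 = svb-zd
  num_read_groups    : u32              # >= 1
  n_aux              : u32
  aux entry * n_aux:
    name_len : u16 ; name : name_len bytes ; type_code : u8
  group attributes * num_read_groups:
    n_attrs : u32
    attr * n_attrs:
      key_len : u16 ; key ; value_len : u32 ; value
```

The *header extent* is `16 + body_len` bytes starting at offset 0; the
index records this length so a remote client can fetch and parse the
header in a single range request.

Aux type codes: 0 i8, 1 i16, 2 i32, 3 i64, 4 u8, 5 u16, 6 u32, 7 u64,
8 f32, 9 f64, 10 string (`u32 len + bytes`), 11 i16 array
(`u64 count + count*2 bytes`), 12 f64 array (`u64 count + count*8 bytes`).

### Records

Each record is framed:

```
frame := body_len : u32   # never 0xFFFFFFFF (that is the EOF marker)
         body     : body_len bytes
```

The frame (length prefix + body) is exactly the byte extent stored in
the index: slicing the file there and decoding reproduces the record
standalone.  `body` is, optionally zlib-compressed as a whole
(per `record_compression`):

```
read_id_len   : u16 ; read_id : read_id_len bytes
read_group    : u32                      # < num_read_groups
digitisation  : f64     # ADC levels, > 0
offset        : f64     # ADC units
range         : f64     # picoamperes
sampling_rate : f64     # Hz, > 0
n_samples     : u64
sig_len       : u32 ; signal_payload : sig_len bytes
aux values, one per header aux entry, in schema order
```

`signal_payload` is the raw `i16` samples (little-endian, `sig_len =
2*n_samples`) when `signal_compression = none`, or the svb-zd encoding
below.  Framing is exact everywhere: trailing bytes at any level are a
corruption error.

Picoampere conversion: `pA = (sample + offset) * range / digitisation`.

### svb-zd signal encoding

1. **Delta**: `d[0] = s[0]`, `d[i] = s[i] - s[i-1]`, in 32-bit signed
   arithmetic (the difference of two i16 always fits).
2. **Zigzag**: non-negative `d → 2d`; negative `d → -2d - 1`
   (a bijection onto the unsigned 32-bit range).
3. **StreamVByte pack** (32-bit lanes): `ceil(n/4)` control bytes, then
   the data bytes.  Value `4k+j` owns bits `2j..2j+1` of control byte
   `k`; the 2-bit code is `stored_bytes - 1` (1–4 data bytes).  Data
   bytes are each value's little-endian low bytes, concatenated in
   value order.  Unused codes in the last control byte are zero.

The empty signal encodes to the empty payload.  Decoders must reject a
payload whose length is not exactly `ceil(n/4) + sum(stored_bytes)`,
nonzero control padding, and any reconstructed sample outside i16.

## Index file (conventionally `<container>.idx`)

```
magic         : 8 bytes = "SIGFIDX1"
index_version : u8 = 1
header_extent : u64      # byte length of the container header (offset 0)
n_entries     : u64
entry * n_entries (container file order):
  read_id_len : u16 ; read_id
  byte_offset : u64      # of the record frame within the container
  byte_length : u64      # full frame length (one range request per read)
```

Entry extents are disjoint and lie after the header extent.  No
trailing bytes are permitted.
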