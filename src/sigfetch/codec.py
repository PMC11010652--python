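"""Signal codec: zigzag + delta + StreamVByte ("svb-zd").

Raw nanopore current samples are 16-bit signed integers.  Consecutive
samples are strongly correlated, so the stored form is the first
difference of the series (computed in 32-bit signed arithmetic; the
difference of two int16 always fits), with the sign interleaved away by
the zigzag map and the resulting small unsigned integers packed with the
standard 32-bit StreamVByte layout:

* ``ceil(n/4)`` control bytes, 2 bits per value, little-endian within the
  byte (value ``4k+j`` occupies bits ``2j..2j+1`` of control byte ``k``);
  the 2-bit code is ``stored_byte_length - 1`` (1–4 data bytes per value);
* followed by the data bytes, each value little-endian, concatenated in
  value order.

The empty series encodes to the empty payload.  Framing is exact: a
payload that is too short *or* too long for ``n_samples`` raises
:class:`~sigfetch.errors.CorruptRecordError`.
"""

from __future__ import annotations

import numpy as np

from .errors import CorruptRecordError, EncodingError

__all__ = [
    "zigzag_encode",
    "zigzag_decode",
    "svb_zd_compress",
    "svb_zd_decompress",
]

_INT16_MIN, _INT16_MAX = -(2**15), 2**15 - 1


def zigzag_encode(v):
    """Map a signed 32-bit integer (or array) onto the unsigned integers.

    Non-negative ``v`` maps to ``2v``; negative ``v`` maps to ``-2v - 1``,
    so small-magnitude values of either sign become small unsigned values.
    Bijective on the signed 32-bit range.
    """
    a = np.asarray(v, dtype=np.int64)
    if np.any(a < -(2**31)) or np.any(a > 2**31 - 1):
        raise EncodingError("zigzag operand outside signed 32-bit range")
    zz = (a << 1) ^ (a >> 63)
    if np.isscalar(v) or np.ndim(v) == 0:
        return int(zz)
    return zz.astype(np.uint32)


def zigzag_decode(u):
    """Inverse of :func:`zigzag_encode`."""
    a = np.asarray(u, dtype=np.int64)
    if np.any(a < 0) or np.any(a > 2**32 - 1):
        raise EncodingError("zigzag code outside unsigned 32-bit range")
    v = (a >> 1) ^ -(a & 1)
    if np.isscalar(u) or np.ndim(u) == 0:
        return int(v)
    return v


def _as_int16(signal) -> np.ndarray:
    arr = np.asarray(signal)
    if arr.ndim != 1 and arr.size != 0:
        raise EncodingError("signal must be one-dimensional")
    arr64 = arr.astype(np.int64, copy=False).ravel()
    if arr64.size and (arr64.min() < _INT16_MIN or arr64.max() > _INT16_MAX):
        raise EncodingError("signal value outside signed 16-bit range")
    return arr64.astype(np.int16)


def svb_zd_compress(signal) -> bytes:
    """Compress a sequence of int16 samples to the svb-zd byte string."""
    s = _as_int16(signal)
    n = s.size
    if n == 0:
        return b""
    s32 = s.astype(np.int32)
    deltas = np.empty(n, dtype=np.int32)
    deltas[0] = s32[0]
    np.subtract(s32[1:], s32[:-1], out=deltas[1:])
    zz = ((deltas.astype(np.int64) << 1) ^ (deltas.astype(np.int64) >> 63)).astype("<u4")

    lengths = (
        1
        + (zz > 0xFF).astype(np.uint8)
        + (zz > 0xFFFF).astype(np.uint8)
        + (zz > 0xFFFFFF).astype(np.uint8)
    )
    n_ctrl = (n + 3) // 4
    codes = np.zeros(n_ctrl * 4, dtype=np.uint8)
    codes[:n] = lengths - 1
    ctrl = (
        codes[0::4]
        | (codes[1::4] << 2)
        | (codes[2::4] << 4)
        | (codes[3::4] << 6)
    )

    b4 = zz.view(np.uint8).reshape(n, 4)
    mask = np.arange(4, dtype=np.uint8)[None, :] < lengths[:, None]
    return ctrl.tobytes() + b4[mask].tobytes()


def svb_zd_decompress(payload: bytes, n_samples: int) -> np.ndarray:
    """Exact inverse of :func:`svb_zd_compress`.

    Raises :class:`CorruptRecordError` if the payload length does not
    match ``n_samples`` exactly or a reconstructed sample falls outside
    the signed 16-bit range.
    """
    if n_samples < 0:
        raise CorruptRecordError("negative sample count")
    if n_samples == 0:
        if payload:
            raise CorruptRecordError("non-empty payload for empty signal")
        return np.empty(0, dtype=np.int16)

    n_ctrl = (n_samples + 3) // 4
    if len(payload) < n_ctrl:
        raise CorruptRecordError("signal payload shorter than its control bytes")
    ctrl = np.frombuffer(payload, dtype=np.uint8, count=n_ctrl)
    codes = np.empty(n_ctrl * 4, dtype=np.uint8)
    codes[0::4] = ctrl & 0x3
    codes[1::4] = (ctrl >> 2) & 0x3
    codes[2::4] = (ctrl >> 4) & 0x3
    codes[3::4] = (ctrl >> 6) & 0x3
    if np.any(codes[n_samples:]):
        raise CorruptRecordError("nonzero padding in final control byte")
    lengths = codes[:n_samples].astype(np.int64) + 1

    n_data = int(lengths.sum())
    if len(payload) != n_ctrl + n_data:
        raise CorruptRecordError(
            f"signal payload is {len(payload)} bytes, expected {n_ctrl + n_data}"
        )
    data = np.frombuffer(payload, dtype=np.uint8, offset=n_ctrl)

    b4 = np.zeros((n_samples, 4), dtype=np.uint8)
    mask = np.arange(4)[None, :] < lengths[:, None]
    b4[mask] = data
    zz = b4.reshape(-1).view("<u4").astype(np.int64)

    deltas = (zz >> 1) ^ -(zz & 1)
    samples = np.cumsum(deltas)
    if samples.min() < _INT16_MIN or samples.max() > _INT16_MAX:
        raise CorruptRecordError("reconstructed sample outside signed 16-bit range")
    return samples.astype(np.int16)
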