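"""Independent scalar reference encoder for the svb-zd signal codec.

Pure-Python, one value at a time, no shared code with the package's
vectorized implementation — used as the oracle in codec tests.
"""


def ref_zigzag(v: int) -> int:
    return 2 * v if v >= 0 else -2 * v - 1


def ref_svb_zd_compress(signal) -> bytes:
    values = [int(s) for s in signal]
    if not values:
        return b""
    deltas = [values[0]] + [b - a for a, b in zip(values, values[1:])]
    codes = []
    data = bytearray()
    for d in deltas:
        zz = ref_zigzag(d)
        nbytes = max(1, (zz.bit_length() + 7) // 8)
        codes.append(nbytes - 1)
        data += zz.to_bytes(4, "little")[:nbytes]
    while len(codes) % 4:
        codes.append(0)
    ctrl = bytearray()
    for k in range(0, len(codes), 4):
        ctrl.append(
            codes[k] | (codes[k + 1] << 2) | (codes[k + 2] << 4) | (codes[k + 3] << 6)
        )
    return bytes(ctrl) + bytes(data)
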