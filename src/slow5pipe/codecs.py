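"""Compression codecs for binary signal records.

Two independent layers:

* a *record* codec (``none`` | ``zlib`` | ``zstd``) applied to the whole
  serialized record payload, and
* a *signal* codec (``none`` | ``delta_zigzag_varint``) applied to the raw
  ADC samples before the record is assembled.

``delta_zigzag_varint`` stores the first sample as a zigzag-mapped varint
and every subsequent sample as the zigzag varint of its delta from the
predecessor.  Nanopore current traces are locally flat, so deltas are
small and most samples fit in one byte.  Encoding/decoding is vectorized
with numpy; the varint group length is capped at 10 bytes (64 bits).
"""

from __future__ import annotations

import zlib

import numpy as np

from .model import Slow5Error

__all__ = [
    "CodecError",
    "compress_record",
    "decompress_record",
    "encode_signal",
    "decode_signal",
    "zigzag_encode",
    "zigzag_decode",
]

_INT16_MIN, _INT16_MAX = -32768, 32767


class CodecError(Slow5Error):
    """Unknown codec, unavailable codec backend, or corrupt payload."""


def zigzag_encode(values: np.ndarray) -> np.ndarray:
    """Map signed int64 to unsigned so small magnitudes get small codes.

    0 -> 0, -1 -> 1, 1 -> 2, -2 -> 3, ...
    """
    v = np.asarray(values, dtype=np.int64)
    return ((v << 1) ^ (v >> 63)).astype(np.uint64)


def zigzag_decode(codes: np.ndarray) -> np.ndarray:
    u = np.asarray(codes, dtype=np.uint64)
    return ((u >> np.uint64(1)).astype(np.int64)) ^ -((u & np.uint64(1)).astype(np.int64))


def _encode_varints(values: np.ndarray) -> bytes:
    """LEB128-style varint encoding of a uint64 array (vectorized)."""
    u = np.asarray(values, dtype=np.uint64)
    if u.size == 0:
        return b""
    nbytes = np.ones(u.size, dtype=np.int64)
    rest = u >> np.uint64(7)
    while rest.any():  # <= 9 iterations for 64-bit input
        nbytes += (rest > 0)
        rest >>= np.uint64(7)
    ends = np.cumsum(nbytes)
    starts = ends - nbytes
    out = np.zeros(int(ends[-1]), dtype=np.uint8)
    for k in range(int(nbytes.max())):
        sel = nbytes > k
        group = ((u[sel] >> np.uint64(7 * k)) & np.uint64(0x7F)).astype(np.uint8)
        cont = (nbytes[sel] - 1 > k).astype(np.uint8) << 7
        out[starts[sel] + k] = group | cont
    return out.tobytes()


def _decode_varints(payload: bytes) -> np.ndarray:
    b = np.frombuffer(payload, dtype=np.uint8)
    if b.size == 0:
        return np.zeros(0, dtype=np.uint64)
    is_last = b < 128
    if not is_last[-1]:
        raise CodecError("truncated varint stream (dangling continuation bit)")
    if is_last.all():  # fast path: every value fits in one byte
        return b.astype(np.uint64)
    # position of each byte within its varint group
    group_start = np.flatnonzero(np.concatenate(([True], is_last[:-1])))
    within = np.arange(b.size) - np.repeat(
        group_start, np.diff(np.append(group_start, b.size))
    )
    if within.max() > 9:
        raise CodecError("varint group exceeds 10 bytes")
    contrib = (b & 0x7F).astype(np.uint64) << (np.uint64(7) * within.astype(np.uint64))
    # groups occupy disjoint bit ranges, so summing equals bitwise-or
    return np.add.reduceat(contrib, group_start)


def encode_signal(samples: np.ndarray, codec: str = "delta_zigzag_varint") -> bytes:
    """Serialize int16 signal samples under *codec*."""
    sig = np.asarray(samples, dtype=np.int16)
    if codec == "none":
        return sig.astype("<i2").tobytes()
    if codec == "delta_zigzag_varint":
        deltas = np.diff(sig.astype(np.int64), prepend=np.int64(0))
        return _encode_varints(zigzag_encode(deltas))
    raise CodecError(f"unknown signal codec {codec!r}")


def decode_signal(payload: bytes, codec: str = "delta_zigzag_varint") -> np.ndarray:
    """Invert :func:`encode_signal`; raises :class:`CodecError` on corruption."""
    if codec == "none":
        if len(payload) % 2:
            raise CodecError("raw int16 payload has odd byte length")
        return np.frombuffer(payload, dtype="<i2").astype(np.int16)
    if codec == "delta_zigzag_varint":
        deltas = zigzag_decode(_decode_varints(payload))
        samples = np.cumsum(deltas)
        if samples.size and (samples.min() < _INT16_MIN or samples.max() > _INT16_MAX):
            raise CodecError("decoded sample outside 16-bit signed range")
        return samples.astype(np.int16)
    raise CodecError(f"unknown signal codec {codec!r}")


def compress_record(data: bytes, codec: str) -> bytes:
    """Compress a serialized record payload under a record codec."""
    if codec == "none":
        return bytes(data)
    if codec == "zlib":
        return zlib.compress(bytes(data), 6)
    if codec == "zstd":
        return _zstd().ZstdCompressor(level=3).compress(bytes(data))
    raise CodecError(f"unknown record codec {codec!r}")


def decompress_record(data: bytes, codec: str) -> bytes:
    if codec == "none":
        return bytes(data)
    if codec == "zlib":
        try:
            return zlib.decompress(bytes(data))
        except zlib.error as exc:
            raise CodecError(f"zlib payload corrupt: {exc}") from exc
    if codec == "zstd":
        zstd = _zstd()
        try:
            return zstd.ZstdDecompressor().decompress(bytes(data))
        except zstd.ZstdError as exc:
            raise CodecError(f"zstd payload corrupt: {exc}") from exc
    raise CodecError(f"unknown record codec {codec!r}")


def _zstd():
    try:
        import zstandard
    except ImportError as exc:  # pragma: no cover - environment-dependent
        raise CodecError("record codec 'zstd' requires the zstandard package") from exc
    return zstandard
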