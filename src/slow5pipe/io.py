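"""Reading and writing of nanopore signal files in two dialects.

* **ASCII** (``.slow5``): ``#``-prefixed header lines followed by one
  tab-separated row per read, signal serialized as comma-separated
  integers.  Diffable, sequential-only.
* **Binary** (``.blow5``): 8-byte magic, versioned header, then one
  ``[u32 length][payload]`` frame per read, with selectable record and
  signal compression codecs.  Supports appending and byte-offset indexing
  for random access.

Both writers are byte-deterministic for identical inputs (stable attribute
order, no timestamps), so round trips can be compared by digest.  The
side-car index (``<file>.idx``) stores the data file's size and mtime so a
stale index is detected instead of silently misused.
"""

from __future__ import annotations

import os
import struct
from dataclasses import dataclass
from typing import IO, Iterable, Iterator

import numpy as np

from .codecs import (
    CodecError,
    _decode_varints,
    compress_record,
    decode_signal,
    decompress_record,
    encode_signal,
    zigzag_decode,
)
from .model import (
    AuxSchemaError,
    RunHeader,
    SignalRead,
    Slow5Error,
    ValidationError,
)

__all__ = [
    "MAGIC",
    "BINARY_VERSION",
    "Slow5ParseError",
    "DuplicateReadIdError",
    "HeaderMismatchError",
    "ReadNotFoundError",
    "StaleIndexError",
    "MissingIndexError",
    "Blow5Index",
    "Slow5File",
    "write_slow5",
    "append_slow5",
    "read_header",
    "stream_reads",
    "build_index",
    "load_index",
    "ensure_index",
    "get_read",
    "index_path_for",
]

MAGIC = b"BLW5PIPE"
BINARY_VERSION = 1
_FORMAT_LINE = "#slow5pipe\t1"
_BASE_COLUMNS = (
    "read_id",
    "read_group",
    "digitisation",
    "offset",
    "range",
    "sampling_rate",
    "len_raw_signal",
    "raw_signal",
)


class Slow5ParseError(Slow5Error):
    """Malformed file: bad magic, unsupported version, truncation, bad row."""


class DuplicateReadIdError(Slow5Error):
    """A read_id occurs more than once in one file."""


class HeaderMismatchError(Slow5Error):
    """Append target's header is incompatible with the expected header."""


class ReadNotFoundError(Slow5Error):
    """Requested read_id is absent from the index/file."""


class StaleIndexError(Slow5Error):
    """Side-car index no longer matches the data file it was built from."""


class MissingIndexError(Slow5Error):
    """Random access requested but no side-car index exists."""


# ---------------------------------------------------------------------------
# header serialization (shared by both dialects; the binary dialect embeds
# the same text after its magic/version/length prelude)

def _fmt_float(x: float) -> str:
    return repr(float(x))


def serialize_header(header: RunHeader) -> str:
    lines = [
        _FORMAT_LINE,
        f"#num_read_groups\t{header.num_read_groups}",
        f"#record_codec\t{header.record_codec}",
        f"#signal_codec\t{header.signal_codec}",
    ]
    for group, attrs in enumerate(header.attributes):
        for key, value in attrs.items():
            lines.append(f"#attr\t{group}\t{key}\t{value}")
    for name, typ in header.aux_schema:
        lines.append(f"#aux\t{name}\t{typ}")
    cols = _BASE_COLUMNS + tuple(n for n, _ in header.aux_schema)
    lines.append("#columns\t" + "\t".join(cols))
    return "\n".join(lines) + "\n"


def parse_header_text(text: str) -> RunHeader:
    lines = text.split("\n")
    if not lines or lines[0] != _FORMAT_LINE:
        raise Slow5ParseError(f"bad header format line: {lines[0] if lines else ''!r}")
    num_groups = None
    record_codec = "none"
    signal_codec = "none"
    attrs: dict[int, dict[str, str]] = {}
    aux: list[tuple[str, str]] = []
    saw_columns = False
    for line in lines[1:]:
        if not line:
            continue
        parts = line.split("\t")
        tag = parts[0]
        if tag == "#num_read_groups":
            num_groups = int(parts[1])
        elif tag == "#record_codec":
            record_codec = parts[1]
        elif tag == "#signal_codec":
            signal_codec = parts[1]
        elif tag == "#attr":
            attrs.setdefault(int(parts[1]), {})[parts[2]] = parts[3]
        elif tag == "#aux":
            aux.append((parts[1], parts[2]))
        elif tag == "#columns":
            saw_columns = True
            expected = _BASE_COLUMNS + tuple(n for n, _ in aux)
            if tuple(parts[1:]) != expected:
                raise Slow5ParseError(f"column list {parts[1:]} does not match schema")
        else:
            raise Slow5ParseError(f"unknown header line tag {tag!r}")
    if num_groups is None or not saw_columns:
        raise Slow5ParseError("truncated header: missing #num_read_groups or #columns line")
    attr_maps = tuple(attrs.get(g, {}) for g in range(num_groups))
    try:
        return RunHeader(
            num_read_groups=num_groups,
            attributes=attr_maps,
            aux_schema=tuple(aux),
            record_codec=record_codec,
            signal_codec=signal_codec,
        )
    except ValidationError as exc:
        raise Slow5ParseError(f"invalid header content: {exc}") from exc


# ---------------------------------------------------------------------------
# record serialization

def _check_read(read: SignalRead, header: RunHeader) -> None:
    if not 0 <= read.read_group < header.num_read_groups:
        raise ValidationError(
            f"read {read.read_id!r}: read_group {read.read_group} outside "
            f"[0, {header.num_read_groups})"
        )
    header.validate_aux(read.aux)


def _encode_record_binary(read: SignalRead, header: RunHeader) -> bytes:
    sig = encode_signal(read.raw_signal, header.signal_codec)
    rid = read.read_id.encode()
    parts = [
        struct.pack("<H", len(rid)),
        rid,
        struct.pack("<I", read.read_group),
        struct.pack("<dddd", read.digitisation, read.offset, read.range, read.sampling_rate),
        struct.pack("<Q", len(read.raw_signal)),
        struct.pack("<Q", len(sig)),
        sig,
    ]
    for name, typ in header.aux_schema:
        val = read.aux[name]
        if typ == "int":
            parts.append(struct.pack("<q", int(val)))
        elif typ == "float":
            parts.append(struct.pack("<d", float(val)))
        else:
            raw = str(val).encode()
            parts.append(struct.pack("<H", len(raw)) + raw)
    core = b"".join(parts)
    payload = compress_record(core, header.record_codec)
    return struct.pack("<I", len(payload)) + payload


def _parse_core(core: bytes, header: RunHeader) -> tuple:
    """Parse one decompressed record, leaving the signal payload encoded.

    Returns ``(read_id, read_group, dig, off, rng, rate, n_samples,
    signal_payload, aux)``.
    """
    view = memoryview(core)
    pos = 0

    def take(n: int) -> memoryview:
        nonlocal pos
        if pos + n > len(view):
            raise Slow5ParseError("record payload truncated")
        out = view[pos:pos + n]
        pos += n
        return out

    (idlen,) = struct.unpack("<H", take(2))
    read_id = bytes(take(idlen)).decode()
    (read_group,) = struct.unpack("<I", take(4))
    dig, off, rng, rate = struct.unpack("<dddd", take(32))
    (n_samples,) = struct.unpack("<Q", take(8))
    (sig_len,) = struct.unpack("<Q", take(8))
    sig_payload = bytes(take(sig_len))
    aux: dict[str, object] = {}
    for name, typ in header.aux_schema:
        if typ == "int":
            (aux[name],) = struct.unpack("<q", take(8))
        elif typ == "float":
            (aux[name],) = struct.unpack("<d", take(8))
        else:
            (slen,) = struct.unpack("<H", take(2))
            aux[name] = bytes(take(slen)).decode()
    if pos != len(view):
        raise Slow5ParseError(f"read {read_id!r}: {len(view) - pos} trailing bytes in record")
    return read_id, read_group, dig, off, rng, rate, n_samples, sig_payload, aux


def _decode_record_binary(payload: bytes, header: RunHeader) -> SignalRead:
    core = decompress_record(payload, header.record_codec)
    rid, group, dig, off, rng, rate, n_samples, sig_payload, aux = _parse_core(core, header)
    signal = decode_signal(sig_payload, header.signal_codec)
    if signal.size != n_samples:
        raise Slow5ParseError(
            f"read {rid!r}: stored length {n_samples} != decoded {signal.size}"
        )
    return SignalRead(rid, group, dig, off, rng, rate, signal, aux)


def _decode_batch_binary(payloads, header: RunHeader) -> list:
    """Decode many records at once, vectorizing the signal codec across the
    whole batch.

    Each record's varint stream is self-delimiting, so the concatenation of
    all signal payloads decodes as one stream; per-record delta cumsums are
    recovered by subtracting the running total at each record boundary.
    Falls back to per-record decoding for other signal codecs.
    """
    if header.signal_codec != "delta_zigzag_varint":
        return [_decode_record_binary(p, header) for p in payloads]
    metas = [
        _parse_core(decompress_record(p, header.record_codec), header)
        for p in payloads
    ]
    if not metas:
        return []
    counts = np.array([m[6] for m in metas], dtype=np.int64)
    concat = b"".join(m[7] for m in metas)
    deltas = zigzag_decode(_decode_varints(concat))
    if deltas.size != int(counts.sum()):
        raise Slow5ParseError(
            f"batch signal decode: {deltas.size} samples for stored total {counts.sum()}"
        )
    csum = np.cumsum(deltas)
    boundaries = np.cumsum(counts)
    if deltas.size:
        # running total just before each record start (0 for records at offset 0)
        prior = boundaries[:-1] - 1
        base = np.zeros(len(counts), dtype=np.int64)
        base[1:] = np.where(prior >= 0, csum[np.maximum(prior, 0)], 0)
        csum = csum - np.repeat(base, counts)
        if csum.min() < -32768 or csum.max() > 32767:
            raise Slow5ParseError("decoded sample outside 16-bit signed range")
    signals = np.split(csum.astype(np.int16), boundaries[:-1])
    return [
        SignalRead(m[0], m[1], m[2], m[3], m[4], m[5], sig, m[8])
        for m, sig in zip(metas, signals)
    ]


def _encode_record_ascii(read: SignalRead, header: RunHeader) -> str:
    sig = ",".join(str(int(v)) for v in read.raw_signal)
    fields = [
        read.read_id,
        str(read.read_group),
        _fmt_float(read.digitisation),
        _fmt_float(read.offset),
        _fmt_float(read.range),
        _fmt_float(read.sampling_rate),
        str(len(read.raw_signal)),
        sig,
    ]
    for name, typ in header.aux_schema:
        val = read.aux[name]
        if typ == "int":
            fields.append(str(int(val)))
        elif typ == "float":
            fields.append(_fmt_float(float(val)))
        else:
            fields.append(str(val))
    return "\t".join(fields) + "\n"


def _decode_record_ascii(line: str, header: RunHeader) -> SignalRead:
    fields = line.rstrip("\n").split("\t")
    n_expected = len(_BASE_COLUMNS) + len(header.aux_schema)
    if len(fields) != n_expected:
        raise Slow5ParseError(f"row has {len(fields)} fields, expected {n_expected}")
    sig_text = fields[7]
    if sig_text:
        signal = np.fromiter((int(v) for v in sig_text.split(",")), dtype=np.int64)
    else:
        signal = np.zeros(0, dtype=np.int64)
    n_samples = int(fields[6])
    if signal.size != n_samples:
        raise Slow5ParseError(
            f"read {fields[0]!r}: stored length {n_samples} != {signal.size} samples"
        )
    aux: dict[str, object] = {}
    for (name, typ), text in zip(header.aux_schema, fields[8:]):
        if typ == "int":
            aux[name] = int(text)
        elif typ == "float":
            aux[name] = float(text)
        else:
            aux[name] = text
    return SignalRead(
        read_id=fields[0],
        read_group=int(fields[1]),
        digitisation=float(fields[2]),
        offset=float(fields[3]),
        range=float(fields[4]),
        sampling_rate=float(fields[5]),
        raw_signal=signal,
        aux=aux,
    )


# ---------------------------------------------------------------------------
# instrumented file handle (used by the bench module's I/O counters)

class CountingFile:
    """Binary file wrapper counting bytes read and repositioning seeks."""

    def __init__(self, fh: IO[bytes]):
        self._fh = fh
        self.bytes_read = 0
        self.seek_count = 0
        self._pos = fh.tell()

    def read(self, n: int = -1) -> bytes:
        data = self._fh.read(n)
        self.bytes_read += len(data)
        self._pos += len(data)
        return data

    def readline(self) -> bytes:
        data = self._fh.readline()
        self.bytes_read += len(data)
        self._pos += len(data)
        return data

    def seek(self, pos: int, whence: int = 0) -> int:
        new = self._fh.seek(pos, whence)
        if new != self._pos:
            self.seek_count += 1
        self._pos = new
        return new

    def tell(self) -> int:
        return self._pos

    def close(self) -> None:
        self._fh.close()


# ---------------------------------------------------------------------------
# side-car index

_INDEX_MAGIC = "#slow5pipe-index\t1"


@dataclass
class Blow5Index:
    """read_id -> (byte_offset, record_length) map for one binary file.

    Offsets address the compressed record payload (after its u32 length
    prefix); reading ``record_length`` bytes there and decoding yields the
    record.  ``file_size``/``mtime_ns`` fingerprint the data file for
    staleness detection.
    """

    entries: dict
    source_path: str
    file_size: int
    mtime_ns: int

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, read_id: str) -> bool:
        return read_id in self.entries

    def save(self, path: str | None = None) -> str:
        path = path or index_path_for(self.source_path)
        with open(path, "w") as fh:
            fh.write(f"{_INDEX_MAGIC}\t{self.file_size}\t{self.mtime_ns}\n")
            for rid, (off, length) in self.entries.items():
                fh.write(f"{rid}\t{off}\t{length}\n")
        return path


def index_path_for(data_path: str) -> str:
    return str(data_path) + ".idx"


# ---------------------------------------------------------------------------
# reader

class Slow5File:
    """Open one signal file (either dialect) for reading.

    Sequential iteration works on both dialects; :meth:`get_read` random
    access works on the binary dialect only and requires an index.
    """

    def __init__(self, path: str, count_io: bool = False):
        self.path = str(path)
        raw = open(self.path, "rb")
        self._fh: IO[bytes] | CountingFile = CountingFile(raw) if count_io else raw
        self._index: Blow5Index | None = None
        try:
            prefix = self._fh.read(8)
            if prefix == MAGIC:
                self.dialect = "binary"
                version_bytes = self._fh.read(2)
                if len(version_bytes) < 2:
                    raise Slow5ParseError("truncated header: missing version")
                (version,) = struct.unpack("<H", version_bytes)
                if version != BINARY_VERSION:
                    raise Slow5ParseError(
                        f"unsupported binary version {version} (expected {BINARY_VERSION})"
                    )
                hlen_bytes = self._fh.read(4)
                if len(hlen_bytes) < 4:
                    raise Slow5ParseError("truncated header: missing length field")
                (hlen,) = struct.unpack("<I", hlen_bytes)
                htext = self._fh.read(hlen)
                if len(htext) < hlen:
                    raise Slow5ParseError("truncated header text")
                self.header = parse_header_text(htext.decode())
                self._data_start = 8 + 2 + 4 + hlen
            elif prefix.startswith(b"#slow5") or prefix.startswith(_FORMAT_LINE[:8].encode()):
                self.dialect = "ascii"
                self._read_ascii_header(prefix)
            else:
                raise Slow5ParseError(f"bad magic bytes {prefix!r}: not a slow5pipe file")
        except Exception:
            self._fh.close()
            raise

    def _read_ascii_header(self, prefix: bytes) -> None:
        first = prefix + self._fh.readline()
        lines = [first.decode().rstrip("\n")]
        while True:
            pos_line = self._fh.readline()
            if not pos_line:
                raise Slow5ParseError("truncated header: no #columns line")
            text = pos_line.decode().rstrip("\n")
            lines.append(text)
            if text.startswith("#columns"):
                break
        self.header = parse_header_text("\n".join(lines) + "\n")
        self._data_start = self._fh.tell()

    # -- sequential access -------------------------------------------------

    #: block size for buffered sequential reading (one forward pass, few
    #: large reads instead of two tiny ones per record)
    _BLOCK = 1 << 22

    def iter_raw(self) -> Iterator:
        """Yield raw records in file order: ``(offset, payload bytes)`` for
        binary files, row strings for ASCII files.  Single forward pass."""
        if self._fh.tell() != self._data_start:
            self._fh.seek(self._data_start)
        if self.dialect == "binary":
            yield from self._iter_raw_binary()
        else:
            while True:
                line = self._fh.readline()
                if not line:
                    return
                text = line.decode()
                if text.strip():
                    yield text

    def _iter_raw_binary(self) -> Iterator:
        fh = self._fh
        base = self._data_start  # absolute file offset of buf[0]
        buf = b""
        cursor = 0

        def refill(at_least: int) -> bytes:
            # an interleaved get_read may have moved the shared handle;
            # re-sync to the streaming position before reading the next block
            next_pos = base + len(buf)
            if fh.tell() != next_pos:
                fh.seek(next_pos)
            return fh.read(max(self._BLOCK, at_least))

        while True:
            if len(buf) - cursor < 4:
                chunk = refill(4)
                base += cursor
                buf = buf[cursor:] + chunk
                cursor = 0
                if not buf:
                    return
                if len(buf) < 4:
                    raise Slow5ParseError(
                        f"truncated record length at offset {base}"
                    )
            (plen,) = struct.unpack_from("<I", buf, cursor)
            while len(buf) - cursor - 4 < plen:
                chunk = refill(plen)
                if not chunk:
                    raise Slow5ParseError(
                        f"truncated record at offset {base + cursor} "
                        f"(last good offset {base + cursor})"
                    )
                base += cursor
                buf = buf[cursor:] + chunk
                cursor = 0
            start = cursor + 4
            yield base + start, buf[start:start + plen]
            cursor = start + plen

    def decode_record(self, raw) -> SignalRead:
        if self.dialect == "binary":
            return _decode_record_binary(raw[1] if isinstance(raw, tuple) else raw, self.header)
        return _decode_record_ascii(raw, self.header)

    def decode_batch(self, raws) -> list:
        """Decode a list of raw records, vectorizing the signal codec across
        the batch for binary files (cheaper than record-at-a-time)."""
        if self.dialect == "binary":
            payloads = [r[1] if isinstance(r, tuple) else r for r in raws]
            return _decode_batch_binary(payloads, self.header)
        return [_decode_record_ascii(r, self.header) for r in raws]

    def seq_reads(self) -> Iterator[SignalRead]:
        """Decode every record in file order (the sequential access path)."""
        chunk = []
        for raw in self.iter_raw():
            chunk.append(raw)
            if len(chunk) == 1024:
                yield from self.decode_batch(chunk)
                chunk = []
        if chunk:
            yield from self.decode_batch(chunk)

    # -- random access (binary only) ---------------------------------------

    def attach_index(self, index: Blow5Index) -> None:
        self._index = index

    def get_read(self, read_id: str, index: Blow5Index | None = None) -> SignalRead:
        if self.dialect != "binary":
            raise Slow5Error("random access is defined for the binary dialect only")
        idx = index or self._index
        if idx is None:
            idx = self._index = ensure_index(self.path)
        try:
            offset, length = idx.entries[read_id]
        except KeyError:
            raise ReadNotFoundError(
                f"read_id {read_id!r} not in index for {self.path}"
            ) from None
        self._fh.seek(offset)
        payload = self._fh.read(length)
        if len(payload) < length:
            raise Slow5ParseError(f"truncated record at offset {offset}")
        return _decode_record_binary(payload, self.header)

    # -- bookkeeping --------------------------------------------------------

    @property
    def bytes_read(self) -> int:
        return self._fh.bytes_read if isinstance(self._fh, CountingFile) else 0

    @property
    def seek_count(self) -> int:
        return self._fh.seek_count if isinstance(self._fh, CountingFile) else 0

    def close(self) -> None:
        self._fh.close()

    def __enter__(self) -> "Slow5File":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


# ---------------------------------------------------------------------------
# module-level operations

def write_slow5(
    path: str,
    header: RunHeader,
    reads: Iterable[SignalRead],
    binary: bool = True,
) -> int:
    """Write *reads* under *header*; returns the record count.

    Duplicate read_ids and aux-schema violations reject the write (the
    partial output file is removed).
    """
    count = 0
    seen: set[str] = set()
    try:
        with open(path, "wb") as fh:
            htext = serialize_header(header).encode()
            if binary:
                fh.write(MAGIC)
                fh.write(struct.pack("<H", BINARY_VERSION))
                fh.write(struct.pack("<I", len(htext)))
                fh.write(htext)
            else:
                fh.write(htext)
            for read in reads:
                if read.read_id in seen:
                    raise DuplicateReadIdError(f"duplicate read_id {read.read_id!r}")
                seen.add(read.read_id)
                _check_read(read, header)
                if binary:
                    fh.write(_encode_record_binary(read, header))
                else:
                    fh.write(_encode_record_ascii(read, header).encode())
                count += 1
    except Exception:
        if os.path.exists(path):
            os.unlink(path)
        raise
    return count


def read_header(path: str) -> RunHeader:
    """Parse and return the file's header (either dialect)."""
    with Slow5File(path) as fh:
        return fh.header


def stream_reads(path: str) -> Iterator[SignalRead]:
    """Sequentially yield every read in file order."""
    with Slow5File(path) as fh:
        yield from fh.seq_reads()


def append_slow5(
    path: str,
    reads: Iterable[SignalRead],
    header: RunHeader | None = None,
) -> int:
    """Append *reads* to an existing file; returns the new total count.

    Records are encoded under the file's own header.  If *header* is given
    it must equal the on-disk header.  read_id collisions with existing
    records reject the append; existing bytes are never touched.
    """
    with Slow5File(path) as fh:
        disk_header = fh.header
        if header is not None and header != disk_header:
            raise HeaderMismatchError("supplied header differs from on-disk header")
        existing = set()
        n_existing = 0
        for raw in fh.iter_raw():  # also verifies no truncation
            rec = fh.decode_record(raw)
            existing.add(rec.read_id)
            n_existing += 1
        binary = fh.dialect == "binary"

    new_records: list[bytes] = []
    for read in reads:
        if read.read_id in existing:
            raise DuplicateReadIdError(
                f"read_id {read.read_id!r} already present in {path}"
            )
        existing.add(read.read_id)
        _check_read(read, disk_header)
        if binary:
            new_records.append(_encode_record_binary(read, disk_header))
        else:
            new_records.append(_encode_record_ascii(read, disk_header).encode())
    with open(path, "ab") as out:
        for blob in new_records:
            out.write(blob)
    return n_existing + len(new_records)


def build_index(path: str, save: bool = True) -> Blow5Index:
    """Scan a binary file and build its read_id -> (offset, length) index.

    A truncated trailing record raises :class:`Slow5ParseError` reporting
    the last good offset.  By default the index is persisted as a side-car
    ``<path>.idx`` file.
    """
    entries: dict[str, tuple[int, int]] = {}
    with Slow5File(path) as fh:
        if fh.dialect != "binary":
            raise Slow5Error("indexing is defined for the binary dialect only")
        for offset, payload in fh.iter_raw():
            rec = _decode_record_binary(payload, fh.header)
            if rec.read_id in entries:
                raise DuplicateReadIdError(f"duplicate read_id {rec.read_id!r} in {path}")
            entries[rec.read_id] = (offset, len(payload))
    stat = os.stat(path)
    idx = Blow5Index(entries, str(path), stat.st_size, stat.st_mtime_ns)
    if save:
        idx.save()
    return idx


def load_index(path: str) -> Blow5Index:
    """Load the side-car index for *path*, verifying it is not stale."""
    idx_path = index_path_for(path)
    if not os.path.exists(idx_path):
        raise MissingIndexError(f"no index at {idx_path}; run `slow5pipe index {path}`")
    with open(idx_path) as fh:
        first = fh.readline().rstrip("\n")
        parts = first.split("\t")
        if parts[:2] != _INDEX_MAGIC.split("\t"):
            raise Slow5ParseError(f"bad index magic in {idx_path}")
        size, mtime_ns = int(parts[2]), int(parts[3])
        stat = os.stat(path)
        if stat.st_size != size or stat.st_mtime_ns != mtime_ns:
            raise StaleIndexError(f"index {idx_path} is stale for {path}")
        entries: dict[str, tuple[int, int]] = {}
        for line in fh:
            rid, off, length = line.rstrip("\n").split("\t")
            entries[rid] = (int(off), int(length))
    return Blow5Index(entries, str(path), size, mtime_ns)


def ensure_index(path: str) -> Blow5Index:
    """Load the side-car index, rebuilding it when missing or stale."""
    try:
        return load_index(path)
    except (MissingIndexError, StaleIndexError):
        return build_index(path, save=True)


def get_read(path: str, index: Blow5Index, read_id: str) -> SignalRead:
    """Random-access fetch of one read from a binary file via its index."""
    with Slow5File(path) as fh:
        return fh.get_read(read_id, index=index)
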