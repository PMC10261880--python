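"""Multi-read FAST5 (HDF5) reading and conversion to the binary dialect.

Only the multi-read layout is supported: one ``read_<id>`` group per read,
holding ``Raw/Signal`` (int16 samples) and a ``channel_id`` group with the
calibration quartet as attributes.  Reads missing the signal dataset or a
calibration attribute are reported per read; the remaining reads are still
returned.  Attributes with no aux-schema representation are dropped (the
lossless contract covers signal + calibration).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import h5py
import numpy as np

from .io import write_slow5
from .model import RunHeader, SignalRead, Slow5Error

__all__ = ["Fast5Error", "Fast5Contents", "read_fast5", "convert_fast5_to_blow5"]

_CALIBRATION_ATTRS = ("digitisation", "offset", "range", "sampling_rate")


class Fast5Error(Slow5Error):
    """The container or one of its read groups is unusable."""


@dataclass
class Fast5Contents:
    """Reads and per-read errors extracted from one FAST5 file."""

    path: str
    reads: List[SignalRead] = field(default_factory=list)
    errors: List[Tuple[str, str]] = field(default_factory=list)  # (group name, message)


def _read_group(fh: h5py.File, name: str, read_group: int) -> SignalRead:
    grp = fh[name]
    if "Raw" not in grp or "Signal" not in grp["Raw"]:
        raise Fast5Error(f"{name}: missing Raw/Signal dataset")
    if "channel_id" not in grp:
        raise Fast5Error(f"{name}: missing channel_id group")
    channel = grp["channel_id"]
    calib = {}
    for attr in _CALIBRATION_ATTRS:
        if attr not in channel.attrs:
            raise Fast5Error(f"{name}: missing calibration attribute {attr!r}")
        calib[attr] = float(channel.attrs[attr])
    raw_attrs = grp["Raw"].attrs
    read_id = raw_attrs["read_id"] if "read_id" in raw_attrs else name.removeprefix("read_")
    if isinstance(read_id, bytes):
        read_id = read_id.decode()
    signal = np.asarray(grp["Raw"]["Signal"][()], dtype=np.int16)
    aux = {}
    if "channel_number" in channel.attrs:
        cn = channel.attrs["channel_number"]
        aux["channel_number"] = int(cn.decode() if isinstance(cn, bytes) else cn)
    return SignalRead(
        read_id=str(read_id),
        read_group=read_group,
        digitisation=calib["digitisation"],
        offset=calib["offset"],
        range=calib["range"],
        sampling_rate=calib["sampling_rate"],
        raw_signal=signal,
        aux=aux,
    )


def read_fast5(path: str, read_group: int = 0) -> Fast5Contents:
    """Extract every read of a multi-read FAST5 file.

    Per-read failures (missing signal/calibration) are collected in
    ``errors`` keyed by HDF5 group name; the other reads are still
    yielded.  Group iteration follows HDF5 name order, which for the
    generator's zero-padded ids equals generation order.
    """
    contents = Fast5Contents(path=str(path))
    try:
        fh = h5py.File(path, "r")
    except OSError as exc:
        raise Fast5Error(f"{path}: not a readable HDF5 container: {exc}") from exc
    with fh:
        for name in fh:
            if not name.startswith("read_"):
                continue
            try:
                contents.reads.append(_read_group(fh, name, read_group))
            except Fast5Error as exc:
                contents.errors.append((name, str(exc)))
    return contents


def convert_fast5_to_blow5(
    in_paths: Sequence[str],
    out_path: str,
    record_codec: str = "zlib",
    signal_codec: str = "delta_zigzag_varint",
    strict: bool = True,
) -> int:
    """Convert one or more FAST5 files into a single binary signal file.

    Reads from the *i*-th input land in read group *i*; signals are copied
    bit-identically.  A read_id collision across inputs, or (under
    ``strict``) any per-read extraction error, rejects the conversion.
    Output is deterministic: re-running produces a byte-identical file.
    Returns the record count.
    """
    all_reads: List[SignalRead] = []
    seen: dict[str, str] = {}
    attrs = []
    for group, path in enumerate(in_paths):
        contents = read_fast5(path, read_group=group)
        if strict and contents.errors:
            detail = "; ".join(f"{g}: {m}" for g, m in contents.errors)
            raise Fast5Error(f"{path}: {len(contents.errors)} unreadable reads ({detail})")
        for read in contents.reads:
            if read.read_id in seen:
                raise Fast5Error(
                    f"read_id {read.read_id!r} appears in both "
                    f"{seen[read.read_id]} and {path}"
                )
            seen[read.read_id] = str(path)
            all_reads.append(read)
        attrs.append({"source_file": os.path.basename(str(path))})
    # conversion carries channel_number through when every read has it
    has_channel = all(("channel_number" in r.aux) for r in all_reads)
    schema = (("channel_number", "int"),) if has_channel and all_reads else ()
    if not has_channel:
        for read in all_reads:
            read.aux.pop("channel_number", None)
    header = RunHeader(
        num_read_groups=max(len(in_paths), 1),
        attributes=tuple(attrs),
        aux_schema=schema,
        record_codec=record_codec,
        signal_codec=signal_codec,
    )
    return write_slow5(out_path, header, all_reads, binary=True)
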