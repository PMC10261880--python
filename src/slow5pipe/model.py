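"""Core domain types for nanopore raw-signal data.

A nanopore device records, per read, a time series of integer ADC samples
("raw signal") together with four calibration scalars.  The picoampere
current is recovered as ``(raw + offset) * range / digitisation``.  These
types carry that data between the file layer, the batching layer and the
basecall pipeline; they do no I/O themselves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np

__all__ = [
    "AUX_TYPES",
    "RECORD_CODECS",
    "SIGNAL_CODECS",
    "Slow5Error",
    "ValidationError",
    "CalibrationError",
    "AuxSchemaError",
    "RunHeader",
    "SignalRead",
    "BasecallResult",
    "PipelineConfig",
    "to_pA",
]

#: auxiliary-field value types supported by the aux schema
AUX_TYPES = ("int", "float", "str")
#: whole-record compression codecs (binary dialect only)
RECORD_CODECS = ("none", "zlib", "zstd")
#: raw-signal codecs (binary dialect only)
SIGNAL_CODECS = ("none", "delta_zigzag_varint")

_INT16_MIN, _INT16_MAX = -32768, 32767


class Slow5Error(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(Slow5Error):
    """A domain object violates one of its invariants."""


class CalibrationError(Slow5Error):
    """Signal calibration scalars are unusable (e.g. digitisation <= 0)."""


class AuxSchemaError(Slow5Error):
    """Auxiliary values do not conform to the file's aux schema."""


def _check_name(name: str, what: str) -> None:
    if not name or "\t" in name or "\n" in name:
        raise ValidationError(f"{what} must be non-empty and contain no tab/newline: {name!r}")


@dataclass(frozen=True)
class RunHeader:
    """Per-file metadata: read groups, attributes, aux schema and codecs.

    Parameters
    ----------
    num_read_groups:
        Number of read groups (acquisition runs) in the file, >= 1.
    attributes:
        One ordered ``{name: value}`` map per read group.  If fewer maps
        than ``num_read_groups`` are given, the remainder are empty.
    aux_schema:
        Ordered ``(field_name, field_type)`` pairs describing auxiliary
        per-read columns; types are ``int``, ``float`` or ``str``.
    record_codec, signal_codec:
        Compression applied to binary records / raw-signal payloads.
        Recorded (and round-tripped) by the ASCII dialect but only applied
        by the binary one.
    """

    num_read_groups: int = 1
    attributes: tuple = ()
    aux_schema: tuple = ()
    record_codec: str = "zlib"
    signal_codec: str = "delta_zigzag_varint"

    def __post_init__(self) -> None:
        if self.num_read_groups < 1:
            raise ValidationError("num_read_groups must be >= 1")
        attrs = tuple(dict(a) for a in self.attributes)
        if len(attrs) > self.num_read_groups:
            raise ValidationError(
                f"{len(attrs)} attribute maps for {self.num_read_groups} read groups"
            )
        attrs = attrs + tuple({} for _ in range(self.num_read_groups - len(attrs)))
        for amap in attrs:
            for k, v in amap.items():
                _check_name(k, "attribute name")
                if "\t" in str(v) or "\n" in str(v):
                    raise ValidationError(f"attribute value contains tab/newline: {v!r}")
        schema = tuple((str(n), str(t)) for n, t in self.aux_schema)
        seen: set[str] = set()
        for name, typ in schema:
            _check_name(name, "aux field name")
            if name in seen:
                raise ValidationError(f"duplicate aux field name {name!r}")
            seen.add(name)
            if typ not in AUX_TYPES:
                raise ValidationError(f"unknown aux type {typ!r} (expected one of {AUX_TYPES})")
        if self.record_codec not in RECORD_CODECS:
            raise ValidationError(f"unknown record codec {self.record_codec!r}")
        if self.signal_codec not in SIGNAL_CODECS:
            raise ValidationError(f"unknown signal codec {self.signal_codec!r}")
        object.__setattr__(self, "attributes", attrs)
        object.__setattr__(self, "aux_schema", schema)

    def validate_aux(self, aux: Mapping[str, Any]) -> None:
        """Raise :class:`AuxSchemaError` unless *aux* matches the schema exactly."""
        names = [n for n, _ in self.aux_schema]
        missing = [n for n in names if n not in aux]
        extra = [k for k in aux if k not in names]
        if missing or extra:
            raise AuxSchemaError(f"aux fields mismatch: missing={missing} unexpected={extra}")
        for name, typ in self.aux_schema:
            val = aux[name]
            if typ == "int" and not isinstance(val, (int, np.integer)):
                raise AuxSchemaError(f"aux field {name!r} expects int, got {type(val).__name__}")
            if typ == "float" and not isinstance(val, (int, float, np.floating)):
                raise AuxSchemaError(f"aux field {name!r} expects float, got {type(val).__name__}")
            if typ == "str":
                if not isinstance(val, str):
                    raise AuxSchemaError(f"aux field {name!r} expects str, got {type(val).__name__}")
                if "\t" in val or "\n" in val:
                    raise AuxSchemaError(f"aux field {name!r} contains tab/newline")


@dataclass
class SignalRead:
    """One raw-signal read: identifier, calibration quartet, samples, aux fields.

    ``raw_signal`` is held as a 16-bit signed integer array (the nanopore
    ADC width); out-of-range input values are rejected at construction.
    """

    read_id: str
    read_group: int
    digitisation: float
    offset: float
    range: float
    sampling_rate: float
    raw_signal: np.ndarray
    aux: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.read_id or any(c.isspace() for c in self.read_id):
            raise ValidationError(f"read_id must be non-empty with no whitespace: {self.read_id!r}")
        if self.read_group < 0:
            raise ValidationError("read_group must be >= 0")
        if not self.digitisation > 0:
            raise CalibrationError(f"digitisation must be > 0, got {self.digitisation}")
        if not self.range > 0:
            raise ValidationError(f"range must be > 0, got {self.range}")
        if not self.sampling_rate > 0:
            raise ValidationError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        sig = np.asarray(self.raw_signal)
        if sig.dtype != np.int16:
            as64 = np.asarray(sig, dtype=np.int64)
            if as64.size and (as64.min() < _INT16_MIN or as64.max() > _INT16_MAX):
                raise ValidationError("raw_signal sample outside 16-bit signed range")
            sig = as64.astype(np.int16)
        self.raw_signal = sig
        self.aux = dict(self.aux)

    def __len__(self) -> int:
        return int(self.raw_signal.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignalRead):
            return NotImplemented
        return (
            self.read_id == other.read_id
            and self.read_group == other.read_group
            and self.digitisation == other.digitisation
            and self.offset == other.offset
            and self.range == other.range
            and self.sampling_rate == other.sampling_rate
            and np.array_equal(self.raw_signal, other.raw_signal)
            and self.aux == other.aux
        )


def to_pA(read: SignalRead) -> np.ndarray:
    """Convert a read's raw ADC samples to picoamperes.

    Uses the standard nanopore calibration
    ``pA[i] = (raw[i] + offset) * range / digitisation``.
    """
    if not read.digitisation > 0:
        raise CalibrationError(f"digitisation must be > 0, got {read.digitisation}")
    return (read.raw_signal.astype(np.float64) + read.offset) * (read.range / read.digitisation)


@dataclass(frozen=True)
class BasecallResult:
    """Basecaller output for one read: sequence, per-base phred scores, mean qscore."""

    read_id: str
    sequence: str
    qualities: tuple
    mean_qscore: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "qualities", tuple(int(q) for q in self.qualities))
        if len(self.qualities) != len(self.sequence):
            raise ValidationError(
                f"{len(self.qualities)} qualities for {len(self.sequence)} bases"
            )
        if set(self.sequence) - set("ACGT"):
            raise ValidationError(f"sequence contains non-ACGT characters: {self.read_id}")
        if any(q < 0 for q in self.qualities):
            raise ValidationError("negative phred score")
        if not math.isnan(self.mean_qscore) and self.mean_qscore < 0:
            raise ValidationError("mean_qscore must be >= 0 (or NaN for empty calls)")


@dataclass(frozen=True)
class PipelineConfig:
    """Batching/queue/worker parameters of the basecall dispatch pipeline.

    Mirrors the command-line surface of server/client basecall wrappers:
    ``guppy_batchsize`` reads are submitted to the server at a time,
    the server queue holds at most ``max_queued_reads`` pending + in-flight
    reads, ``slow5_threads``/``slow5_batchsize`` control file decoding, and
    ``procs`` workers move data to and from the server.
    """

    guppy_batchsize: int = 4000
    max_queued_reads: int = 20000
    slow5_threads: int = 4
    slow5_batchsize: int = 4096
    procs: int = 4
    qscore_threshold: float | None = None
    output_format: str = "fastq"

    def __post_init__(self) -> None:
        for name in ("guppy_batchsize", "max_queued_reads", "slow5_threads",
                     "slow5_batchsize", "procs"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be a positive integer")
        if self.guppy_batchsize > self.max_queued_reads:
            raise ValidationError("guppy_batchsize must be <= max_queued_reads")
        if self.qscore_threshold is not None and self.qscore_threshold < 0:
            raise ValidationError("qscore_threshold must be >= 0")
        if self.output_format not in ("fastq", "sam"):
            raise ValidationError(f"output_format must be 'fastq' or 'sam', got {self.output_format!r}")
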