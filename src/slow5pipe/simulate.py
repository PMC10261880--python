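"""Deterministic synthetic nanopore-signal generator.

Emulates a drastically simplified pore: each base produces a fixed current
level (the four levels are well separated), held for a constant dwell of
``D`` samples, with additive Gaussian noise.  Ground-truth sequences are
kept alongside so downstream basecalls can be scored exactly.  This is
intentionally much simpler than a real pore — no k-mer context, no dwell
time distribution, no adapter/stall artefacts — so that the matching mock
basecaller's behaviour is analytically predictable.

Everything is reproducible from ``MockModel.seed``; fixture files written
twice with the same seed are byte-identical.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .io import write_slow5
from .model import RunHeader, SignalRead, ValidationError

__all__ = ["MockModel", "default_header", "generate_reads", "write_fixture", "write_fasta"]

_BASES = "ACGT"
_INT16_MIN, _INT16_MAX = -32768, 32767

#: aux columns the generator populates (exercises generic aux plumbing)
AUX_SCHEMA = (
    ("channel_number", "int"),
    ("read_number", "int"),
    ("start_time", "int"),
    ("median_before", "float"),
)


@dataclass(frozen=True)
class MockModel:
    """Pore-level signal model plus ADC calibration.

    Default levels 80/100/120/140 pA give a 20 pA spacing; with the default
    noise sd of 2 pA a 10-sample window median essentially never crosses the
    10 pA decision boundary, so basecall recovery is near-certain.
    Calibration defaults are plausible nanopore-era constants fixed for
    reproducibility.
    """

    level_pA: dict = field(
        default_factory=lambda: {"A": 80.0, "C": 100.0, "G": 120.0, "T": 140.0}
    )
    dwell: int = 10
    noise_sd: float = 2.0
    digitisation: float = 8192.0
    offset: float = 10.0
    range: float = 1402.882
    sampling_rate: float = 4000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.level_pA) != set(_BASES):
            raise ValidationError("level_pA must define exactly A, C, G, T")
        levels = sorted(self.level_pA.values())
        if min(b - a for a, b in zip(levels, levels[1:])) <= 0:
            raise ValidationError("pA levels must be pairwise distinct")
        if self.dwell < 1:
            raise ValidationError("dwell must be >= 1")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")

    @property
    def levels(self) -> np.ndarray:
        """Levels in base-alphabetical order (A, C, G, T)."""
        return np.array([self.level_pA[b] for b in _BASES], dtype=np.float64)

    def pa_to_raw(self, pa: np.ndarray) -> np.ndarray:
        raw = np.rint(np.asarray(pa) * self.digitisation / self.range - self.offset)
        return np.clip(raw, _INT16_MIN, _INT16_MAX).astype(np.int16)


def default_header(model: MockModel, num_read_groups: int = 1) -> RunHeader:
    attrs = tuple(
        {
            "run_id": f"synthetic-run-{g}",
            "instrument": "slow5pipe-simulator",
            "sample_frequency": repr(float(model.sampling_rate)),
        }
        for g in range(num_read_groups)
    )
    return RunHeader(num_read_groups=num_read_groups, attributes=attrs, aux_schema=AUX_SCHEMA)


def _draw_length(length_distribution, rng: np.random.Generator) -> int:
    if isinstance(length_distribution, int):
        return length_distribution
    if callable(length_distribution):
        return int(length_distribution(rng))
    lo, hi = length_distribution
    return int(rng.integers(lo, hi + 1))


def generate_reads(
    n: int,
    length_distribution,
    model: MockModel,
    read_group: int = 0,
    id_prefix: str = "sim",
    id_start: int = 0,
) -> list:
    """Generate ``n`` reads; returns ``[(SignalRead, ground_truth_seq), ...]``.

    ``length_distribution`` is a fixed int, an inclusive ``(lo, hi)`` range,
    or a callable ``rng -> int``.  Sequences are uniform over ACGT; the
    signal is ``dwell`` samples per base at the base's pA level plus
    Gaussian noise, converted to raw ADC integers by inverting the standard
    calibration and rounding (clipped to the int16 range).
    """
    # fail early if the model's levels cannot be represented after calibration
    raw_levels = np.rint(model.levels * model.digitisation / model.range - model.offset)
    if raw_levels.min() < _INT16_MIN or raw_levels.max() > _INT16_MAX:
        raise ValidationError("model pA level outside representable 16-bit raw range")
    rng = np.random.default_rng(model.seed)
    levels = model.levels
    out = []
    for i in range(n):
        length = _draw_length(length_distribution, rng)
        base_idx = rng.integers(0, 4, size=length)
        pa = np.repeat(levels[base_idx], model.dwell)
        if model.noise_sd > 0:
            pa = pa + rng.normal(0.0, model.noise_sd, size=pa.size)
        aux = {
            "channel_number": int(rng.integers(1, 513)),
            "read_number": id_start + i,
            "start_time": (id_start + i) * 4000,
            "median_before": float(np.round(rng.normal(250.0, 20.0), 3)),
        }
        read = SignalRead(
            read_id=f"{id_prefix}_{id_start + i:06d}",
            read_group=read_group,
            digitisation=model.digitisation,
            offset=model.offset,
            range=model.range,
            sampling_rate=model.sampling_rate,
            raw_signal=model.pa_to_raw(pa),
            aux=aux,
        )
        out.append((read, "".join(_BASES[j] for j in base_idx)))
    return out


def write_fasta(reads_with_truth: Iterable, path: str) -> int:
    """Write ground-truth sequences as FASTA keyed by read_id."""
    records = [
        SeqRecord(Seq(seq), id=read.read_id, description="")
        for read, seq in reads_with_truth
    ]
    return SeqIO.write(records, path, "fasta")


def _write_fast5(reads: Sequence[SignalRead], path: str) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        fh.attrs["file_type"] = "multi-read"
        fh.attrs["file_version"] = "2.2"
        for read in reads:
            grp = fh.create_group(f"read_{read.read_id}")
            raw = grp.create_group("Raw")
            raw.create_dataset(
                "Signal", data=read.raw_signal, dtype="<i2", track_times=False
            )
            raw.attrs["read_id"] = read.read_id
            ch = grp.create_group("channel_id")
            ch.attrs["digitisation"] = float(read.digitisation)
            ch.attrs["offset"] = float(read.offset)
            ch.attrs["range"] = float(read.range)
            ch.attrs["sampling_rate"] = float(read.sampling_rate)
            if "channel_number" in read.aux:
                ch.attrs["channel_number"] = str(read.aux["channel_number"])


def write_fixture(
    reads_with_truth: Sequence,
    out_dir: str,
    formats: Iterable[str] = ("slow5", "blow5", "fast5"),
    stem: str = "reads",
    header: RunHeader | None = None,
    model: MockModel | None = None,
) -> dict:
    """Write the reads in the requested formats plus a ground-truth FASTA.

    Returns ``{format_or_"fasta": path}``.  Output is deterministic: the
    same reads produce byte-identical files on every call.
    """
    formats = list(formats)
    unknown = set(formats) - {"slow5", "blow5", "fast5"}
    if unknown:
        raise ValueError(f"unknown fixture formats: {sorted(unknown)}")
    os.makedirs(out_dir, exist_ok=True)
    if header is None:
        header = default_header(model or MockModel())
    reads = [r for r, _ in reads_with_truth]
    paths: dict[str, str] = {}
    if "slow5" in formats:
        p = os.path.join(out_dir, stem + ".slow5")
        write_slow5(p, header, reads, binary=False)
        paths["slow5"] = p
    if "blow5" in formats:
        p = os.path.join(out_dir, stem + ".blow5")
        write_slow5(p, header, reads, binary=True)
        paths["blow5"] = p
    if "fast5" in formats:
        p = os.path.join(out_dir, stem + ".fast5")
        _write_fast5(reads, p)
        paths["fast5"] = p
    fasta = os.path.join(out_dir, stem + ".fasta")
    write_fasta(reads_with_truth, fasta)
    paths["fasta"] = fasta
    return paths
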