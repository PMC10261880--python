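"""FASTQ / unaligned-SAM emission and mean-qscore pass/fail splitting.

FASTQ records are four lines with phred+33 quality characters.  SAM
records are unmapped (flag 4, no reference), written and parsed through
pysam, and carry the read's mean qscore twice: rounded half-up in the
integer ``qs`` tag and at full precision in the float ``mq`` tag, so a
later split is reproducible from either.  Sequences and qualities survive
a round trip through either format losslessly.

The standalone splitter routes existing FASTQ/SAM records byte-identically
(pure routing, no re-serialization).
"""

from __future__ import annotations

import logging
import math
import os
from typing import Iterable, List, Sequence, Tuple

import pysam

from .model import BasecallResult, Slow5Error
from .pipeline import mean_qscore

__all__ = [
    "encode_qualities",
    "decode_qualities",
    "write_fastq",
    "read_fastq",
    "write_sam",
    "read_sam",
    "split_by_qscore",
    "split_qscore_tool",
]

logger = logging.getLogger(__name__)

QMAX = 93  # highest phred value encodable as printable phred+33


class RecordFormatError(Slow5Error):
    """Malformed FASTQ/SAM record encountered while splitting."""


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def encode_qualities(qualities: Sequence[int]) -> str:
    """Phred scores -> phred+33 string; values outside [0, 93] are clamped
    (with a logged count)."""
    clamped = 0
    chars = []
    for q in qualities:
        qq = int(q)
        if qq < 0 or qq > QMAX:
            qq = min(max(qq, 0), QMAX)
            clamped += 1
        chars.append(chr(qq + 33))
    if clamped:
        logger.warning("clamped %d quality values into [0, %d]", clamped, QMAX)
    return "".join(chars)


def decode_qualities(text: str) -> Tuple[int, ...]:
    return tuple(ord(c) - 33 for c in text)


def write_fastq(results: Iterable[BasecallResult], path: str) -> int:
    """Write 4-line FASTQ records; returns the record count."""
    n = 0
    with open(path, "w") as fh:
        for res in results:
            fh.write(f"@{res.read_id}\n{res.sequence}\n+\n{encode_qualities(res.qualities)}\n")
            n += 1
    return n


def read_fastq(path: str) -> List[BasecallResult]:
    """Parse a FASTQ file back into results (mean qscore recomputed)."""
    out: List[BasecallResult] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if len(lines) % 4:
        raise RecordFormatError(f"{path}: line count {len(lines)} not a multiple of 4")
    for i in range(0, len(lines), 4):
        head, seq, plus, qual = lines[i:i + 4]
        if not head.startswith("@") or not plus.startswith("+"):
            raise RecordFormatError(f"{path}: malformed record at index {i // 4}")
        quals = decode_qualities(qual)
        mq = mean_qscore(quals) if quals else float("nan")
        out.append(BasecallResult(head[1:].split()[0], seq, quals, mq))
    return out


_SAM_HEADER = {"HD": {"VN": "1.6", "SO": "unknown"}}


def write_sam(results: Iterable[BasecallResult], path: str) -> int:
    """Write unaligned SAM (flag 4, no RNAME/POS/CIGAR); returns the count."""
    n = 0
    header = pysam.AlignmentHeader.from_dict(_SAM_HEADER)
    with pysam.AlignmentFile(path, "w", header=header) as fh:
        for res in results:
            seg = pysam.AlignedSegment(header)
            seg.query_name = res.read_id
            seg.flag = 4
            seg.query_sequence = res.sequence
            seg.query_qualities = pysam.qualitystring_to_array(
                encode_qualities(res.qualities)
            )
            if not math.isnan(res.mean_qscore):
                seg.set_tag("qs", _round_half_up(res.mean_qscore), "i")
                seg.set_tag("mq", float(res.mean_qscore), "f")
            fh.write(seg)
            n += 1
    return n


def read_sam(path: str) -> List[BasecallResult]:
    """Parse unaligned SAM back into results (stored mean-qscore tag trusted,
    recomputed when absent)."""
    out: List[BasecallResult] = []
    with pysam.AlignmentFile(path, "r", check_sq=False) as fh:
        for seg in fh.fetch(until_eof=True):
            seq = seg.query_sequence or ""
            quals = tuple(int(q) for q in (seg.query_qualities or ()))
            if seg.has_tag("mq"):
                mq = float(seg.get_tag("mq"))
            elif seg.has_tag("qs"):
                mq = float(seg.get_tag("qs"))
            else:
                mq = mean_qscore(quals) if quals else float("nan")
            out.append(BasecallResult(seg.query_name, seq, quals, mq))
    return out


def split_by_qscore(
    results: Iterable[BasecallResult], threshold: float
) -> Tuple[List[BasecallResult], List[BasecallResult]]:
    """Partition results into (pass, fail): pass iff mean_qscore >= threshold.

    NaN mean qscores (empty calls) go to fail.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    passed: List[BasecallResult] = []
    failed: List[BasecallResult] = []
    for res in results:
        if not math.isnan(res.mean_qscore) and res.mean_qscore >= threshold:
            passed.append(res)
        else:
            failed.append(res)
    return passed, failed


# ---------------------------------------------------------------------------
# standalone re-splitting tool: pure routing of existing records


def _sniff_format(path: str) -> str:
    ext = os.path.splitext(path)[1].lower()
    if ext in (".fastq", ".fq"):
        return "fastq"
    if ext == ".sam":
        return "sam"
    with open(path) as fh:
        first = fh.readline()
    return "sam" if first.startswith("@HD") or "\t" in first else "fastq"


def _fastq_record_qscore(record_lines: Sequence[str], index: int) -> float:
    if len(record_lines) < 4 or not record_lines[0].startswith("@") \
            or not record_lines[2].startswith("+"):
        raise RecordFormatError(f"malformed FASTQ record at index {index}")
    quals = decode_qualities(record_lines[3].rstrip("\n"))
    if not quals:
        return float("nan")
    return mean_qscore(quals)


def _sam_record_qscore(line: str, index: int, recompute: bool) -> float:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 11:
        raise RecordFormatError(f"malformed SAM record at index {index}")
    if not recompute:
        for field in fields[11:]:
            if field.startswith("mq:f:"):
                return float(field[5:])
        for field in fields[11:]:
            if field.startswith("qs:i:"):
                return float(field[5:])
    qual = fields[10]
    if qual == "*" or not qual:
        return float("nan")
    return mean_qscore(decode_qualities(qual))


def split_qscore_tool(
    input_path: str,
    threshold: float,
    out_prefix: str,
    fmt: str | None = None,
    recompute: bool = False,
) -> Tuple[int, int]:
    """Split an existing FASTQ or unaligned-SAM file at *threshold*.

    Writes ``<out_prefix>.pass.<ext>`` and ``<out_prefix>.fail.<ext>``;
    records are copied byte-identically.  For FASTQ the mean qscore is
    recomputed from per-base qualities; for SAM the stored ``mq``/``qs``
    tag is trusted unless ``recompute`` is set.  Returns (n_pass, n_fail);
    on a malformed record both outputs are removed before the error
    propagates.
    """
    fmt = fmt or _sniff_format(input_path)
    if fmt not in ("fastq", "sam"):
        raise ValueError(f"unknown format {fmt!r}")
    ext = "fastq" if fmt == "fastq" else "sam"
    pass_path = f"{out_prefix}.pass.{ext}"
    fail_path = f"{out_prefix}.fail.{ext}"
    n_pass = n_fail = 0
    try:
        with open(input_path) as src, open(pass_path, "w") as pfh, open(fail_path, "w") as ffh:
            if fmt == "fastq":
                record: list[str] = []
                index = 0
                for line in src:
                    record.append(line)
                    if len(record) == 4:
                        mq = _fastq_record_qscore(record, index)
                        target = pfh if (not math.isnan(mq) and mq >= threshold) else ffh
                        target.writelines(record)
                        if target is pfh:
                            n_pass += 1
                        else:
                            n_fail += 1
                        record = []
                        index += 1
                if record:
                    raise RecordFormatError(
                        f"truncated FASTQ record at index {index}"
                    )
            else:
                index = 0
                for line in src:
                    if line.startswith("@"):  # header lines go to both outputs
                        pfh.write(line)
                        ffh.write(line)
                        continue
                    if not line.strip():
                        continue
                    mq = _sam_record_qscore(line, index, recompute)
                    target = pfh if (not math.isnan(mq) and mq >= threshold) else ffh
                    target.write(line)
                    if target is pfh:
                        n_pass += 1
                    else:
                        n_fail += 1
                    index += 1
    except Exception:
        for p in (pass_path, fail_path):
            if os.path.exists(p):
                os.unlink(p)
        raise
    return n_pass, n_fail
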