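"""Access-pattern benchmarks: sequential streaming vs indexed random access.

Sequential mode streams batches in one forward pass; random mode visits
every read once in a seeded shuffled order via the index.  Both decode the
identical record multiset, so any throughput difference is purely the
access pattern.  The machine-independent evidence is the instrumented I/O
counters: random access performs one repositioning seek per record while
sequential access needs at most a constant few, regardless of OS caching.
Wall-clock throughputs are reported but are hardware-dependent and never a
contract.
"""

from __future__ import annotations

import threading
import time
from dataclasses import dataclass, field
from typing import List, Sequence

import numpy as np

from .batch import stream_batches
from .io import Slow5File, load_index
from .model import Slow5Error

__all__ = ["AccessStats", "ParallelStats", "bench_access", "bench_parallel"]


@dataclass
class AccessStats:
    """Result of one full-file scan under one access mode."""

    mode: str
    n_reads: int
    seconds: float
    reads_per_second: float
    bytes_read: int
    seek_count: int
    read_ids: List[str] = field(default_factory=list, repr=False)

    def as_tsv_row(self) -> str:
        return "\t".join(
            str(v)
            for v in (
                self.mode,
                self.n_reads,
                f"{self.reads_per_second:.1f}",
                self.seek_count,
                self.bytes_read,
            )
        )


def bench_access(
    path: str,
    mode: str,
    batchsize: int = 4096,
    threads: int = 1,
    seed: int = 0,
) -> AccessStats:
    """Decode every record of an indexed binary file under one access mode.

    ``sequential`` streams batches; ``random`` shuffles the indexed
    read_ids with *seed* and fetches each via the index.  Random mode
    requires an existing side-car index (build one with ``slow5pipe
    index``).
    """
    if mode not in ("sequential", "random"):
        raise ValueError(f"mode must be 'sequential' or 'random', got {mode!r}")
    if mode == "random":
        index = load_index(path)  # raises MissingIndexError with instructions
    read_ids: List[str] = []
    start = time.perf_counter()
    with Slow5File(path, count_io=True) as fh:
        if mode == "sequential":
            for batch in stream_batches(fh, batchsize, threads):
                read_ids.extend(r.read_id for r in batch.reads)
        else:
            order = list(index.entries)
            rng = np.random.default_rng(seed)
            rng.shuffle(order)
            fh.attach_index(index)
            for rid in order:
                read_ids.append(fh.get_read(rid).read_id)
        seconds = time.perf_counter() - start
        stats = AccessStats(
            mode=mode,
            n_reads=len(read_ids),
            seconds=seconds,
            reads_per_second=len(read_ids) / seconds if seconds > 0 else float("inf"),
            bytes_read=fh.bytes_read,
            seek_count=fh.seek_count,
            read_ids=read_ids,
        )
    return stats


@dataclass
class ParallelStats:
    """k identical jobs run concurrently, one per file copy."""

    mode: str
    jobs: int
    baseline_seconds: float
    per_job: List[AccessStats]
    #: mean concurrent per-job time over the single-job baseline time
    slowdown_ratio: float


def bench_parallel(
    paths: Sequence[str],
    mode: str,
    jobs: int,
    batchsize: int = 4096,
    threads: int = 1,
    seed: int = 0,
) -> ParallelStats:
    """Run *jobs* concurrent :func:`bench_access` scans, one per file copy.

    Requires at least *jobs* independent copies (so jobs do not share a
    file).  A single-job baseline on the first copy is measured first;
    ``slowdown_ratio`` is mean(concurrent job time) / baseline time.
    """
    if jobs < 1:
        raise ValueError("jobs must be >= 1")
    if len(paths) < jobs:
        raise Slow5Error(
            f"{jobs} jobs need {jobs} independent file copies, got {len(paths)}"
        )
    baseline = bench_access(paths[0], mode, batchsize, threads, seed)

    results: List[AccessStats | None] = [None] * jobs
    errors: List[BaseException] = []

    def run(i: int) -> None:
        try:
            results[i] = bench_access(paths[i], mode, batchsize, threads, seed + i)
        except BaseException as exc:  # surfaced after join
            errors.append(exc)

    workers = [threading.Thread(target=run, args=(i,)) for i in range(jobs)]
    for w in workers:
        w.start()
    for w in workers:
        w.join()
    if errors:
        raise errors[0]
    per_job = [r for r in results if r is not None]
    mean_time = float(np.mean([r.seconds for r in per_job]))
    ratio = mean_time / baseline.seconds if baseline.seconds > 0 else float("nan")
    return ParallelStats(
        mode=mode,
        jobs=jobs,
        baseline_seconds=baseline.seconds,
        per_job=per_job,
        slowdown_ratio=ratio,
    )
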