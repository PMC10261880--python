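"""Basecall dispatch pipeline: bounded server queue, workers, mock backend.

The workflow mirrors a server/client basecall wrapper:

1. start the basecall server (in-process, bounded queue);
2. connect a client;
3. stream read batches sequentially from the signal file;
4. submit reads in chunks of ``guppy_batchsize``, blocking while the server
   already holds ``max_queued_reads`` pending + in-flight reads;
5. collect results with ``procs`` workers and write FASTQ/SAM, optionally
   split into pass/fail files by mean qscore.

The neural-network basecaller itself is replaced by a pluggable backend
interface; the bundled :class:`MockBasecaller` inverts the synthetic
generator's signal model (window median -> nearest pore level), which makes
end-to-end sequence recovery exactly scorable.
"""

from __future__ import annotations

import logging
import math
import os
import threading
from concurrent.futures import Future, ThreadPoolExecutor
from dataclasses import dataclass
from typing import Iterable, List, Protocol, Sequence

import numpy as np

from .batch import stream_batches
from .model import BasecallResult, PipelineConfig, SignalRead, Slow5Error, to_pA
from .simulate import MockModel

__all__ = [
    "BasecallerBackend",
    "MockBasecaller",
    "BasecallServer",
    "PipelineError",
    "PipelineSummary",
    "mean_qscore",
    "mock_basecall",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

_BASES = "ACGT"


class PipelineError(Slow5Error):
    """A batch failed inside the basecall pipeline."""


def mean_qscore(qualities: Sequence[int]) -> float:
    """Mean read qscore: the phred transform of the mean per-base error
    probability, ``-10*log10(mean_i 10^(-q_i/10))``.

    This is the convention of production basecallers (and is monotone in
    the error rate), *not* the arithmetic mean of the per-base scores.
    """
    q = np.asarray(qualities, dtype=np.float64)
    if q.size == 0:
        raise ValueError("mean_qscore is undefined for an empty quality vector")
    return float(-10.0 * np.log10(np.mean(np.power(10.0, -q / 10.0))))


class BasecallerBackend(Protocol):
    """Anything that turns signal reads into basecalls, one result per read.

    Implementations must be pure functions of the input signal for fixed
    backend parameters: the same read always yields the same result.
    """

    name: str

    def call(self, reads: Sequence[SignalRead]) -> List[BasecallResult]: ...


def mock_basecall(read: SignalRead, model: MockModel) -> BasecallResult:
    """Decode one read under the simulator's signal model.

    The pA trace is cut into consecutive windows of ``model.dwell`` samples
    (a trailing remainder shorter than one dwell is discarded, logged); each
    window's median is assigned the nearest pore level, ties going to the
    lexicographically smaller base.  Per-base quality is the margin between
    the distances to the second-nearest and nearest level in pA, clamped to
    [2, 40].
    """
    pa = to_pA(read)
    dwell = model.dwell
    n_windows = pa.size // dwell
    remainder = pa.size - n_windows * dwell
    if remainder:
        logger.debug("read %s: discarding %d trailing samples (< dwell %d)",
                     read.read_id, remainder, dwell)
    if n_windows == 0:
        return BasecallResult(read.read_id, "", (), float("nan"))
    medians = np.median(pa[: n_windows * dwell].reshape(n_windows, dwell), axis=1)
    levels = model.levels  # base-alphabetical order => argmin tie-break is lexicographic
    dist = np.abs(medians[:, None] - levels[None, :])
    nearest = np.argmin(dist, axis=1)
    two = np.sort(dist, axis=1)[:, :2]
    margin = two[:, 1] - two[:, 0]
    quals = np.clip(np.round(margin), 2, 40).astype(int)
    seq = "".join(_BASES[i] for i in nearest)
    return BasecallResult(read.read_id, seq, tuple(quals), mean_qscore(quals))


class MockBasecaller:
    """Deterministic model-inverting backend (see :func:`mock_basecall`)."""

    def __init__(self, model: MockModel | None = None):
        self.model = model or MockModel()
        self.name = "mock"

    def call(self, reads: Sequence[SignalRead]) -> List[BasecallResult]:
        return [mock_basecall(r, self.model) for r in reads]


class BasecallServer:
    """In-process basecall server with a bounded read queue.

    ``submit`` blocks while accepting the chunk would push pending +
    in-flight reads above ``max_queued_reads``; ``procs`` worker threads
    run the backend.  ``max_occupancy`` records the high-water mark for
    the queue-bound invariant.
    """

    def __init__(self, backend: BasecallerBackend, max_queued_reads: int, procs: int):
        self.backend = backend
        self.capacity = max_queued_reads
        self._count = 0
        self.max_occupancy = 0
        self.submitted = 0
        self.completed = 0
        self._cond = threading.Condition()
        self._pool = ThreadPoolExecutor(max_workers=procs)

    def submit(self, reads: Sequence[SignalRead]) -> Future:
        k = len(reads)
        if k > self.capacity:
            raise PipelineError(
                f"chunk of {k} reads exceeds server queue capacity {self.capacity}"
            )
        with self._cond:
            while self._count + k > self.capacity:
                self._cond.wait()
            self._count += k
            self.submitted += k
            self.max_occupancy = max(self.max_occupancy, self._count)
        return self._pool.submit(self._process, list(reads))

    def _process(self, reads: List[SignalRead]) -> List[BasecallResult]:
        try:
            results = self.backend.call(reads)
            if len(results) != len(reads):
                raise PipelineError(
                    f"backend {self.backend.name!r} returned {len(results)} results "
                    f"for {len(reads)} reads"
                )
            return results
        finally:
            with self._cond:
                self._count -= len(reads)
                self.completed += len(reads)
                self._cond.notify_all()

    def shutdown(self) -> None:
        self._pool.shutdown(wait=True)


@dataclass
class PipelineSummary:
    """Counts and aggregate quality for one pipeline run."""

    reads_in: int
    reads_out: int
    mean_of_mean_qscores: float
    passed: int | None = None
    failed: int | None = None
    max_queue_occupancy: int = 0


def _split_output_paths(output_path: str) -> tuple[str, str]:
    root, ext = os.path.splitext(output_path)
    return f"{root}.pass{ext}", f"{root}.fail{ext}"


def run_pipeline(
    input_path: str,
    output_path: str,
    config: PipelineConfig,
    backend: BasecallerBackend,
    sort_output: bool = False,
) -> PipelineSummary:
    """Run the full dispatch workflow; returns a :class:`PipelineSummary`.

    Every input read appears exactly once in the output.  With
    ``config.qscore_threshold`` set, output goes to ``<root>.pass<ext>`` /
    ``<root>.fail<ext>`` instead of ``output_path``.  Record order follows
    completion order unless ``sort_output`` canonicalizes by read_id.
    """
    from . import writers  # deferred: writers imports model only, avoids cycle at import time

    # fail on unwritable output before the server starts
    targets = (
        list(_split_output_paths(output_path))
        if config.qscore_threshold is not None
        else [output_path]
    )
    for t in targets:
        with open(t, "w"):
            pass

    server = BasecallServer(backend, config.max_queued_reads, config.procs)
    futures: list[tuple[int, Future]] = []
    reads_in = 0
    results: list[BasecallResult] = []
    failed_batch: int | None = None
    try:
        chunk: list[SignalRead] = []
        chunk_index = 0
        for batch in stream_batches(
            input_path, config.slow5_batchsize, config.slow5_threads
        ):
            for read in batch.reads:
                reads_in += 1
                chunk.append(read)
                if len(chunk) == config.guppy_batchsize:
                    futures.append((chunk_index, server.submit(chunk)))
                    chunk = []
                    chunk_index += 1
        if chunk:
            futures.append((chunk_index, server.submit(chunk)))

        for idx, fut in futures:
            try:
                results.extend(fut.result())
            except Exception as exc:
                failed_batch, failed_exc = idx, exc
                break
    finally:
        server.shutdown()

    if failed_batch is not None:
        # drain results of chunks that did complete cleanly after the failure
        for idx, fut in futures[failed_batch + 1:]:
            if fut.done() and fut.exception() is None:
                results.extend(fut.result())
        writer = writers.write_fastq if config.output_format == "fastq" else writers.write_sam
        writer(results, targets[0])
        raise PipelineError(f"backend failed on batch {failed_batch}: {failed_exc}") from failed_exc

    if sort_output:
        results.sort(key=lambda r: r.read_id)

    if config.qscore_threshold is not None:
        passed, failed = writers.split_by_qscore(results, config.qscore_threshold)
        writer = writers.write_fastq if config.output_format == "fastq" else writers.write_sam
        writer(passed, targets[0])
        writer(failed, targets[1])
        n_pass, n_fail = len(passed), len(failed)
    else:
        writer = writers.write_fastq if config.output_format == "fastq" else writers.write_sam
        writer(results, output_path)
        n_pass = n_fail = None

    finite = [r.mean_qscore for r in results if not math.isnan(r.mean_qscore)]
    mean_of_means = float(np.mean(finite)) if finite else float("nan")
    return PipelineSummary(
        reads_in=reads_in,
        reads_out=len(results),
        mean_of_mean_qscores=mean_of_means,
        passed=n_pass,
        failed=n_fail,
        max_queue_occupancy=server.max_occupancy,
    )
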