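"""Sequential, batched, parallel-decode read streaming.

Raw record bytes are fetched in one forward pass over the file; decoding
(decompression + parsing) of each batch may be spread over a thread pool.
The thread count is observable only as speed: output order and content are
identical for any ``slow5_threads`` value.  At most one batch is being
decoded ahead of the one handed to the consumer, so memory stays bounded
for genome-scale files.
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass
from typing import Iterator, List

from .io import Slow5File
from .model import SignalRead, Slow5Error

__all__ = ["ReadBatch", "stream_batches"]


class BatchDecodeError(Slow5Error):
    """A record inside one batch failed to decode."""

    def __init__(self, batch_index: int, offset, cause: Exception):
        self.batch_index = batch_index
        self.offset = offset
        super().__init__(
            f"corrupt record in batch {batch_index} (near offset {offset}): {cause}"
        )


@dataclass
class ReadBatch:
    """One batch of decoded reads; concatenating batches in ``batch_index``
    order reproduces file order exactly."""

    batch_index: int
    reads: List[SignalRead]

    def __len__(self) -> int:
        return len(self.reads)


def _chunks(iterator, size: int):
    chunk = []
    for item in iterator:
        chunk.append(item)
        if len(chunk) == size:
            yield chunk
            chunk = []
    if chunk:
        yield chunk


def stream_batches(
    source, slow5_batchsize: int = 4096, slow5_threads: int = 1
) -> Iterator[ReadBatch]:
    """Yield :class:`ReadBatch` objects covering the file exactly once, in
    file order.

    *source* is a path or an open :class:`Slow5File` (the latter lets callers
    instrument I/O).  All batches except possibly the last hold exactly
    ``slow5_batchsize`` reads.
    """
    if slow5_batchsize < 1:
        raise ValueError("slow5_batchsize must be >= 1")
    if slow5_threads < 1:
        raise ValueError("slow5_threads must be >= 1")

    own = not isinstance(source, Slow5File)
    fh = Slow5File(source) if own else source
    pool = ThreadPoolExecutor(max_workers=slow5_threads) if slow5_threads > 1 else None
    try:
        for batch_index, raws in enumerate(_chunks(fh.iter_raw(), slow5_batchsize)):
            try:
                if pool is None or len(raws) < 2 * slow5_threads:
                    reads = fh.decode_batch(raws)
                else:
                    # contiguous slices, one per thread; order preserved by map
                    step = (len(raws) + slow5_threads - 1) // slow5_threads
                    slices = [raws[i:i + step] for i in range(0, len(raws), step)]
                    reads = [r for part in pool.map(fh.decode_batch, slices) for r in part]
            except Slow5Error as exc:
                offset = raws[0][0] if isinstance(raws[0], tuple) else "?"
                raise BatchDecodeError(batch_index, offset, exc) from exc
            yield ReadBatch(batch_index, reads)
    finally:
        if pool is not None:
            pool.shutdown(wait=False)
        if own:
            fh.close()
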