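# Methods

## Data model

A signal file holds one `RunHeader` and a sequence of `SignalRead`
records. The header carries the number of read groups (acquisition runs),
one ordered attribute map per group, an ordered auxiliary-field schema
(`int`/`float`/`str` columns), and the two codec selections. Each read
carries its identifier, read-group index, the standard nanopore
calibration quartet — `digitisation` (ADC quantisation levels), `offset`
(ADC offset), `range` (pA span), `sampling_rate` (samples/s) — a 16-bit
signed integer sample array, and aux values conforming to the schema.
Current is recovered as `pA = (raw + offset) · range / digitisation`.
Every invariant (non-empty whitespace-free ids, positive calibration,
int16 sample range, schema conformance) is enforced at construction and
re-checked after deserialization.

## File dialects

**ASCII** (`.slow5`): `#`-prefixed header lines (format line, read-group
count, codec declarations, per-group `#attr` lines in insertion order,
`#aux` schema lines, a `#columns` line), then one TSV row per read with
the signal as comma-separated integers. Floats are serialized with
`repr`, which round-trips exactly. Codecs are recorded — so a header
survives a round trip unchanged — but rows are always plain text; the
ASCII dialect is sequential-only by design.

**Binary** (`.blow5`): 8-byte magic, little-endian u16 version, u32
header length, then the same header text, followed by one
`[u32 length][payload]` frame per read. The payload is the record codec's
compression of a fixed-layout core (id, group, calibration as f64,
sample count, encoded signal, aux fields). The signal codec
`delta_zigzag_varint` stores the first sample and then successive
deltas, each zigzag-mapped (0→0, −1→1, 1→2, …) and varint-coded; pore
traces are locally flat, so most deltas fit in one byte. Defaults are
`zlib` + `delta_zigzag_varint`; both can be set to `none`, and `zstd` is
available for the record layer. Both writers are byte-deterministic
(stable attribute order, no timestamps), so tests compare digests.

**Index**: a side-car `<file>.idx` maps read_id → (payload offset,
payload length). It stores the data file's size and mtime; a mismatch is
reported as staleness rather than silently serving wrong offsets
(`ensure_index` rebuilds transparently). Duplicate read ids are a hard
error everywhere — index keys must be unique. Appending re-scans the
existing file (verifying integrity and collecting ids), then only ever
appends bytes; a supplied expected header must equal the on-disk one.

## Sequential streaming and the access-pattern argument

`stream_batches` fetches raw bytes in one forward pass (4 MiB blocks)
and yields fixed-size `ReadBatch`es in file order; decoding may be
spread over `slow5_threads` contiguous slices, which is observable only
as speed — output order and content are identical for every thread
count, the stricter and testable contract.

Because sequential access delivers records in bulk, the signal codec is
decoded batch-at-a-time: the self-delimiting varint streams of a whole
batch are concatenated and decoded in a single vectorized pass, with
per-record delta cumsums recovered by subtracting the running total at
each record boundary. Random access necessarily decodes one record at a
time and pays one repositioning seek per read. These are the two
mechanisms behind the sequential-vs-random throughput gap the `bench`
module measures; the machine-independent evidence asserted by the tests
is the instrumented counters (seeks = n for random, ≤ constant for
sequential; bytes read ≤ file size), while wall-clock throughput is
reported but never asserted as a magnitude, since it depends on the
host's cache and filesystem. `bench_parallel` runs k concurrent scans on
k independent file copies and reports per-job times and the slowdown
ratio relative to a single-job baseline.

## The dispatch pipeline

`run_pipeline` realizes the server/client basecall workflow in process:
a bounded counter (capacity `max_queued_reads`) plays the server queue,
`procs` worker threads run the backend, and the client submits chunks of
`guppy_batchsize` reads, blocking while the queue is full (the config
enforces `guppy_batchsize ≤ max_queued_reads`, so submission cannot
deadlock). Pending + in-flight occupancy is instrumented and its
high-water mark reported. Completion order is inherently nondeterministic,
so `sort_output` canonicalizes by read_id for reproducible diffs. A
backend failure aborts the run after draining cleanly completed batches,
reporting the failed batch index. An in-process queue was chosen over a
TCP transport because the transport is incidental to the batching
contract; the backend interface would accommodate a socket client.

## Mock basecaller and simulator

The simulator emulates a deliberately simplified pore: each base emits a
fixed current level — defaults A=80, C=100, G=120, T=140 pA — held for a
constant dwell of D=10 samples, plus Gaussian noise (default sd 2 pA),
inverted through the calibration (defaults digitisation 8192, offset 10,
range 1402.882 pA, sampling 4 kHz — plausible nanopore-era constants
fixed for reproducibility) and rounded to int16. Sequences are uniform
over ACGT; read lengths come from a constant, an inclusive range, or a
callable. Everything derives from one integer seed; fixtures regenerate
byte-identically (FAST5 fixtures disable HDF5 timestamp tracking for the
same reason).

The mock basecaller inverts this model: convert to pA, cut into
consecutive D-sample windows (a trailing remainder shorter than D is
discarded and logged), take each window's median, assign the nearest
level, ties to the lexicographically smaller base. Per-base quality is
the margin `d₂ − d₁` between the distances to the second-nearest and
nearest level in pA, rounded (numpy round-half-even; the tie rule was an
open choice and only affects exact .5 margins) and clamped to [2, 40].
With 20 pA spacing and sd 2 pA, the median of 10 samples has a standard
error of ≈0.8 pA against a 10 pA decision boundary, so the per-base
error probability is far below 10⁻³ — near-certain recovery with a
testable margin, which is the point: correctness of the surrounding
machinery is what is under test, not basecalling realism. No k-mer
context, dwell variation, homopolymer compression, adapter/stall
artefacts or RNA signals are modelled, so passing recovery tests says
nothing about accuracy on real pore data — only that signal transport,
batching, dispatch and output are lossless and deterministic.

Mean read quality is the phred transform of the mean per-base error
probability, `−10·log₁₀(mean 10^(−q/10))` — the production-basecaller
convention, monotone in error rate — not the arithmetic mean of scores.
An empty call has no defined mean quality; it is carried as NaN and
routed to the fail file by the splitter.

## Output formats and splitting

FASTQ is written as canonical 4-line records with phred+33 qualities
(values outside [0, 93] clamped with a logged count). SAM records are
unmapped (flag 4, `*` reference/CIGAR), written and read through pysam,
with the mean qscore stored twice: rounded half-up in the integer `qs`
tag and full-precision in the float `mq` tag, so splitting is
reproducible from either. The pass boundary is inclusive
(`mean_qscore ≥ threshold` passes, matching the common q≥7 "pass"
convention). The standalone splitter is pure routing: it copies record
bytes verbatim, recomputing mean quality from FASTQ qualities and
trusting the stored SAM tag unless asked to recompute; a malformed
record removes both outputs before the error propagates.

## FAST5 interoperability

Only the multi-read HDF5 layout is read (one `read_<id>` group with
`Raw/Signal` and a `channel_id` attribute group); the legacy single-read
layout and VBZ-plugin-compressed third-party files are out of scope, and
FAST5 is never written except by the simulator's fixture writer.
Per-read extraction failures are reported by group name while the
remaining reads are still returned; strict conversion refuses files with
unreadable reads, maps each input file to its own read group, rejects
cross-file read_id collisions, and keeps `channel_number` as the one aux
column when every read carries it. Conversion output is deterministic.

## Problem sizes and numerical choices

The test suite and acceptance script use desk-scale sizes chosen to
exercise the asymptotics that matter — 1000 reads for codec round trips,
10,000 for index/sequential agreement, 100×500 bases (50,000 bases) for
pipeline recovery, 16 thread/batch configurations on 1000 reads, and
20,000–50,000 short reads for the access-pattern counters — all
generated at run time from seeds. Quantisation of the signal path
(range/digitisation ≈ 0.17 pA per ADC step) bounds round-off well below
the decision margins. Varint groups are capped at 10 bytes; truncated
streams, dangling continuation bits, out-of-range decoded samples,
corrupted magic/version/length fields and mid-file truncation each raise
distinct, located errors.

## Known limitations

Random access is defined for the binary dialect only. The in-process
server measures queueing semantics, not network transport. Thread
parallelism helps only where decoding is the bottleneck (the GIL is
released in zlib/zstd and numpy, but single-CPU hosts see no gain).
Reported throughputs and the sequential:random ratio are properties of
the host's storage stack; only the I/O-operation counters are portable
claims.
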