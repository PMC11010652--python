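# Methods

## The problem and the design

Raw nanopore signal is a per-read time series of 16-bit ADC samples.
Downstream tools address reads by **read ID** (a UUID-like string), and
a typical re-analysis touches a tiny, ID-addressed subset of a very
large file.  sigfetch therefore separates three concerns:

1. a container whose records are *independently decodable* from their
   byte extent alone;
2. a sidecar index mapping read ID → `(byte offset, byte length)` and
   recording the header's byte extent;
3. a client that turns ID lookups into HTTP Range requests.

Everything the client does reduces to one invariant, proved in the test
suite as *slice addressability*: for every record, decoding the bytes
at its indexed extent reproduces the record exactly.  Given that, a
remote fetch of one read is one range request, and the traffic for a
batch is bounded by `index size + header extent + Σ requested extents`
(the *frugality* property, asserted byte-exactly against the fixture
server's accounting).

## Container and codec

The byte layout is fixed in `FORMAT.md`.  Choices that were genuinely
open, and how they were settled:

* **Signal codec (svb-zd).**  Deltas are taken first (`d[0] = s[0]`,
  `d[i] = s[i] − s[i−1]`) in 32-bit signed arithmetic — the difference
  of two int16 always fits, so no wrap-around convention is needed.
  Zigzag (`v ≥ 0 → 2v`, `v < 0 → −2v−1`) interleaves signs so small
  magnitudes of either sign become small unsigned codes.  StreamVByte
  then stores each code in 1–4 little-endian bytes with 2-bit length
  codes packed four-per control byte.  The 32-bit lane variant was
  chosen over 16-bit lanes: it is the standard StreamVByte layout and
  removes any ambiguity for the `d[0] = s[0]` delta.  Consequence: if
  every zigzagged delta is below 256, the payload is at most
  `n + ceil(n/4)` bytes (one data byte per sample plus control bytes) —
  on realistic smooth signal about 0.62× the raw int16 size before the
  zlib layer.
* **Two independent compression layers.**  Signal compression (svb-zd)
  and whole-record compression (zlib, level 6) are separate header
  enums, each switchable to `none`.  zlib is applied to the serialized
  record *after* signal compression, so the record stays one opaque,
  self-delimiting unit.
* **Exact framing everywhere.**  No trailing-byte tolerance at any
  level (signal payload, record body, file). Corruption surfaces as an
  error naming the failing field or record ordinal instead of decoding
  to silently wrong data.
* **Determinism.**  Encoding has no timestamps, no randomness, and a
  fixed zlib level, so identical inputs give byte-identical files — the
  CLI's output is reproducible and cacheable.
* **Degenerate inputs.**  Empty files, empty signals and single-read
  files are all legal; the empty signal encodes to an empty payload.

This container is a documented dialect of the community SLOW5/BLOW5
idea, not a byte-compatible BLOW5 implementation; the index stores the
header extent precisely so a remote client can fetch and parse the
header with a single range request.

## Client semantics

* **Range discipline.**  A reply of 200 (full content) to a range
  request is an error (`RangeUnsupportedError`), never a fallback:
  silently accepting it would break the frugality guarantee on servers
  without range support.
* **Retry policy.**  Retries apply per individual range request, with a
  flat wait and no backoff.  Defaults: `retry_count = 1`,
  `retry_wait_seconds = 1` — a request that fails twice in a row is
  taken to indicate a server/connection problem and fails for good.
  404 is permanent and never retried.  Both HTTP 5xx replies and
  dropped connections take the retry path (both are exercised in
  tests).
* **Concurrency contract.**  Batches run on a thread pool capped at
  `min(n_threads, max_connections)` in-flight requests (thread-based
  I/O concurrency; the GIL is irrelevant while blocked on sockets).
  Output order is restored to input order regardless of completion
  order, so results are thread-count invariant.  The thread default is
  128: network fetching is latency-bound, so the useful thread count is
  far above the CPU count, limited mostly by server connection caps —
  `max_connections` exposes that cap, with no universal default
  ceiling.
* **Partial failure.**  In a batch, a missing ID or an exhausted-retry
  fetch marks that read failed in the `FetchReport` and the batch
  continues; the single-read call raises instead, giving callers
  per-read control.  Only a batch in which *no* requested ID exists in
  the index raises.  Duplicate input IDs are deduplicated (first
  occurrence kept) with a warning, mirroring the `sort -u` most users
  run upstream.
* **Index caching.**  A downloaded index goes to the configured cache
  path and persists there, or to a temporary file deleted when the
  session closes.  A local index path is used in place with no
  download.  No coalescing of adjacent extents is attempted: one
  request per read keeps transfers read-specific and the accounting
  exact.
* **Scope.**  http/https only; ftp and S3-native access are extension
  points, not implemented.  No authentication schemes.

## Region selection

Region syntax is 1-based inclusive (`chr1:1-1000000`), converted to the
0-based half-open convention internally; BED input is already 0-based
half-open and only its first three columns are read.  Selection is
implemented over pysam against an indexed, coordinate-sorted BAM and
returns the sorted, deduplicated query names of *all* overlapping
alignments — secondary, supplementary, duplicate-flagged and
unmapped-mate records included, because the shell pipeline
(`samtools view | cut -f1 | sort -u`) it reproduces does not filter
them.  Equivalence with both a brute-force overlap scan and the actual
shell pipeline is asserted in tests.

## Synthetic data and the network test-bed

The fixture generator emulates the *structure* of a real signal
dataset, not its biophysics:

* **Reads.**  UUID-like IDs from a seeded generator; signal lengths
  normal around a mean (default 2000 ± 500 samples, floor 1);
  per-read scaling in realistic ranges (digitisation 8192, range
  1400–1500 pA, 5 kHz sampling); a small typed auxiliary schema
  (channel, read number, start time, median_before, end reason) of the
  kind real acquisition software writes.
* **Signal models.**  `random-walk` (default) reflects an integer
  random walk (steps ≤ 120) inside a ±6000 band via a triangle map —
  the map is 1-Lipschitz, so per-sample deltas keep the step magnitude
  and the svb-zd small-delta size bound is genuinely exercised.
  `white-noise` spans the full int16 range and is nearly
  incompressible.  Neither reproduces pore-level kinetics (dwell-time
  segmentation, adapter/stall artefacts); tests passing on these
  fixtures demonstrate the *container and transport* contracts, not
  signal-analysis quality.
* **Server.**  An in-process HTTP server (thread per connection,
  listen backlog 256) with exact Range semantics, an append-only
  request log with byte counts, fixed pre-response latency injection,
  and scripted failures — transient (first *k* attempts of a request
  fail) or permanent (predicate on path/offset), delivered either as
  HTTP 503 or as a dropped connection.  Latency is injected before the
  response is written, so concurrency measurements reflect
  request-level parallelism rather than bandwidth.
* **Alignments.**  Read IDs are placed at deterministic coordinates,
  ~60% overlapping a chosen region (including boundary-straddling
  placements) and the rest in a gap zone, with one supplementary
  alignment to exercise deduplication; SAM text is written and
  converted to sorted+indexed BAM at run time, and the ground-truth
  region → ID map is returned alongside.

## Problem sizes and measured properties

The shipped checks use a 120-read shared dataset for module tests, a
500-read dataset for the remote-equals-local equivalence check, and 200
reads × 50 ms injected latency for the concurrency property (single
thread ≈ 10 s wall; 50 threads must finish in ≤ 0.25× of that —
observed ≈ 0.03×).  These sizes keep the whole suite under a minute of
compute apart from the deliberate latency runs while still exercising
every contract at meaningful scale.  `scripts/acceptance.py` recomputes
the same quantities from scratch at the same sizes; it reports, among
others, the codec round-trip rate over 1000 fuzzed arrays (100%), the
equivalence rate over 550 remote reads (100%), traffic utilisation
against the byte budget (≤ 1.0), and the measured 50-vs-1-thread
speed-up (~30× here, where nothing but latency is being hidden).

## Known limitations

* Not byte-compatible with published BLOW5 files; converting real data
  requires the community tools, then re-encoding into this dialect.
* No request coalescing: per-read requests are simple and exactly
  accountable but waste round trips when many wanted reads are
  adjacent on disk.
* The HTTP layer opens one connection per request (stdlib urllib, no
  keep-alive pooling); against high-latency real servers a pooled
  client would shave per-request TCP/TLS setup time.  The concurrency
  contract is unaffected.
* Remote *alignment* access is delegated entirely to the alignment
  library (pysam/htslib's own remote support); sigfetch only handles
  the signal side.
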