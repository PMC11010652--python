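# sigfetch

Remote random access for nanopore raw-signal data.

Nanopore sequencers record a time series of 16-bit current samples for
every molecule ("read"), and signal-level algorithms — basecalling,
methylation calling — keep improving, so raw signal is worth keeping
and re-analysing.  But a whole-genome signal dataset is ~1 TB, and
public repositories host hundreds of them: re-analysing one gene should
not require downloading a terabyte.

sigfetch implements the stack that makes targeted remote re-analysis
practical:

* **a binary signal container** (`FORMAT.md`): one framed,
  independently decodable record per read — read ID, scaling
  (digitisation, offset, range, sampling rate), raw int16 signal
  compressed with **svb-zd** (delta → zigzag → StreamVByte), the whole
  record then zlib-compressed;
* **a sidecar index** mapping every read ID to its `(byte offset, byte
  length)` extent, plus the header extent;
* **a remote client** that downloads only the index (or uses a local
  copy), then fetches each wanted read with one HTTP byte-range
  request.  Batches run hundreds of requests concurrently so
  per-request latency overlaps (for N reads on T in-flight requests the
  wall time is ≈ `ceil(N/T)·L` at latency `L`); each request is retried
  on transient failure (default: 1 retry, 1 s flat wait) and per-read
  failures are reported, not fatal;
* **region selection**: given a coordinate-sorted BAM, the read IDs
  overlapping `chr1:1-1000000` or a BED panel, exactly as
  `samtools view … | cut -f1 | sort -u` would produce them;
* **a CLI** (`sigfetch get | head | reads | index`) mirroring the
  library;
* **an instrumented test-bed** (`sigfetch.fixtures`): deterministic
  dataset generator and an in-process range server with request
  accounting, latency injection and scripted failures, so every network
  property is testable offline.

The key invariant everything rests on: *slicing the file at an indexed
extent and decoding yields exactly the record that keyed the entry* —
so a range request per read is sufficient, and total traffic for a
batch is bounded by the index, the header, and the requested extents,
never the file.

## Worked example

```python
from pathlib import Path
from sigfetch.fixtures import FixtureSpec, generate_dataset, serve
from sigfetch import RemoteSource, FetchPolicy, RemoteContainer, to_picoamperes

d = Path("demo")
manifest = generate_dataset(FixtureSpec(n_reads=500, seed=7), d)
with serve(d) as server:                       # local stand-in for a repository
    source = RemoteSource(server.url_for("reads.sfc"))   # index at <url>.idx
    with RemoteContainer(source, FetchPolicy(n_threads=32)) as remote:
        records, report = remote.get_batch(manifest.read_ids[:100])
        print("report:", report)
        rec = records[0]
        print("first read:", rec.read_id)
        print("samples:", rec.n_samples, "| sampling rate:", rec.sampling_rate, "Hz")
        pa = to_picoamperes(rec)
        print("signal (pA): mean %.2f, min %.2f, max %.2f"
              % (pa.mean(), pa.min(), pa.max()))
        remote.save(records, d / "fetched.sfc")
    print("bytes served by server:", server.behavior.bytes_served())
    print("container size on disk:", Path(manifest.container_path).stat().st_size)
```

prints

```
report: requested 100, fetched 100, retries 0, failed 0
first read: eafb0581-1088-221e-d53d-b5186fe7a532
samples: 1862 | sampling rate: 5000.0 Hz
signal (pA): mean -752.46, min -1099.55, max -470.63
bytes served by server: 244009
container size on disk: 1072310
```

Fetching 100 of 500 reads moved 244 kB — the index plus the header plus
exactly the hundred record extents — against a 1.07 MB file; the ratio
shrinks with file size, since the per-read cost is fixed.  `fetched.sfc`
is itself a valid container (same header, the hundred records) that can
be indexed and served again.

The same fetch from a shell:

```sh
sigfetch get https://host/path/reads.sfc --list readidlist.txt -o fetched.sfc
sigfetch get https://host/path/reads.sfc <read-id> -o one_read.sfc
sigfetch head  https://host/path/reads.sfc          # print the header
sigfetch reads https://host/path/reads.sfc          # print all read IDs
```

`--cache PATH` keeps the downloaded index for reuse via `--index PATH`
on later invocations (otherwise the temporary index is deleted);
`-t/--threads` (default 128), `--retry` (default 1) and `--wait`
(default 1 s) control the fetch policy.  Exit codes: 0 success, 1 hard
error, 2 partial fetch failure.

To pull the reads for a genomic region, pair it with an alignment file:

```python
from sigfetch import parse_region, read_ids_for_regions, ids_to_file
ids = read_ids_for_regions("reads.bam", [parse_region("chr1:1-1000000")])
ids_to_file(ids, "readidlist.txt")
```

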