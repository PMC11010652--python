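"""Synthetic datasets and an instrumented local range server.

Everything the remote client promises — byte-exact range replies,
latency hiding, retry on transient failure, traffic frugality, cache
semantics — is testable against this module with no network access:

* :func:`generate_dataset` writes a deterministic container + index with
  a manifest of read IDs and signal checksums;
* :func:`serve` runs an in-process HTTP server with Range support,
  per-request latency injection, scripted transient/permanent failures,
  and an append-only request log with byte accounting;
* :func:`generate_alignment_fixture` places the dataset's read IDs at
  known genomic coordinates (SAM text, converted to sorted+indexed BAM)
  with the ground-truth region → read-ID mapping returned alongside.

Signal models: ``white-noise`` draws independent int16 samples across
the full ADC range (nearly incompressible); ``random-walk`` emulates the
smooth, small-step character of real pore current by reflecting an
integer random walk inside a bounded band, so successive deltas stay
small and the svb-zd size bound is exercised.
"""

from __future__ import annotations

import json
import threading
import time
import zlib
from dataclasses import dataclass, field
from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer
from pathlib import Path
from typing import Callable

import numpy as np
import pysam

from .container import AuxType, ReadRecord, RunHeader, write_file
from .index import build_index, write_index
from .region import GenomicRegion

__all__ = [
    "FixtureSpec",
    "DatasetManifest",
    "generate_dataset",
    "ServerBehavior",
    "ServerHandle",
    "serve",
    "AlignmentFixture",
    "generate_alignment_fixture",
]


@dataclass
class FixtureSpec:
    """Shape of a synthetic dataset; same seed → byte-identical files."""

    n_reads: int = 100
    signal_length: tuple[int, int] = (2000, 500)  # (mean, spread); spread 0 = fixed
    signal_model: str = "random-walk"  # or "white-noise"
    n_read_groups: int = 1
    seed: int = 42


@dataclass
class DatasetManifest:
    """Everything needed to verify a fetched read without re-reading the
    source container: IDs in file order, sample counts, CRC32 of the raw
    int16 signal bytes."""

    container_path: str
    index_path: str
    read_ids: list[str]
    n_samples: dict[str, int]
    signal_crc32: dict[str, int]
    seed: int

    def verify(self, record: ReadRecord) -> bool:
        """True iff the record's signal matches the manifest checksum."""
        expected = self.signal_crc32.get(record.read_id)
        if expected is None:
            return False
        return (
            record.n_samples == self.n_samples[record.read_id]
            and zlib.crc32(record.raw_signal.astype("<i2").tobytes()) == expected
        )


def _uuid_like(rng: np.random.Generator) -> str:
    h = rng.bytes(16).hex()
    return f"{h[:8]}-{h[8:12]}-{h[12:16]}-{h[16:20]}-{h[20:32]}"


def _random_walk_signal(rng: np.random.Generator, n: int) -> np.ndarray:
    # Bounded walk: reflect the cumulative sum into [0, band] with a
    # triangle map (1-Lipschitz), so per-sample deltas keep the step
    # magnitude (<= 120) and zigzagged deltas stay below 256.
    band = 12000
    steps = rng.integers(-120, 121, size=n, dtype=np.int64)
    walk = np.cumsum(steps)
    m = np.mod(walk, 2 * band)
    tri = band - np.abs(m - band)
    return (tri - band // 2).astype(np.int16)


def _white_noise_signal(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(-32768, 32768, size=n, dtype=np.int64).astype(np.int16)


_AUX_SCHEMA = [
    ("channel_number", AuxType.INT32),
    ("read_number", AuxType.INT32),
    ("start_time", AuxType.UINT64),
    ("median_before", AuxType.FLOAT64),
    ("end_reason", AuxType.STRING),
]

_END_REASONS = ["signal_positive", "unblock_mux_change", "signal_negative"]


def generate_dataset(spec: FixtureSpec, directory) -> DatasetManifest:
    """Write ``reads.sfc`` and ``reads.sfc.idx`` under ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    attributes = [
        {
            "run_id": rng.bytes(8).hex(),
            "flow_cell_id": f"FC{rng.integers(10000, 99999)}",
            "exp_start_time": "2024-01-01T00:00:00Z",
        }
        for _ in range(spec.n_read_groups)
    ]
    header = RunHeader(
        version="1.0",
        num_read_groups=spec.n_read_groups,
        attributes=attributes,
        aux_schema=list(_AUX_SCHEMA),
    )

    mean, spread = spec.signal_length
    records = []
    for i in range(spec.n_reads):
        if spread > 0:
            n = max(1, int(rng.normal(mean, spread)))
        else:
            n = max(1, mean)
        if spec.signal_model == "random-walk":
            signal = _random_walk_signal(rng, n)
        elif spec.signal_model == "white-noise":
            signal = _white_noise_signal(rng, n)
        else:
            raise ValueError(f"unknown signal model {spec.signal_model!r}")
        records.append(
            ReadRecord(
                read_id=_uuid_like(rng),
                read_group=int(rng.integers(spec.n_read_groups)),
                digitisation=8192.0,
                offset=float(rng.integers(-10, 11)),
                range=float(np.round(rng.uniform(1400.0, 1500.0), 1)),
                sampling_rate=5000.0,
                raw_signal=signal,
                aux_values=(
                    int(rng.integers(1, 3001)),
                    i,
                    int(rng.integers(0, 10**9)),
                    float(np.round(rng.normal(220.0, 15.0), 3)),
                    _END_REASONS[int(rng.integers(len(_END_REASONS)))],
                ),
            )
        )

    container_path = directory / "reads.sfc"
    write_file(header, records, container_path)
    index = build_index(container_path)
    index_path = directory / "reads.sfc.idx"
    write_index(index, index_path)

    manifest = DatasetManifest(
        container_path=str(container_path),
        index_path=str(index_path),
        read_ids=[r.read_id for r in records],
        n_samples={r.read_id: r.n_samples for r in records},
        signal_crc32={
            r.read_id: zlib.crc32(r.raw_signal.astype("<i2").tobytes())
            for r in records
        },
        seed=spec.seed,
    )
    (directory / "manifest.json").write_text(
        json.dumps(
            {
                "seed": manifest.seed,
                "read_ids": manifest.read_ids,
                "n_samples": manifest.n_samples,
                "signal_crc32": manifest.signal_crc32,
            },
            indent=1,
        )
    )
    return manifest


@dataclass
class ServerBehavior:
    """Scripted behaviour of the fixture server.

    ``transient_failures_per_request`` makes every distinct (path, range)
    request fail that many times before succeeding — the client's retry
    path must absorb them.  ``permanent_fail`` is a predicate over
    (path, range-start) for requests that never succeed.  ``fail_mode``
    chooses between an HTTP 503 reply and dropping the connection before
    any response is written; both must trigger the client's retry.
    """

    latency_seconds: float = 0.0
    range_support: bool = True
    transient_failures_per_request: int = 0
    permanent_fail: Callable[[str, int | None], bool] | None = None
    fail_mode: str = "status"  # "status" (503) or "drop"
    request_log: list = field(default_factory=list)  # (path, range, status, n_bytes)
    _attempts: dict = field(default_factory=dict)
    _lock: threading.Lock = field(default_factory=threading.Lock)

    def bytes_served(self) -> int:
        return sum(entry[3] for entry in self.request_log)

    def requests_for(self, name: str) -> list:
        return [e for e in self.request_log if e[0].endswith(name)]


class _RangeHandler(BaseHTTPRequestHandler):
    protocol_version = "HTTP/1.1"

    def log_message(self, *args) -> None:  # silence default stderr chatter
        pass

    def _log(self, rng, status, n_bytes) -> None:
        b: ServerBehavior = self.server.behavior  # type: ignore[attr-defined]
        with b._lock:
            b.request_log.append((self.path, rng, status, n_bytes))

    def do_GET(self) -> None:
        b: ServerBehavior = self.server.behavior  # type: ignore[attr-defined]
        root: Path = self.server.root  # type: ignore[attr-defined]
        if b.latency_seconds:
            time.sleep(b.latency_seconds)

        rng = None
        range_header = self.headers.get("Range")
        if range_header and range_header.startswith("bytes="):
            a, _, z = range_header[6:].partition("-")
            rng = (int(a), int(z) if z else None)

        target = (root / self.path.lstrip("/")).resolve()
        if root.resolve() not in target.parents and target != root.resolve():
            self._log(rng, 403, 0)
            self.send_error(403)
            return
        if not target.is_file():
            self._log(rng, 404, 0)
            self.send_error(404)
            return

        key = (self.path, rng)
        fail = False
        if b.permanent_fail and b.permanent_fail(
            self.path, None if rng is None else rng[0]
        ):
            fail = True
        elif b.transient_failures_per_request:
            with b._lock:
                seen = b._attempts.get(key, 0)
                b._attempts[key] = seen + 1
            if seen < b.transient_failures_per_request:
                fail = True
        if fail:
            if b.fail_mode == "drop":
                self._log(rng, -1, 0)
                self.close_connection = True
                self.connection.close()
                return
            self._log(rng, 503, 0)
            self.send_response(503)
            self.send_header("Content-Length", "0")
            self.end_headers()
            return

        cache = self.server.file_cache  # type: ignore[attr-defined]
        with b._lock:
            data = cache.get(target)
            if data is None:
                data = cache[target] = target.read_bytes()
        if rng is not None and b.range_support:
            start, end = rng
            end = len(data) - 1 if end is None else min(end, len(data) - 1)
            if start >= len(data) or start > end:
                self._log(rng, 416, 0)
                self.send_error(416)
                return
            chunk = data[start : end + 1]
            self._log(rng, 206, len(chunk))
            self.send_response(206)
            self.send_header("Content-Type", "application/octet-stream")
            self.send_header("Content-Range", f"bytes {start}-{end}/{len(data)}")
            self.send_header("Content-Length", str(len(chunk)))
            self.end_headers()
            self.wfile.write(chunk)
            return
        self._log(rng, 200, len(data))
        self.send_response(200)
        self.send_header("Content-Type", "application/octet-stream")
        self.send_header("Content-Length", str(len(data)))
        self.end_headers()
        self.wfile.write(data)


class _QuietServer(ThreadingHTTPServer):
    daemon_threads = True
    request_queue_size = 256  # hundreds of concurrent connections expected

    def handle_error(self, request, client_address) -> None:
        # Dropped connections are scripted behaviour, not server bugs.
        pass


@dataclass
class ServerHandle:
    url: str
    behavior: ServerBehavior
    _server: ThreadingHTTPServer = None  # type: ignore[assignment]
    _thread: threading.Thread = None  # type: ignore[assignment]

    def url_for(self, name: str) -> str:
        return f"{self.url}/{name}"

    @property
    def request_log(self) -> list:
        return self.behavior.request_log

    def shutdown(self) -> None:
        self._server.shutdown()
        self._server.server_close()
        self._thread.join(timeout=5)

    def __enter__(self) -> "ServerHandle":
        return self

    def __exit__(self, *exc) -> None:
        self.shutdown()


def serve(directory, behavior: ServerBehavior | None = None) -> ServerHandle:
    """Serve ``directory`` on an ephemeral localhost port; one handler
    thread per connection, so injected latency measures request-level
    parallelism rather than server bandwidth."""
    behavior = behavior or ServerBehavior()
    server = _QuietServer(("127.0.0.1", 0), _RangeHandler)
    server.behavior = behavior  # type: ignore[attr-defined]
    server.root = Path(directory)  # type: ignore[attr-defined]
    server.file_cache = {}  # type: ignore[attr-defined]
    thread = threading.Thread(target=server.serve_forever, daemon=True)
    thread.start()
    host, port = server.server_address[:2]
    return ServerHandle(
        url=f"http://{host}:{port}", behavior=behavior, _server=server, _thread=thread
    )


@dataclass
class AlignmentFixture:
    """A synthetic alignment file plus the truth it encodes."""

    sam_path: str
    bam_path: str  # coordinate-sorted, indexed; built at run time
    placements: dict[str, list[tuple[str, int, int, int]]]  # id -> (contig, start, end, flag)
    region_ids: dict[str, list[str]]  # str(region) -> sorted unique ids in region


def generate_alignment_fixture(
    manifest: DatasetManifest,
    regions: list[GenomicRegion],
    seed: int,
    directory,
) -> AlignmentFixture:
    """Place the manifest's read IDs at deterministic coordinates.

    Roughly 60% of reads land inside a (randomly chosen) region —
    including boundary-straddling placements — and the rest in a gap
    zone beyond every region on the same contig.  The first in-region
    read also gets a supplementary alignment so query-name
    deduplication is exercised.  SAM text is written, then sorted and
    indexed into BAM with pysam.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    contigs = sorted({r.contig for r in regions}) or ["chr1"]
    gap_base = {
        c: max((r.end or 0) for r in regions if r.contig == c) + 50_000
        if any(r.contig == c for r in regions)
        else 50_000
        for c in contigs
    }

    placements: dict[str, list[tuple[str, int, int, int]]] = {}
    supplementary_done = False
    for read_id in manifest.read_ids:
        span = int(rng.integers(500, 5001))
        if regions and rng.random() < 0.6:
            region = regions[int(rng.integers(len(regions)))]
            lo = max(0, region.start - span + 1)
            hi = max(lo + 1, (region.end or region.start + 1))
            start = int(rng.integers(lo, hi))
            contig = region.contig
            flag = 0
            placements[read_id] = [(contig, start, start + span, flag)]
            if not supplementary_done:
                s2 = start + span + 100
                if s2 + 200 <= (region.end or 0):  # only if still in-region
                    placements[read_id].append((contig, s2, s2 + 200, 2048))
                    supplementary_done = True
        else:
            contig = contigs[int(rng.integers(len(contigs)))]
            start = gap_base[contig]
            gap_base[contig] += span + 100
            placements[read_id] = [(contig, start, start + span, 0)]

    contig_len = {
        c: max(
            [end for pl in placements.values() for cc, _, end, _ in pl if cc == c]
            + [r.end or 0 for r in regions if r.contig == c]
            + [1000]
        )
        + 10_000
        for c in contigs
    }

    sam_path = directory / "alignments.sam"
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for c in contigs:
        lines.append(f"@SQ\tSN:{c}\tLN:{contig_len[c]}")
    for read_id, pls in placements.items():
        for contig, start, end, flag in pls:
            lines.append(
                "\t".join(
                    [
                        read_id,
                        str(flag),
                        contig,
                        str(start + 1),  # SAM is 1-based
                        "60",
                        f"{end - start}M",
                        "*",
                        "0",
                        "0",
                        "*",
                        "*",
                    ]
                )
            )
    sam_path.write_text("\n".join(lines) + "\n")

    bam_path = directory / "alignments.bam"
    pysam.sort("-o", str(bam_path), str(sam_path))
    pysam.index(str(bam_path))

    region_ids = {}
    for region in regions:
        hit = {
            rid
            for rid, pls in placements.items()
            for contig, start, end, _ in pls
            if contig == region.contig
            and start < (region.end if region.end is not None else end + 1)
            and end > region.start
        }
        region_ids[str(region)] = sorted(hit)

    return AlignmentFixture(
        sam_path=str(sam_path),
        bam_path=str(bam_path),
        placements=placements,
        region_ids=region_ids,
    )
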