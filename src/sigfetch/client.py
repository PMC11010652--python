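"""Remote access engine: byte-range fetches of indexed signal reads.

A remote container is never downloaded whole.  The client downloads the
(small) index — or uses a local copy — then issues one HTTP Range
request per read at the byte extent the index records.  Batch fetches
run many requests concurrently to hide per-request latency; each request
is retried independently on transient failure with a flat wait, and
per-read failures are reported rather than aborting the batch.
"""

from __future__ import annotations

import http.client
import os
import tempfile
import threading
import time
import urllib.error
import urllib.parse
import urllib.request
import warnings
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field

from .container import (
    ReadRecord,
    RunHeader,
    decode_framed_record,
    parse_header,
    write_file,
)
from .errors import (
    FetchFailedError,
    IndexMismatchError,
    IndexNotFoundError,
    MissingReadError,
    RangeUnsupportedError,
    SigfetchError,
)
from .index import INDEX_SUFFIX, ReadIndex, load_index

_HTTP_TIMEOUT = 60.0


def _is_url(location: str) -> bool:
    return urllib.parse.urlparse(str(location)).scheme in ("http", "https")


@dataclass
class FetchPolicy:
    """How fetches are issued: concurrency, retry, and connection cap.

    ``retry_count`` is the number of times one failed range request is
    re-attempted before it is declared failed (default 1: a request that
    fails twice in a row fails for good).  ``retry_wait_seconds`` is the
    flat delay before each retry (default 1 second; no backoff).
    """

    n_threads: int = 128
    retry_count: int = 1
    retry_wait_seconds: float = 1.0
    max_connections: int | None = None

    def validate(self) -> None:
        if self.n_threads < 1:
            raise SigfetchError("n_threads must be >= 1")
        if self.retry_count < 0:
            raise SigfetchError("retry_count must be >= 0")
        if self.retry_wait_seconds < 0:
            raise SigfetchError("retry_wait_seconds must be >= 0")
        if self.max_connections is not None and self.max_connections < 1:
            raise SigfetchError("max_connections must be >= 1 when set")

    @property
    def effective_threads(self) -> int:
        if self.max_connections is None:
            return self.n_threads
        return min(self.n_threads, self.max_connections)


@dataclass
class RemoteSource:
    """Resolved locations of the data URL, its index, and an optional
    cache path for the downloaded index."""

    data_url: str
    index_location: str | None = None
    cache_path: str | None = None

    def __post_init__(self) -> None:
        if not _is_url(self.data_url):
            raise SigfetchError(
                f"data_url must be an http/https URL, got {self.data_url!r}"
            )

    @property
    def resolved_index_location(self) -> str:
        """Explicit location, or the conventional ``<url>.idx`` sidecar."""
        if self.index_location is not None:
            return str(self.index_location)
        return self.data_url + INDEX_SUFFIX

    @property
    def index_is_local(self) -> bool:
        return not _is_url(self.resolved_index_location)


@dataclass
class FetchReport:
    """Outcome of a batch fetch: every requested ID is either fetched or
    listed in ``failed_ids`` (n_fetched + len(failed_ids) == n_requested)."""

    n_requested: int = 0
    n_fetched: int = 0
    n_retried: int = 0
    failed_ids: list[str] = field(default_factory=list)

    def __str__(self) -> str:
        return (
            f"requested {self.n_requested}, fetched {self.n_fetched}, "
            f"retries {self.n_retried}, failed {len(self.failed_ids)}"
        )


def _http_get(url: str, headers: dict[str, str]) -> tuple[int, bytes]:
    req = urllib.request.Request(url, headers=headers)
    with urllib.request.urlopen(req, timeout=_HTTP_TIMEOUT) as resp:
        return resp.status, resp.read()


_RETRYABLE = (
    urllib.error.URLError,
    http.client.HTTPException,
    ConnectionError,
    TimeoutError,
    OSError,
)


def _fetch_with_retry(url: str, headers: dict[str, str], policy: FetchPolicy):
    """One logical fetch with per-request retry; returns
    ``(status, body, n_retried)``.  404 and a full-content reply to a
    range request are permanent conditions and are not retried."""
    attempts = policy.retry_count + 1
    n_retried = 0
    last_exc: Exception | None = None
    for attempt in range(attempts):
        if attempt > 0:
            time.sleep(policy.retry_wait_seconds)
            n_retried += 1
        try:
            status, body = _http_get(url, headers)
            return status, body, n_retried
        except urllib.error.HTTPError as exc:
            if exc.code == 404:
                raise FetchFailedError(f"not found (404): {url}") from None
            last_exc = exc
        except _RETRYABLE as exc:
            last_exc = exc
    raise FetchFailedError(
        f"fetch failed after {attempts} attempt(s) ({n_retried} retried): "
        f"{url}: {last_exc}"
    )


def fetch_range(
    url: str, byte_offset: int, byte_length: int, policy: FetchPolicy | None = None
) -> bytes:
    """Fetch exactly ``byte_length`` bytes at ``byte_offset`` via an HTTP
    Range request.  A full-content (200) reply raises
    :class:`RangeUnsupportedError` — the client never silently downloads
    the whole file."""
    data, _ = fetch_range_with_stats(url, byte_offset, byte_length, policy)
    return data


def fetch_range_with_stats(
    url: str, byte_offset: int, byte_length: int, policy: FetchPolicy | None = None
) -> tuple[bytes, int]:
    if byte_length < 1:
        raise SigfetchError("byte_length must be >= 1")
    policy = policy or FetchPolicy()
    policy.validate()
    headers = {"Range": f"bytes={byte_offset}-{byte_offset + byte_length - 1}"}
    status, body, n_retried = _fetch_with_retry(url, headers, policy)
    if status != 206:
        raise RangeUnsupportedError(
            f"server answered a range request with status {status} "
            f"(full content); byte-range access is required: {url}"
        )
    if len(body) != byte_length:
        raise FetchFailedError(
            f"range reply carried {len(body)} bytes, expected {byte_length}: {url}"
        )
    return body, n_retried


class IndexHandle:
    """Where the loaded index lives on disk, and whether it is ephemeral.

    Ephemeral downloads (no cache path configured) are deleted on
    :meth:`close`; cached or local-path indexes persist.
    """

    def __init__(self, path: str | None, ephemeral: bool):
        self.path = path
        self.ephemeral = ephemeral
        self._closed = False

    def close(self) -> None:
        if self._closed:
            return
        self._closed = True
        if self.ephemeral and self.path and os.path.exists(self.path):
            os.unlink(self.path)

    def __enter__(self) -> "IndexHandle":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


def get_remote_index(
    source: RemoteSource, policy: FetchPolicy | None = None
) -> tuple[ReadIndex, IndexHandle]:
    """Load the index for a remote container.

    A local index path is loaded in place (no download).  A remote index
    is downloaded to ``source.cache_path`` if set (and persists there),
    else to a temporary file deleted when the returned handle closes.
    """
    policy = policy or FetchPolicy()
    policy.validate()
    location = source.resolved_index_location
    if source.index_is_local:
        try:
            return load_index(location), IndexHandle(location, ephemeral=False)
        except FileNotFoundError:
            raise IndexNotFoundError(f"local index not found: {location}") from None
    try:
        status, body, _ = _fetch_with_retry(location, {}, policy)
    except FetchFailedError as exc:
        if "404" in str(exc):
            raise IndexNotFoundError(
                f"remote index not found at {location}; host the index next "
                "to the data or pass an explicit index location"
            ) from None
        raise
    if source.cache_path:
        path = str(source.cache_path)
        ephemeral = False
    else:
        fd, path = tempfile.mkstemp(prefix="sigfetch-idx-", suffix=INDEX_SUFFIX)
        os.close(fd)
        ephemeral = True
    with open(path, "wb") as fh:
        fh.write(body)
    return load_index(path), IndexHandle(path, ephemeral=ephemeral)


def get_remote_header(
    source: RemoteSource,
    policy: FetchPolicy | None = None,
    index: ReadIndex | None = None,
) -> RunHeader:
    """Fetch and parse the container header in a single range request of
    the header extent the index records."""
    policy = policy or FetchPolicy()
    if index is None:
        index, handle = get_remote_index(source, policy)
        with handle:
            return get_remote_header(source, policy, index)
    _, header_len = index.header_extent
    buf = fetch_range(source.data_url, 0, header_len, policy)
    return parse_header(buf)


def get_read(
    source: RemoteSource,
    index: ReadIndex,
    header: RunHeader,
    read_id: str,
    policy: FetchPolicy | None = None,
) -> ReadRecord:
    """Fetch one read by ID: one range request at the indexed extent."""
    record, _ = _get_read_with_stats(source, index, header, read_id, policy)
    return record


def _get_read_with_stats(source, index, header, read_id, policy):
    entry = index.lookup(read_id)
    if entry is None:
        raise MissingReadError(f"read ID {read_id!r} not in index")
    offset, length = entry
    buf, n_retried = fetch_range_with_stats(source.data_url, offset, length, policy)
    record = decode_framed_record(buf, header)
    if record.read_id != read_id:
        raise IndexMismatchError(
            f"record at bytes {offset}+{length} is {record.read_id!r}, "
            f"index promised {read_id!r}"
        )
    return record, n_retried


def get_batch(
    source: RemoteSource,
    index: ReadIndex,
    header: RunHeader,
    read_ids,
    policy: FetchPolicy | None = None,
) -> tuple[list[ReadRecord], FetchReport]:
    """Fetch many reads concurrently; results come back in input order.

    Duplicate IDs are deduplicated (first occurrence kept) with a
    warning.  Per-read failures — missing from the index, or transport
    failure after retries — go into ``FetchReport.failed_ids`` instead of
    aborting the batch.  If *no* requested ID exists in the index the
    call raises, since nothing could ever be fetched.
    """
    policy = policy or FetchPolicy()
    policy.validate()
    ids = list(read_ids)
    deduped = list(dict.fromkeys(ids))
    if len(deduped) != len(ids):
        warnings.warn(
            f"{len(ids) - len(deduped)} duplicate read ID(s) removed from batch",
            stacklevel=2,
        )
    if not deduped:
        raise SigfetchError("batch read-ID list is empty")
    if not any(index.lookup(i) is not None for i in deduped):
        raise MissingReadError("none of the requested read IDs are in the index")

    report = FetchReport(n_requested=len(deduped))
    results: dict[str, ReadRecord] = {}
    lock = threading.Lock()

    def _one(read_id: str) -> None:
        try:
            record, n_retried = _get_read_with_stats(
                source, index, header, read_id, policy
            )
        except SigfetchError:
            with lock:
                report.failed_ids.append(read_id)
            return
        with lock:
            results[read_id] = record
            report.n_fetched += 1
            report.n_retried += n_retried

    with ThreadPoolExecutor(max_workers=policy.effective_threads) as pool:
        list(pool.map(_one, deduped))

    report.failed_ids = [i for i in deduped if i not in results]  # input order
    records = [results[i] for i in deduped if i in results]
    return records, report


def save_fetched(records, header: RunHeader, destination):
    """Write fetched records to a valid container carrying the full
    source header; the output is re-readable and re-indexable."""
    return write_file(header, records, destination)


class RemoteContainer:
    """Convenience session over one remote container.

    Resolves the index (honouring cache semantics) and the header on
    entry; ``get``/``get_batch`` then need only read IDs.  Closing the
    session removes an ephemeral downloaded index.
    """

    def __init__(self, source: RemoteSource, policy: FetchPolicy | None = None):
        self.source = source
        self.policy = policy or FetchPolicy()
        self.index, self._handle = get_remote_index(source, self.policy)
        try:
            self.header = get_remote_header(source, self.policy, self.index)
        except Exception:
            self._handle.close()
            raise

    def get(self, read_id: str) -> ReadRecord:
        return get_read(self.source, self.index, self.header, read_id, self.policy)

    def get_batch(self, read_ids) -> tuple[list[ReadRecord], FetchReport]:
        return get_batch(
            self.source, self.index, self.header, read_ids, self.policy
        )

    def save(self, records, destination):
        return save_fetched(records, self.header, destination)

    def close(self) -> None:
        self._handle.close()

    def __enter__(self) -> "RemoteContainer":
        return self

    def __exit__(self, *exc) -> None:
        self.close()
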