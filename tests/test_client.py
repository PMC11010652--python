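"""Remote client: range fetches, retry, batching, caching, frugality."""

import os
import shutil
import time
from pathlib import Path

import pytest

from sigfetch.client import (
    FetchPolicy,
    RemoteContainer,
    RemoteSource,
    fetch_range,
    fetch_range_with_stats,
    get_batch,
    get_read,
    get_remote_header,
    get_remote_index,
    save_fetched,
)
from sigfetch.container import read_all
from sigfetch.errors import (
    FetchFailedError,
    FormatError,
    IndexMismatchError,
    IndexNotFoundError,
    MissingReadError,
    RangeUnsupportedError,
    SigfetchError,
)
from sigfetch.fixtures import ServerBehavior
from sigfetch.index import build_index, load_index

NOWAIT = dict(retry_wait_seconds=0.0)


def remote_setup(server, dataset):
    """(source, index, header) for the shared dataset behind `server`."""
    source = RemoteSource(
        server.url_for("reads.sfc"), index_location=dataset.index_path
    )
    index = load_index(dataset.index_path)
    header = get_remote_header(source, FetchPolicy(**NOWAIT), index)
    return source, index, header


def test_fetch_range_equals_local_slice(start_server, dataset):
    server = start_server()
    raw = Path(dataset.container_path).read_bytes()
    got = fetch_range(server.url_for("reads.sfc"), 100, 57, FetchPolicy(**NOWAIT))
    assert got == raw[100:157]
    assert server.request_log[-1][2] == 206


def test_full_content_reply_is_an_error_not_a_fallback(start_server):
    server = start_server(ServerBehavior(range_support=False))
    with pytest.raises(RangeUnsupportedError):
        fetch_range(server.url_for("reads.sfc"), 0, 10, FetchPolicy(**NOWAIT))


def test_retry_recovers_from_single_transient_failure(start_server):
    server = start_server(ServerBehavior(transient_failures_per_request=1))
    policy = FetchPolicy(retry_count=1, **NOWAIT)
    data, n_retried = fetch_range_with_stats(server.url_for("reads.sfc"), 0, 8, policy)
    assert data == b"SIGFET01"
    assert n_retried == 1
    statuses = [e[2] for e in server.request_log]
    assert statuses == [503, 206]


def test_no_retries_means_single_failure_is_fatal(start_server):
    server = start_server(ServerBehavior(transient_failures_per_request=1))
    with pytest.raises(FetchFailedError):
        fetch_range(server.url_for("reads.sfc"), 0, 8, FetchPolicy(retry_count=0, **NOWAIT))


def test_two_consecutive_failures_exhaust_default_retry(start_server):
    # A fetch that fails twice in a row fails for good under retry_count=1.
    server = start_server(ServerBehavior(transient_failures_per_request=2))
    with pytest.raises(FetchFailedError):
        fetch_range(server.url_for("reads.sfc"), 0, 8, FetchPolicy(retry_count=1, **NOWAIT))


def test_connection_drop_also_triggers_retry(start_server):
    server = start_server(
        ServerBehavior(transient_failures_per_request=1, fail_mode="drop")
    )
    data = fetch_range(
        server.url_for("reads.sfc"), 0, 8, FetchPolicy(retry_count=1, **NOWAIT)
    )
    assert data == b"SIGFET01"


def test_retry_wait_is_honoured(start_server):
    server = start_server(ServerBehavior(transient_failures_per_request=1))
    t0 = time.monotonic()
    fetch_range(
        server.url_for("reads.sfc"),
        0,
        8,
        FetchPolicy(retry_count=1, retry_wait_seconds=0.3),
    )
    assert time.monotonic() - t0 >= 0.3


def test_remote_header_equals_local(start_server, dataset, local_reads):
    server = start_server()
    source, index, header = remote_setup(server, dataset)
    assert header == local_reads[0]
    # Repeated fetches are byte-identical (deterministic serialization).
    again = get_remote_header(source, FetchPolicy(**NOWAIT), index)
    assert again == header


def test_corrupt_remote_header_is_a_format_error(start_server, dataset, tmp_path):
    corrupt_dir = tmp_path / "corrupt"
    corrupt_dir.mkdir()
    raw = bytearray(Path(dataset.container_path).read_bytes())
    raw[:8] = b"XXXXXXXX"
    (corrupt_dir / "reads.sfc").write_bytes(bytes(raw))
    server = start_server(directory=corrupt_dir)
    source = RemoteSource(
        server.url_for("reads.sfc"), index_location=dataset.index_path
    )
    with pytest.raises(FormatError):
        get_remote_header(source, FetchPolicy(**NOWAIT), load_index(dataset.index_path))


def test_remote_index_download_equals_local(start_server, dataset):
    server = start_server()
    source = RemoteSource(server.url_for("reads.sfc"))  # default <url>.idx sidecar
    index, handle = get_remote_index(source, FetchPolicy(**NOWAIT))
    with handle:
        assert index == load_index(dataset.index_path)
        assert handle.ephemeral
        path = handle.path
        assert os.path.exists(path)
    assert not os.path.exists(path)  # ephemeral download removed on close


def test_local_index_means_no_index_request(start_server, dataset):
    server = start_server()
    source = RemoteSource(
        server.url_for("reads.sfc"), index_location=dataset.index_path
    )
    index, handle = get_remote_index(source, FetchPolicy(**NOWAIT))
    handle.close()
    assert not handle.ephemeral
    assert server.behavior.requests_for("reads.sfc.idx") == []


def test_cache_path_persists_index_and_skips_second_download(start_server, dataset, tmp_path):
    server = start_server()
    cache = tmp_path / "cached.idx"
    source = RemoteSource(server.url_for("reads.sfc"), cache_path=str(cache))
    index, handle = get_remote_index(source, FetchPolicy(**NOWAIT))
    handle.close()
    assert cache.exists()  # survives the session
    assert len(server.behavior.requests_for("reads.sfc.idx")) == 1

    # Second session pointed at the cached copy: zero index downloads.
    source2 = RemoteSource(server.url_for("reads.sfc"), index_location=str(cache))
    index2, handle2 = get_remote_index(source2, FetchPolicy(**NOWAIT))
    handle2.close()
    assert index2 == index
    assert len(server.behavior.requests_for("reads.sfc.idx")) == 1


def test_missing_remote_index_suggests_explicit_location(start_server, dataset, tmp_path):
    bare = tmp_path / "bare"
    bare.mkdir()
    shutil.copy(dataset.container_path, bare / "reads.sfc")  # no sidecar index
    server = start_server(directory=bare)
    source = RemoteSource(server.url_for("reads.sfc"))
    with pytest.raises(IndexNotFoundError, match="index"):
        get_remote_index(source, FetchPolicy(**NOWAIT))


def test_every_remote_read_equals_its_local_record(start_server, dataset, local_reads):
    # Master correctness property: remote get_read == local decode, per read.
    server = start_server()
    source, index, header = remote_setup(server, dataset)
    policy = FetchPolicy(**NOWAIT)
    local_by_id = {r.read_id: r for r in local_reads[1]}
    for read_id in dataset.read_ids[:40]:
        assert get_read(source, index, header, read_id, policy) == local_by_id[read_id]


def test_get_read_unknown_id(start_server, dataset):
    server = start_server()
    source, index, header = remote_setup(server, dataset)
    with pytest.raises(MissingReadError):
        get_read(source, index, header, "not-a-read", FetchPolicy(**NOWAIT))


def test_tampered_index_offset_is_an_index_mismatch(start_server, dataset):
    server = start_server()
    source, index, header = remote_setup(server, dataset)
    a, b = dataset.read_ids[0], dataset.read_ids[1]
    index.entries[a] = index.entries[b]  # point read a at read b's extent
    with pytest.raises(IndexMismatchError):
        get_read(source, index, header, a, FetchPolicy(**NOWAIT))


@pytest.mark.parametrize("n_threads", [1, 8, 64])
def test_batch_output_is_thread_count_invariant(start_server, dataset, local_reads, n_threads):
    server = start_server()
    source, index, header = remote_setup(server, dataset)
    records, report = get_batch(
        source, index, header, dataset.read_ids,
        FetchPolicy(n_threads=n_threads, **NOWAIT),
    )
    assert records == local_reads[1]  # input order == file order here
    assert report.n_fetched == len(dataset.read_ids)
    assert report.failed_ids == []


def test_batch_respects_input_order_not_file_order(start_server, dataset, local_reads):
    server = start_server()
    source, index, header = remote_setup(server, dataset)
    ids = list(reversed(dataset.read_ids[:30]))
    records, _ = get_batch(source, index, header, ids, FetchPolicy(n_threads=8, **NOWAIT))
    assert [r.read_id for r in records] == ids


def test_batch_deduplicates_with_warning(start_server, dataset):
    server = start_server()
    source, index, header = remote_setup(server, dataset)
    ids = dataset.read_ids[:5] + dataset.read_ids[:2]
    with pytest.warns(UserWarning, match="duplicate"):
        records, report = get_batch(
            source, index, header, ids, FetchPolicy(n_threads=4, **NOWAIT)
        )
    assert [r.read_id for r in records] == dataset.read_ids[:5]
    assert report.n_requested == 5


def test_batch_retries_transient_failures_to_full_success(start_server, dataset):
    server = start_server(ServerBehavior(transient_failures_per_request=1))
    source, index, header = remote_setup(server, dataset)
    ids = dataset.read_ids[:25]
    records, report = get_batch(
        source, index, header, ids, FetchPolicy(n_threads=8, retry_count=1, **NOWAIT)
    )
    assert report.failed_ids == [] and report.n_fetched == 25
    assert report.n_retried >= 25  # every read needed its one retry


def test_batch_reports_permanently_failing_ids(start_server, dataset, local_reads):
    doomed = set(dataset.read_ids[3:6])
    index_local = load_index(dataset.index_path)
    doomed_offsets = {index_local.lookup(i)[0] for i in doomed}
    server = start_server(
        ServerBehavior(
            permanent_fail=lambda path, start: start in doomed_offsets
        )
    )
    source, index, header = remote_setup(server, dataset)
    ids = dataset.read_ids[:10]
    records, report = get_batch(
        source, index, header, ids, FetchPolicy(n_threads=4, retry_count=1, **NOWAIT)
    )
    assert sorted(report.failed_ids) == sorted(doomed)
    assert report.n_fetched == 7
    assert report.n_fetched + len(report.failed_ids) == report.n_requested
    fetched_ids = [r.read_id for r in records]
    assert fetched_ids == [i for i in ids if i not in doomed]


def test_batch_missing_ids_are_per_read_failures(start_server, dataset):
    server = start_server()
    source, index, header = remote_setup(server, dataset)
    ids = dataset.read_ids[:4] + ["ghost-1", "ghost-2"]
    records, report = get_batch(source, index, header, ids, FetchPolicy(n_threads=4, **NOWAIT))
    assert report.failed_ids == ["ghost-1", "ghost-2"]
    assert len(records) == 4


def test_batch_with_no_resolvable_ids_raises(start_server, dataset):
    server = start_server()
    source, index, header = remote_setup(server, dataset)
    with pytest.raises(MissingReadError):
        get_batch(source, index, header, ["ghost"], FetchPolicy(**NOWAIT))
    with pytest.raises(SigfetchError):
        get_batch(source, index, header, [], FetchPolicy(**NOWAIT))


def test_invalid_policy_rejected():
    with pytest.raises(SigfetchError):
        FetchPolicy(n_threads=0).validate()
    with pytest.raises(SigfetchError):
        FetchPolicy(retry_count=-1).validate()


def test_batch_never_downloads_the_file(start_server, dataset):
    # Traffic frugality: total bytes served <= sum of indexed extents
    # + header extent + index file size.
    server = start_server()
    index = load_index(dataset.index_path)
    source = RemoteSource(server.url_for("reads.sfc"))  # remote index too
    with RemoteContainer(source, FetchPolicy(n_threads=16, **NOWAIT)) as rc:
        records, report = rc.get_batch(dataset.read_ids)
    assert report.failed_ids == []
    budget = (
        sum(length for _, length in index.entries.values())
        + index.header_extent_length
        + os.path.getsize(dataset.index_path)
    )
    assert server.behavior.bytes_served() <= budget
    file_size = os.path.getsize(dataset.container_path)
    assert budget < file_size + os.path.getsize(dataset.index_path) + 4  # sanity


def test_latency_hiding_scales_with_in_flight_requests(start_server, dataset):
    # Desk-scale analogue of throughput scaling linearly with threads:
    # with fixed per-request latency L, N reads on T threads take about
    # ceil(N/T)*L, so T=50 must beat a quarter of the T=1 wall time.
    server = start_server(ServerBehavior(latency_seconds=0.05))
    source, index, header = remote_setup(server, dataset)
    ids = list(dataset.read_ids)  # 120 unique reads

    t0 = time.monotonic()
    serial, _ = get_batch(source, index, header, ids, FetchPolicy(n_threads=1, **NOWAIT))
    wall_serial = time.monotonic() - t0

    t0 = time.monotonic()
    wide, _ = get_batch(source, index, header, ids, FetchPolicy(n_threads=50, **NOWAIT))
    wall_wide = time.monotonic() - t0

    assert wide == serial  # identical ordered output
    assert wall_wide <= 0.25 * wall_serial


def test_max_connections_caps_thread_count():
    policy = FetchPolicy(n_threads=64, max_connections=8)
    assert policy.effective_threads == 8


def test_save_fetched_round_trip(start_server, dataset, local_reads, tmp_path):
    server = start_server()
    source, index, header = remote_setup(server, dataset)
    records, _ = get_batch(
        source, index, header, dataset.read_ids[:10], FetchPolicy(n_threads=4, **NOWAIT)
    )
    out = tmp_path / "fetched.sfc"
    save_fetched(records, header, out)
    got_header, got_records = read_all(out)
    assert got_header == header
    assert got_records == records
    assert build_index(out).n_entries == 10  # output is re-indexable

    empty_out = tmp_path / "empty.sfc"
    save_fetched([], header, empty_out)
    assert read_all(empty_out) == (header, [])
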