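"""Exception hierarchy for sigfetch.

All library errors derive from :class:`SigfetchError` so callers (and the
CLI) can catch one base class and turn it into a message rather than a
traceback.
"""


class SigfetchError(Exception):
    """Base class for all sigfetch errors."""


class FormatError(SigfetchError):
    """A file does not look like a sigfetch container or index (bad magic,
    unsupported version, malformed header)."""


class CorruptRecordError(FormatError):
    """A record (or signal payload) could not be decoded: truncation,
    decompression failure, field overrun, or trailing bytes."""


class EncodingError(SigfetchError):
    """A record is inconsistent with the header schema it is being encoded
    under, or a value violates a field precondition."""


class DuplicateReadIdError(SigfetchError):
    """Two records in one container share a read ID."""


class MissingReadError(SigfetchError):
    """A requested read ID is not present in the index."""


class IndexMismatchError(SigfetchError):
    """The record decoded at an index entry's byte extent carries a
    different read ID than the one that keyed the entry — the index does
    not describe this file."""


class RangeUnsupportedError(SigfetchError):
    """The server answered a byte-range request with a full-content (200)
    reply.  Treated as a hard error, never a silent fallback, so a client
    can never accidentally download the whole file."""


class FetchFailedError(SigfetchError):
    """A range request failed after all retries were exhausted."""


class IndexNotFoundError(FetchFailedError):
    """The remote index could not be found; the user should supply an
    explicit index location."""


class RegionError(SigfetchError):
    """A genomic region string could not be parsed, or the alignment file
    cannot be queried by region (e.g. no index)."""
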