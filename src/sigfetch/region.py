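"""Region → read-ID selection from coordinate-sorted alignments.

Raw-signal containers are keyed by read ID, not genomic coordinate, so
fetching "the reads over BRCA1" means first asking an alignment file
which read names overlap the region — the same division of labour as
the classic shell pipeline::

    samtools view reads.bam chr1:1-1000000 | cut -f1 | sort -u > readidlist.txt

``read_ids_for_regions`` reproduces that pipeline exactly: every
alignment overlapping a region contributes its query name (secondary
and supplementary alignments included, as ``cut -f1`` does not filter),
deduplicated and sorted.  User-facing region syntax is 1-based
inclusive (the samtools convention); internal coordinates are 0-based
half-open.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pysam

from .errors import RegionError

_REGION_RE = re.compile(r"^([^:]+)(?::([\d,]+)-([\d,]+))?$")


@dataclass(frozen=True)
class GenomicRegion:
    """0-based half-open interval; ``end=None`` means the whole contig."""

    contig: str
    start: int = 0
    end: int | None = None

    def __post_init__(self) -> None:
        if not self.contig:
            raise RegionError("region contig must be non-empty")
        if self.start < 0:
            raise RegionError("region start must be >= 0")
        if self.end is not None and self.start >= self.end:
            raise RegionError(
                f"empty region: start {self.start} >= end {self.end} (0-based)"
            )

    def __str__(self) -> str:
        if self.end is None:
            return self.contig
        return f"{self.contig}:{self.start + 1}-{self.end}"


def parse_region(text: str) -> GenomicRegion:
    """Parse ``contig[:start-end]`` (1-based inclusive, commas allowed)
    into the 0-based half-open internal convention."""
    m = _REGION_RE.match(text.strip())
    if not m:
        raise RegionError(f"malformed region {text!r} (expected contig[:start-end])")
    contig, start_s, end_s = m.groups()
    if start_s is None:
        return GenomicRegion(contig)
    start1 = int(start_s.replace(",", ""))
    end1 = int(end_s.replace(",", ""))
    if start1 < 1 or start1 > end1:
        raise RegionError(
            f"malformed region {text!r}: need 1 <= start <= end, "
            f"got {start1}-{end1}"
        )
    return GenomicRegion(contig, start1 - 1, end1)


def regions_from_bed(path) -> list[GenomicRegion]:
    """First three BED columns (natively 0-based half-open)."""
    regions = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) < 3:
            raise RegionError(f"{path}:{lineno}: BED line needs >= 3 columns")
        regions.append(GenomicRegion(fields[0], int(fields[1]), int(fields[2])))
    return regions


def read_ids_for_regions(
    alignment_source, regions: Iterable[GenomicRegion] | str | Path
) -> list[str]:
    """Unique query names of alignments overlapping any region, sorted.

    ``regions`` may be GenomicRegion objects or a path to a BED file.
    The alignment file must be indexed for region queries.
    """
    if isinstance(regions, (str, Path)):
        regions = regions_from_bed(regions)
    regions = list(regions)
    names: set[str] = set()
    with pysam.AlignmentFile(str(alignment_source)) as af:
        if not af.has_index():
            raise RegionError(
                f"{alignment_source} has no index; create one "
                "(e.g. `samtools index`) to enable region queries"
            )
        for region in regions:
            try:
                it = af.fetch(region.contig, region.start, region.end)
            except ValueError as exc:
                raise RegionError(f"cannot query {region}: {exc}") from None
            for aln in it:
                if aln.query_name is not None:
                    names.add(aln.query_name)
    return sorted(names)


def ids_from_file(path) -> list[str]:
    """One read ID per line; blank lines ignored."""
    return [
        line.strip()
        for line in Path(path).read_text().splitlines()
        if line.strip()
    ]


def ids_to_file(ids: Sequence[str], path) -> None:
    Path(path).write_text("".join(f"{i}\n" for i in ids))
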