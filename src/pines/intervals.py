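"""Interval tracks (BED/narrowPeak) and membership queries.

Intervals follow the BED convention: 0-based, half-open [start, end).
Chromosome names are normalized to one dialect (default: strip a
leading "chr") so tracks and variant files from different sources line
up.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

from intervaltree import IntervalTree


class BedParseError(ValueError):
    """Raised for malformed BED lines; carries the 1-based line number."""

    def __init__(self, path, line_number: int, message: str):
        self.path = path
        self.line_number = line_number
        super().__init__(f"{path}:{line_number}: {message}")


def normalize_chrom(name: str, style: str = "strip") -> str:
    """Normalize a chromosome name to one dialect.

    style "strip": "chr1" -> "1"; "add": "1" -> "chr1"; "none": unchanged.
    """
    if style == "strip":
        return name[3:] if name.lower().startswith("chr") else name
    if style == "add":
        return name if name.lower().startswith("chr") else f"chr{name}"
    if style == "none":
        return name
    raise ValueError(f"unknown chromosome style: {style!r}")


@dataclass
class GenomicIntervals:
    """Per-chromosome interval trees for one annotation track."""

    track_id: str
    trees: dict[str, IntervalTree] = field(default_factory=dict)

    @classmethod
    def from_intervals(
        cls,
        track_id: str,
        intervals: Iterable[tuple[str, int, int]],
        chrom_style: str = "strip",
    ) -> "GenomicIntervals":
        obj = cls(track_id)
        for chrom, start, end in intervals:
            obj.add(chrom, start, end, chrom_style=chrom_style)
        return obj

    def add(self, chrom: str, start: int, end: int, chrom_style: str = "strip") -> None:
        if start >= end:
            raise ValueError(f"empty/inverted interval [{start}, {end})")
        self.trees.setdefault(normalize_chrom(chrom, chrom_style), IntervalTree()).addi(start, end)

    def contains(self, chrom: str, pos0: int) -> bool:
        """True iff 0-based position pos0 lies inside >=1 interval."""
        tree = self.trees.get(chrom)
        return bool(tree is not None and tree.overlaps_point(pos0))

    @property
    def chromosomes(self) -> set[str]:
        return set(self.trees)

    @property
    def n_intervals(self) -> int:
        return sum(len(t) for t in self.trees.values())

    def __iter__(self) -> Iterator[tuple[str, int, int]]:
        for chrom in sorted(self.trees):
            for iv in sorted(self.trees[chrom]):
                yield chrom, iv.begin, iv.end


def load_peak_track(path, track_id: str | None = None, chrom_style: str = "strip") -> GenomicIntervals:
    """Read a BED3+/narrowPeak file into a :class:`GenomicIntervals`.

    Only the first three columns are used.  Lines starting with
    ``track``, ``browser`` or ``#`` are skipped.  A malformed line or
    an interval with start >= end raises :class:`BedParseError` with
    the offending line number.
    """
    if track_id is None:
        track_id = str(path)
    out = GenomicIntervals(track_id)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(path, lineno, f"expected >=3 tab-separated columns, got {len(fields)}")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise BedParseError(path, lineno, f"non-integer coordinates: {fields[1]!r}, {fields[2]!r}") from None
            if start < 0:
                raise BedParseError(path, lineno, f"negative start {start}")
            if start >= end:
                raise BedParseError(path, lineno, f"rejected record: start {start} >= end {end}")
            out.add(chrom, start, end, chrom_style=chrom_style)
    return out


def merge_interval_sets(track_id: str, sets: Iterable[GenomicIntervals]) -> GenomicIntervals:
    """Union several tracks into one aggregate track.

    Used for the chromatin-interaction annotation, where per-cell-type
    interaction maps are pooled into a single global column.
    """
    merged = GenomicIntervals(track_id)
    for s in sets:
        for chrom, start, end in s:
            merged.add(chrom, start, end, chrom_style="none")
    return merged
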