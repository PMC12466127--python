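"""Genomic interval algebra and coordinate conventions.

All intervals are BED-style: 0-based, half-open ``[start, end)``. Variant
positions follow the VCF convention (1-based); :func:`vcf_pos_in_interval`
is the single place where the two conventions meet.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "GenomicInterval",
    "merge_intervals",
    "overlaps",
    "overlap_bp",
    "vcf_pos_in_interval",
    "read_bed",
    "write_bed",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic span ``chrom:[start, end)``.

    Parameters
    ----------
    chrom : str
        Chromosome name; must be non-empty.
    start : int
        0-based inclusive start.
    end : int
        0-based exclusive end; must satisfy ``start < end``.
    strand : str
        One of ``+``, ``-`` or ``.`` (default: unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = field(default=".", compare=False)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be a non-empty string")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        """Integer midpoint (floor) of the span."""
        return (self.start + self.end) // 2

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff *a* and *b* share at least one base (same chromosome)."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of bases shared by *a* and *b* (0 if disjoint)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def vcf_pos_in_interval(pos: int, iv: GenomicInterval) -> bool:
    """True iff the 1-based position *pos* falls inside the 0-based
    half-open interval *iv* (chromosome is not checked here)."""
    if pos < 1:
        raise ValueError(f"VCF positions are 1-based; got {pos}")
    return iv.start <= pos - 1 < iv.end


def merge_intervals(
    intervals: Iterable[GenomicInterval],
) -> list[GenomicInterval]:
    """Merge overlapping or abutting intervals.

    Returns a list sorted by ``(chrom, start)`` in which no two intervals
    on the same chromosome overlap or abut; the set of covered bases is
    exactly the union of the inputs. Abutting intervals (``a.end ==
    b.start``) are merged: regulatory regions are treated as closed
    genomic segments.
    """
    items = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in items:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a BED3/BED6 file (tab-separated, no header, half-open)."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed BED line in {path}: {line!r}")
            strand = fields[5] if len(fields) >= 6 else "."
            out.append(
                GenomicInterval(fields[0], int(fields[1]), int(fields[2]), strand)
            )
    return out


def write_bed(
    intervals: Sequence[GenomicInterval],
    path: str | Path,
    names: Sequence[str] | None = None,
    scores: Sequence[float] | None = None,
) -> None:
    """Write intervals as BED3 (default) or BED6 when names/scores given."""
    bed6 = names is not None or scores is not None
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            if bed6:
                name = names[i] if names is not None else f"region_{i + 1}"
                score = scores[i] if scores is not None else 0
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n"
                )
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
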