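"""Group-specific accessible-region calling from two peak cohorts.

Given per-sample ATAC-seq (or similar) peak sets for two tumor-type
cohorts, merged consensus regions are classified as specific to one group,
specific to the other, or shared, by a recurrence-threshold rule: a region
is *recurrent* in a group when at least a fraction ``f_min`` of that
group's samples carry an overlapping peak, and *specific* to a group when
it is recurrent there while at most ``f_max`` of the other group's samples
carry it. Recurrent regions specific to neither group are called shared.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .intervals import GenomicInterval, merge_intervals, overlap_bp, write_bed

__all__ = [
    "PeakCohort",
    "SpecificityCall",
    "recurrent_regions",
    "call_specific_regions",
    "read_sample_sheet",
    "write_specificity_calls",
]


@dataclass(frozen=True)
class PeakCohort:
    """A labelled group of samples, each with a called peak set."""

    group: str
    samples: tuple[tuple[str, tuple[GenomicInterval, ...]], ...]

    def __post_init__(self) -> None:
        if not self.samples:
            raise ValueError(f"cohort {self.group!r} has no samples")

    @classmethod
    def from_dict(cls, group: str, peaks: dict[str, Sequence[GenomicInterval]]) -> "PeakCohort":
        return cls(group, tuple((sid, tuple(ivs)) for sid, ivs in peaks.items()))

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def all_peaks(self) -> list[GenomicInterval]:
        return [iv for _, ivs in self.samples for iv in ivs]


@dataclass(frozen=True)
class SpecificityCall:
    """A consensus region with its group-specificity status and per-group
    recurrence fractions."""

    region: GenomicInterval
    status: str  # A_specific | B_specific | shared
    recurrence_A: float
    recurrence_B: float

    def __post_init__(self) -> None:
        if self.status not in ("A_specific", "B_specific", "shared"):
            raise ValueError(f"invalid status {self.status!r}")


def _sample_hits(
    region: GenomicInterval,
    cohort: PeakCohort,
    min_overlap_frac: float,
) -> int:
    """Number of samples with a qualifying overlap of *region*."""
    n = 0
    for _, peaks in cohort.samples:
        for p in peaks:
            ob = overlap_bp(region, p)
            if ob > 0 and ob >= min_overlap_frac * len(p):
                n += 1
                break
    return n


def recurrent_regions(
    cohort: PeakCohort,
    f_min: float,
    min_overlap_frac: float = 0.0,
) -> list[tuple[GenomicInterval, float]]:
    """Merged consensus regions recurrent in at least ``f_min`` of samples.

    The union of all samples' peaks is merged; each merged region's
    recurrence is the fraction of samples with at least one overlapping
    peak (>= 1 bp by default; ``min_overlap_frac`` optionally requires the
    overlap to cover that fraction of the sample peak).
    """
    if not (0 < f_min <= 1):
        raise ValueError(f"f_min must be in (0, 1]; got {f_min}")
    merged = merge_intervals(cohort.all_peaks())
    out = []
    for region in merged:
        rec = _sample_hits(region, cohort, min_overlap_frac) / cohort.n_samples
        if rec >= f_min:
            out.append((region, rec))
    return out


def call_specific_regions(
    cohort_a: PeakCohort,
    cohort_b: PeakCohort,
    f_min: float = 0.5,
    f_max: float = 0.1,
    min_overlap_frac: float = 0.0,
) -> list[SpecificityCall]:
    """Partition consensus regions into A-specific, B-specific and shared.

    Consensus regions are the merged union of all peaks from both cohorts.
    Regions recurrent (>= ``f_min``) in neither group are dropped; every
    remaining region receives exactly one status. Swapping the cohort
    arguments swaps A_specific and B_specific exactly.
    """
    if f_max >= f_min:
        raise ValueError(
            f"f_max ({f_max}) must be strictly below f_min ({f_min})"
        )
    merged = merge_intervals(cohort_a.all_peaks() + cohort_b.all_peaks())
    calls: list[SpecificityCall] = []
    for region in merged:
        rec_a = _sample_hits(region, cohort_a, min_overlap_frac) / cohort_a.n_samples
        rec_b = _sample_hits(region, cohort_b, min_overlap_frac) / cohort_b.n_samples
        if rec_a < f_min and rec_b < f_min:
            continue  # active in neither group
        if rec_a >= f_min and rec_b <= f_max:
            status = "A_specific"
        elif rec_b >= f_min and rec_a <= f_max:
            status = "B_specific"
        else:
            status = "shared"
        calls.append(SpecificityCall(region, status, rec_a, rec_b))
    return calls


def read_sample_sheet(
    path: str | Path, bed_dir: str | Path | None = None
) -> tuple[PeakCohort, PeakCohort]:
    """Read a two/three-column sample sheet (sample ID, group[, BED path])
    plus per-sample BED files, returning the two cohorts in the order the
    groups first appear."""
    from .intervals import read_bed

    bed_dir = Path(bed_dir) if bed_dir is not None else Path(path).parent
    groups: dict[str, dict[str, list[GenomicInterval]]] = {}
    order: list[str] = []
    with open(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            sid, group = row[0], row[1]
            bed_path = Path(row[2]) if len(row) > 2 else bed_dir / f"{sid}.bed"
            if group not in groups:
                groups[group] = {}
                order.append(group)
            groups[group][sid] = read_bed(bed_path)
    if len(order) != 2:
        raise ValueError(f"sample sheet must define exactly 2 groups; got {order}")
    return (
        PeakCohort.from_dict(order[0], groups[order[0]]),
        PeakCohort.from_dict(order[1], groups[order[1]]),
    )


def write_specificity_calls(calls: Sequence[SpecificityCall], out_dir: str | Path) -> dict:
    """Write one BED6 per status (recurrence of the owning group in the
    score column) plus a TSV summary; returns the per-status counts."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    counts = {}
    for status in ("A_specific", "B_specific", "shared"):
        subset = [c for c in calls if c.status == status]
        counts[status] = len(subset)
        scores = [
            c.recurrence_A if status == "A_specific" else
            c.recurrence_B if status == "B_specific" else
            max(c.recurrence_A, c.recurrence_B)
            for c in subset
        ]
        write_bed(
            [c.region for c in subset],
            out_dir / f"{status}.bed",
            names=[f"{status}_{i + 1}" for i in range(len(subset))],
            scores=[round(s, 4) for s in scores],
        )
    with open(out_dir / "specificity_summary.tsv", "w") as fh:
        fh.write("chrom\tstart\tend\tstatus\trecurrence_A\trecurrence_B\n")
        for c in calls:
            fh.write(
                f"{c.region.chrom}\t{c.region.start}\t{c.region.end}\t"
                f"{c.status}\t{c.recurrence_A:.4f}\t{c.recurrence_B:.4f}\n"
            )
    return counts
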