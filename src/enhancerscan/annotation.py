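"""Regulatory-element classification and per-class enrichment testing.

Group-specific accessible regions are classified as promoter, insulator
element (IE), enhancer element (EE) or other by overlap with annotation
tracks, and the per-class composition of the two groups is compared with a
Pearson chi-square test on 2x2 tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from scipy import stats

from .intervals import GenomicInterval, merge_intervals, overlaps

__all__ = [
    "RegulatoryElement",
    "AnnotationTracks",
    "EnrichmentTable",
    "classify_elements",
    "class_enrichment_test",
    "enrichment_report",
]

CLASSES = ("promoter", "IE", "EE")
DEFAULT_PRIORITY = ("promoter", "IE", "EE")


@dataclass(frozen=True)
class RegulatoryElement:
    """A classified regulatory region with identifier and group tag."""

    region: GenomicInterval
    element_class: str  # promoter | IE | EE | other
    element_id: str
    group: str = ""

    def __post_init__(self) -> None:
        if self.element_class not in CLASSES + ("other",):
            raise ValueError(f"invalid element class {self.element_class!r}")


@dataclass(frozen=True)
class AnnotationTracks:
    """Promoter / insulator / enhancer annotation intervals. Each track is
    merged on construction so it is internally non-overlapping."""

    promoter: tuple[GenomicInterval, ...]
    insulator: tuple[GenomicInterval, ...]
    enhancer: tuple[GenomicInterval, ...]

    @classmethod
    def from_lists(cls, promoter, insulator, enhancer) -> "AnnotationTracks":
        return cls(
            tuple(merge_intervals(promoter)),
            tuple(merge_intervals(insulator)),
            tuple(merge_intervals(enhancer)),
        )

    @classmethod
    def from_bed_files(cls, promoter: str | Path, insulator: str | Path,
                       enhancer: str | Path) -> "AnnotationTracks":
        from .intervals import read_bed
        return cls.from_lists(read_bed(promoter), read_bed(insulator),
                              read_bed(enhancer))

    def track(self, element_class: str) -> tuple[GenomicInterval, ...]:
        return {
            "promoter": self.promoter,
            "IE": self.insulator,
            "EE": self.enhancer,
        }[element_class]


def classify_elements(
    regions: Sequence[GenomicInterval],
    tracks: AnnotationTracks,
    priority: Sequence[str] = DEFAULT_PRIORITY,
) -> list[tuple[GenomicInterval, str]]:
    """Assign each region exactly one class.

    Tracks are tried in priority order (default promoter > IE > EE); the
    first track with a >= 1 bp overlap wins. Regions overlapping no track
    are classified "other".
    """
    if sorted(priority) != sorted(CLASSES):
        raise ValueError(f"priority must be a permutation of {CLASSES}")
    out = []
    for region in regions:
        label = "other"
        for cls_name in priority:
            if any(overlaps(region, t) for t in tracks.track(cls_name)):
                label = cls_name
                break
        out.append((region, label))
    return out


def class_enrichment_test(
    count_a: int, total_a: int, count_b: int, total_b: int
) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) on the 2x2
    table ``[[count_a, total_a - count_a], [count_b, total_b - count_b]]``.

    Uses the closed form ``chi2 = N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d))``
    and returns ``(chi2, p)`` with a two-sided p-value from the chi-square
    distribution.
    """
    for count, total in ((count_a, total_a), (count_b, total_b)):
        if count < 0 or total <= 0 or count > total:
            raise ValueError(
                f"invalid cell counts: count={count}, total={total}"
            )
    a, b = count_a, total_a - count_a
    c, d = count_b, total_b - count_b
    n = a + b + c + d
    margins = ((a + b), (c + d), (a + c), (b + d))
    if 0 in margins:
        raise ValueError(
            "chi-square statistic undefined: a marginal total is zero "
            f"(table [[{a},{b}],[{c},{d}]])"
        )
    chi2 = n * (a * d - b * c) ** 2 / (margins[0] * margins[1] * margins[2] * margins[3])
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


@dataclass
class EnrichmentTable:
    """Per-class 2x2 enrichment results between two groups.

    ``significant`` flags p < alpha_sig (default 0.001); ``ns`` flags
    p > alpha_ns (default 0.05), mirroring a two-tier figure annotation.
    """

    group_a: str
    group_b: str
    total_a: int
    total_b: int
    rows: dict[str, dict] = field(default_factory=dict)
    alpha_sig: float = 0.001
    alpha_ns: float = 0.05

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(
                "class\tcount_A\ttotal_A\tprop_A\tcount_B\ttotal_B\tprop_B"
                "\tchi2\tp_value\tsignificant\tns\n"
            )
            for cls_name, r in self.rows.items():
                fh.write(
                    f"{cls_name}\t{r['count_A']}\t{self.total_a}\t"
                    f"{r['count_A'] / self.total_a:.6f}\t{r['count_B']}\t"
                    f"{self.total_b}\t{r['count_B'] / self.total_b:.6f}\t"
                    f"{r['chi2']:.6g}\t{r['p_value']:.6g}\t"
                    f"{r['significant']}\t{r['ns']}\n"
                )

    def to_dict(self) -> dict:
        return {
            "group_A": self.group_a,
            "group_B": self.group_b,
            "total_A": self.total_a,
            "total_B": self.total_b,
            "classes": self.rows,
        }


def enrichment_report(
    calls_a_classified: Sequence[tuple[GenomicInterval, str]],
    calls_b_classified: Sequence[tuple[GenomicInterval, str]],
    group_a: str = "A",
    group_b: str = "B",
    alpha_sig: float = 0.001,
    alpha_ns: float = 0.05,
) -> EnrichmentTable:
    """Per-class counts, proportions and chi-square enrichment between two
    classified region lists."""
    if not calls_a_classified or not calls_b_classified:
        raise ValueError("both classification lists must be non-empty")
    total_a, total_b = len(calls_a_classified), len(calls_b_classified)
    table = EnrichmentTable(group_a, group_b, total_a, total_b,
                            alpha_sig=alpha_sig, alpha_ns=alpha_ns)
    for cls_name in CLASSES:
        count_a = sum(1 for _, c in calls_a_classified if c == cls_name)
        count_b = sum(1 for _, c in calls_b_classified if c == cls_name)
        chi2, p = class_enrichment_test(count_a, total_a, count_b, total_b)
        table.rows[cls_name] = {
            "count_A": count_a,
            "count_B": count_b,
            "chi2": chi2,
            "p_value": p,
            "significant": p < alpha_sig,
            "ns": p > alpha_ns,
        }
    return table
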