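"""SNV-to-enhancer overlap, mutational hotspot clustering, and candidate
enhancer prioritization.

Somatic SNVs from a patient cohort are intersected with one group's
specific enhancer elements; per-element mutation profiles are summarized
(distinct patients, hotspot clusters) and ranked to nominate candidate
elements, optionally supported by curated disease genes in a +/- 1 Mb
neighborhood and enhancer-gene interaction evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .annotation import RegulatoryElement
from .genome import Genome
from .intervals import GenomicInterval, vcf_pos_in_interval
from .variants import SNVRecord, check_ref_consistency

__all__ = [
    "Hotspot",
    "EnhancerMutationProfile",
    "GeneAnnotation",
    "CandidateEE",
    "map_snvs_to_elements",
    "cluster_hotspots",
    "prioritize_candidates",
]

DEFAULT_HOTSPOT_GAP = 7
DEFAULT_NEIGHBORHOOD_BP = 1_000_000


@dataclass(frozen=True)
class Hotspot:
    """A single-linkage cluster of SNV positions on one chromosome."""

    chrom: str
    min_pos: int
    max_pos: int
    snvs: tuple[SNVRecord, ...]

    @property
    def n_snvs(self) -> int:
        return len(self.snvs)

    @property
    def n_positions(self) -> int:
        return len({s.pos for s in self.snvs})

    @property
    def span_bp(self) -> int:
        return self.max_pos - self.min_pos


@dataclass
class EnhancerMutationProfile:
    """All SNVs falling inside one enhancer element."""

    element: RegulatoryElement
    snvs: list[SNVRecord]
    hotspots: list[Hotspot] = field(default_factory=list)

    def __post_init__(self) -> None:
        for snv in self.snvs:
            if snv.chrom != self.element.region.chrom or not vcf_pos_in_interval(
                snv.pos, self.element.region
            ):
                raise ValueError(
                    f"SNV {snv} lies outside element {self.element.element_id}"
                )

    @property
    def n_snvs(self) -> int:
        return len(self.snvs)

    @property
    def n_patients(self) -> int:
        return len({s.patient for s in self.snvs})


@dataclass(frozen=True)
class GeneAnnotation:
    symbol: str
    region: GenomicInterval
    curated: bool = False


@dataclass
class CandidateEE:
    """A prioritized enhancer element with its supporting evidence."""

    profile: EnhancerMutationProfile
    nearby_genes: list[GeneAnnotation]
    interactions: list[dict]
    rank: int = 0

    @property
    def has_high_confidence_interaction(self) -> bool:
        return any(i.get("confidence") == "high" for i in self.interactions)


def map_snvs_to_elements(
    snvs: Sequence[SNVRecord],
    elements: Sequence[RegulatoryElement],
    genome: Genome | None = None,
    hotspot_gap: int = DEFAULT_HOTSPOT_GAP,
) -> tuple[list[EnhancerMutationProfile], list[SNVRecord]]:
    """Intersect SNVs with elements.

    Returns one profile per element carrying >= 1 SNV (with hotspots
    clustered at ``hotspot_gap``), plus the spill-over list of SNVs that
    overlap no element. When a genome is supplied, every SNV's ref allele
    is checked against it first. SNVs are assigned by 1-based-to-half-open
    containment; a VCF position equal to an element's BED start falls one
    base before the element and is not assigned.
    """
    if genome is not None:
        check_ref_consistency(snvs, genome)
    by_element: dict[str, list[SNVRecord]] = {e.element_id: [] for e in elements}
    spillover: list[SNVRecord] = []
    for snv in snvs:
        hit = False
        for elem in elements:
            if snv.chrom == elem.region.chrom and vcf_pos_in_interval(
                snv.pos, elem.region
            ):
                by_element[elem.element_id].append(snv)
                hit = True
        if not hit:
            spillover.append(snv)
    profiles = []
    for elem in elements:
        hits = by_element[elem.element_id]
        if hits:
            profiles.append(
                EnhancerMutationProfile(
                    elem, hits, hotspots=cluster_hotspots(hits, gap=hotspot_gap)
                )
            )
    return profiles, spillover


def cluster_hotspots(
    snvs: Sequence[SNVRecord], gap: int = DEFAULT_HOTSPOT_GAP
) -> list[Hotspot]:
    """Single-linkage clustering of SNV positions per chromosome: two SNVs
    join one cluster iff their positions differ by <= ``gap`` bp, directly
    or transitively. ``gap=0`` yields one cluster per distinct position."""
    if gap < 0:
        raise ValueError("gap must be >= 0")
    by_chrom: dict[str, list[SNVRecord]] = {}
    for snv in snvs:
        by_chrom.setdefault(snv.chrom, []).append(snv)
    clusters: list[Hotspot] = []
    for chrom in sorted(by_chrom):
        members: list[SNVRecord] = []
        for snv in sorted(by_chrom[chrom], key=lambda s: s.pos):
            if members and snv.pos - members[-1].pos <= gap:
                members.append(snv)
            else:
                if members:
                    clusters.append(_make_hotspot(chrom, members))
                members = [snv]
        if members:
            clusters.append(_make_hotspot(chrom, members))
    return clusters


def _make_hotspot(chrom: str, members: list[SNVRecord]) -> Hotspot:
    positions = [s.pos for s in members]
    return Hotspot(chrom, min(positions), max(positions), tuple(members))


def _gene_distance(element: RegulatoryElement, gene: GeneAnnotation) -> int | None:
    """Distance from the element midpoint to the gene's nearest edge;
    None when on different chromosomes."""
    if gene.region.chrom != element.region.chrom:
        return None
    mid = element.region.midpoint
    if gene.region.start <= mid < gene.region.end:
        return 0
    return min(abs(gene.region.start - mid), abs(gene.region.end - 1 - mid))


def prioritize_candidates(
    profiles: Sequence[EnhancerMutationProfile],
    genes: Sequence[GeneAnnotation] = (),
    interactions: Sequence[dict] = (),
    top_n: int = 3,
    neighborhood_bp: int = DEFAULT_NEIGHBORHOOD_BP,
) -> list[CandidateEE]:
    """Rank mutated elements and return the top ``top_n``.

    The ordering key is lexicographic: distinct mutated patients
    (descending), SNV count (descending), curated genes within the +/-
    ``neighborhood_bp`` window of the element midpoint (descending),
    presence of a high-confidence interaction (descending), element ID
    (ascending) as the final tiebreak. Recurrence across patients outranks
    raw SNV count. Interactions (dicts with keys element_id, gene,
    confidence) are supporting evidence only, never a filter.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    candidates = []
    for profile in profiles:
        nearby = [
            g
            for g in genes
            if g.curated
            and (d := _gene_distance(profile.element, g)) is not None
            and d <= neighborhood_bp
        ]
        links = [
            i for i in interactions
            if i.get("element_id") == profile.element.element_id
        ]
        candidates.append(CandidateEE(profile, nearby, links))
    candidates.sort(
        key=lambda c: (
            -c.profile.n_patients,
            -c.profile.n_snvs,
            -len(c.nearby_genes),
            -int(c.has_high_confidence_interaction),
            c.profile.element.element_id,
        )
    )
    top = candidates[:top_n]
    for i, cand in enumerate(top, start=1):
        cand.rank = i
    return top


def write_candidate_table(candidates: Sequence[CandidateEE], path: str | Path) -> None:
    """TSV candidate table: element, coords, patients, SNVs, hotspots,
    nearby curated genes, rank."""
    with open(path, "w") as fh:
        fh.write(
            "rank\telement_id\tchrom\tstart\tend\tn_patients\tn_snvs\t"
            "n_hotspots\thotspots\tnearby_curated_genes\thigh_conf_interaction\n"
        )
        for c in candidates:
            iv = c.profile.element.region
            hotspots = ";".join(
                f"{h.chrom}:{h.min_pos}-{h.max_pos}(n={h.n_snvs})"
                for h in c.profile.hotspots
            )
            genes = ";".join(sorted(g.symbol for g in c.nearby_genes))
            fh.write(
                f"{c.rank}\t{c.profile.element.element_id}\t{iv.chrom}\t"
                f"{iv.start}\t{iv.end}\t{c.profile.n_patients}\t"
                f"{c.profile.n_snvs}\t{len(c.profile.hotspots)}\t{hotspots}\t"
                f"{genes}\t{c.has_high_confidence_interaction}\n"
            )
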