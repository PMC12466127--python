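"""Synthetic-data generation with machine-readable planted ground truth.

Every input the pipeline consumes can be generated here: a small random
reference genome, two cohorts of per-sample accessibility peak sets with
planted group-specific and shared regions, promoter/insulator/enhancer
annotation tracks with curated disease genes and enhancer-gene
interactions, per-patient somatic SNV calls (plus germline known-SNP
decoys), a JASPAR-style PFM library containing motifs whose best match is
created or destroyed by a planted allele, and a multi-section targeted
genotype table with planted callability, mutation frequency, concordance,
co-occurrence and peritumoral structure.

All generators are pure functions of their parameters and a mandatory
seed. Planted fractions are realized with exact integer arithmetic
(counts rounded to the nearest achievable integer and recorded in the
ground truth) rather than Bernoulli draws, so recovery assertions can be
exact.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Sequence

import numpy as np

from .annotation import AnnotationTracks, RegulatoryElement
from .cohort import GenotypeTable, Specimen
from .genome import Genome, extract_window, write_fasta
from .intervals import GenomicInterval, write_bed
from .motifs import PFM, write_jaspar
from .overlap import GeneAnnotation
from .specificity import PeakCohort
from .variants import KnownSNPSet, SNVRecord, write_known_snps, write_vcf

__all__ = [
    "generate_genome",
    "generate_cohorts",
    "generate_annotations",
    "generate_snvs",
    "generate_pwms",
    "generate_genotype_table",
    "simulate_paper_like",
    "save_ground_truth",
    "load_ground_truth",
]

BASES = "ACGT"

# Paper-like preset defaults: cohort sizes of the two accessibility
# groups, the WGS discovery cohort, and the targeted validation cohort.
DEFAULT_N_A = 9
DEFAULT_N_B = 12
DEFAULT_N_SPECIFIC_A = 20
DEFAULT_N_SPECIFIC_B = 30
DEFAULT_N_SHARED = 50
DEFAULT_N_WGS_PATIENTS = 39
DEFAULT_N_VALIDATION_PATIENTS = 54
DEFAULT_N_MULTIFOCAL = 11
DEFAULT_N_PERITUMORAL = 9
DEFAULT_N_COOCCURRENT = 7
DEFAULT_FREQUENCIES = (0.30, 0.15, 0.0, 0.12, 0.18)
DEFAULT_CALLABILITY = (0.95, 0.90, 0.90, 0.88, 0.50)
DEFAULT_CONCORDANCE = (0.90, 0.82, 1.0, 0.78, 0.60)
DEFAULT_CLASS_MIX = {"promoter": 0.35, "IE": 0.20, "EE": 0.35}


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def generate_genome(
    n_chroms: int = 2,
    length_bp: int = 100_000,
    gc: float = 0.41,
    seed: int | None = None,
) -> Genome:
    """Random genome of ``n_chroms`` chromosomes of ``length_bp`` each with
    the given expected GC fraction (default 0.41, genome-wide human)."""
    if seed is None:
        raise ValueError("seed is a mandatory parameter")
    if length_bp < 10_000:
        raise ValueError("chromosome length must be >= 10 kb")
    if not 0 <= gc <= 1:
        raise ValueError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    at, gchalf = (1 - gc) / 2, gc / 2
    probs = [at, gchalf, gchalf, at]  # A, C, G, T
    seqs = {}
    for i in range(n_chroms):
        draws = rng.choice(4, size=length_bp, p=probs)
        seqs[f"chr{i + 1}"] = "".join(BASES[j] for j in draws)
    return Genome(seqs)


# ---------------------------------------------------------------------------
# accessibility cohorts
# ---------------------------------------------------------------------------

def _place_regions(
    genome: Genome,
    n_regions: int,
    rng: np.random.Generator,
    min_len: int = 300,
    max_len: int = 800,
    min_gap: int = 150,
    max_gap: int = 400,
) -> list[GenomicInterval]:
    """Place non-overlapping regions sequentially across chromosomes with
    random lengths and inter-region gaps; gaps keep distinct regions from
    merging downstream."""
    placements: list[GenomicInterval] = []
    chroms = list(genome.chroms)
    ci, cursor = 0, 0
    for _ in range(n_regions):
        length = int(rng.integers(min_len, max_len + 1))
        gap = int(rng.integers(min_gap, max_gap + 1))
        while ci < len(chroms) and cursor + gap + length > genome.length(chroms[ci]):
            ci += 1
            cursor = 0
        if ci >= len(chroms):
            raise ValueError(
                f"infeasible packing: cannot place {n_regions} regions in "
                f"the genome"
            )
        start = cursor + gap
        placements.append(GenomicInterval(chroms[ci], start, start + length))
        cursor = start + length
    return placements


def generate_cohorts(
    genome: Genome,
    n_a: int = DEFAULT_N_A,
    n_b: int = DEFAULT_N_B,
    n_specific_a: int = DEFAULT_N_SPECIFIC_A,
    n_specific_b: int = DEFAULT_N_SPECIFIC_B,
    n_shared: int = DEFAULT_N_SHARED,
    dropout: float = 0.0,
    seed: int | None = None,
) -> tuple[PeakCohort, PeakCohort, dict]:
    """Two peak cohorts with planted group-specific and shared regions.

    Each group-specific region is dropped from exactly
    ``round(dropout * n_group)`` samples of its own group (chosen at
    random) and never appears in the other group; shared regions appear
    in every sample of both groups. With ``dropout <= 1 - f_min`` the
    planted statuses therefore remain exactly recoverable.
    """
    if seed is None:
        raise ValueError("seed is a mandatory parameter")
    if not 0 <= dropout < 1:
        raise ValueError("dropout must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n_regions = n_specific_a + n_specific_b + n_shared
    placements = _place_regions(genome, n_regions, rng)
    statuses = (
        ["A_specific"] * n_specific_a
        + ["B_specific"] * n_specific_b
        + ["shared"] * n_shared
    )
    rng.shuffle(statuses)

    samples_a = [f"A{i + 1:02d}" for i in range(n_a)]
    samples_b = [f"B{i + 1:02d}" for i in range(n_b)]
    peaks_a: dict[str, list[GenomicInterval]] = {s: [] for s in samples_a}
    peaks_b: dict[str, list[GenomicInterval]] = {s: [] for s in samples_b}

    regions_gt = []
    counters = {"A_specific": 0, "B_specific": 0, "shared": 0}
    for region, status in zip(placements, statuses):
        counters[status] += 1
        rid = f"{status[0].upper()}R{counters[status]:03d}" if status != "shared" \
            else f"SR{counters[status]:03d}"
        if status == "shared":
            carriers_a, carriers_b = list(samples_a), list(samples_b)
        elif status == "A_specific":
            n_drop = _round_half_up(dropout * n_a)
            dropped = set(rng.choice(n_a, size=n_drop, replace=False).tolist())
            carriers_a = [s for i, s in enumerate(samples_a) if i not in dropped]
            carriers_b = []
        else:
            n_drop = _round_half_up(dropout * n_b)
            dropped = set(rng.choice(n_b, size=n_drop, replace=False).tolist())
            carriers_a = []
            carriers_b = [s for i, s in enumerate(samples_b) if i not in dropped]
        for s in carriers_a:
            peaks_a[s].append(region)
        for s in carriers_b:
            peaks_b[s].append(region)
        regions_gt.append(
            {
                "id": rid,
                "chrom": region.chrom,
                "start": region.start,
                "end": region.end,
                "status": status,
                "recurrence_A": len(carriers_a) / n_a,
                "recurrence_B": len(carriers_b) / n_b,
            }
        )
    cohort_a = PeakCohort.from_dict("A", peaks_a)
    cohort_b = PeakCohort.from_dict("B", peaks_b)
    gt = {
        "n_samples": {"A": n_a, "B": n_b},
        "dropout": dropout,
        "counts": {
            "A_specific": n_specific_a,
            "B_specific": n_specific_b,
            "shared": n_shared,
        },
        "regions": regions_gt,
    }
    return cohort_a, cohort_b, gt


# ---------------------------------------------------------------------------
# annotations, genes, interactions
# ---------------------------------------------------------------------------

def _apportion(n: int, mix: dict[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment of *n* items over class fractions;
    the remainder is assigned to 'other'."""
    if sum(mix.values()) > 1 + 1e-9:
        raise ValueError("class_mix proportions must sum to <= 1")
    quotas = {c: n * f for c, f in mix.items()}
    counts = {c: int(math.floor(q)) for c, q in quotas.items()}
    leftover = int(round(n * sum(mix.values()))) - sum(counts.values())
    by_frac = sorted(mix, key=lambda c: (-(quotas[c] - counts[c]), c))
    for c in by_frac[:leftover]:
        counts[c] += 1
    counts["other"] = n - sum(counts.values())
    return counts


def generate_annotations(
    cohort_gt: dict,
    class_mix: dict[str, float] | None = None,
    seed: int | None = None,
    genome: Genome | None = None,
    neighborhood_bp: int = 1_000_000,
    n_candidate_ees: int = 3,
    gene_length: int = 1_000,
) -> tuple[AnnotationTracks, list[GeneAnnotation], list[dict], dict]:
    """Annotation tracks, curated genes and interactions for planted regions.

    Each planted group-specific region is assigned a class by exact
    largest-remainder apportionment of ``class_mix`` (default 35%
    promoter, 20% insulator, 35% enhancer, remainder other); its class
    track receives exactly its interval, so classification recovery is
    exact by construction. Curated disease genes are placed near (and,
    when chromosome space allows, at the +/- ``neighborhood_bp`` boundary
    of) the first ``n_candidate_ees`` A-specific enhancers, plus one
    curated gene on a different chromosome (outside any neighborhood on
    the gene's absence chromosome).
    """
    if seed is None:
        raise ValueError("seed is a mandatory parameter")
    class_mix = dict(class_mix) if class_mix is not None else dict(DEFAULT_CLASS_MIX)
    rng = np.random.default_rng(seed)

    tracks: dict[str, list[GenomicInterval]] = {"promoter": [], "IE": [], "EE": []}
    elements_gt = []
    class_counts: dict[str, dict[str, int]] = {}
    for group, status in (("A", "A_specific"), ("B", "B_specific")):
        regions = [r for r in cohort_gt["regions"] if r["status"] == status]
        counts = _apportion(len(regions), class_mix)
        class_counts[group] = counts
        labels = (
            ["promoter"] * counts["promoter"]
            + ["IE"] * counts["IE"]
            + ["EE"] * counts["EE"]
            + ["other"] * counts["other"]
        )
        rng.shuffle(labels)
        per_class = {c: 0 for c in ("promoter", "IE", "EE", "other")}
        for rec, label in zip(regions, labels):
            per_class[label] += 1
            eid = f"{label}-{group}-{per_class[label]:03d}"
            iv = GenomicInterval(rec["chrom"], rec["start"], rec["end"])
            if label != "other":
                tracks[label].append(iv)
            elements_gt.append(
                {
                    "element_id": eid,
                    "region_id": rec["id"],
                    "chrom": rec["chrom"],
                    "start": rec["start"],
                    "end": rec["end"],
                    "group": group,
                    "class": label,
                }
            )

    annotation_tracks = AnnotationTracks.from_lists(
        tracks["promoter"], tracks["IE"], tracks["EE"]
    )

    # curated genes around the first n_candidate_ees A-specific enhancers
    a_ees = [e for e in elements_gt if e["group"] == "A" and e["class"] == "EE"]
    genes: list[GeneAnnotation] = []
    gidx = 0
    chrom_lengths = (
        {c: genome.length(c) for c in genome.chroms}
        if genome is not None
        else {}
    )

    def _chrom_len(chrom: str) -> int:
        if chrom in chrom_lengths:
            return chrom_lengths[chrom]
        return max(
            r["end"] for r in cohort_gt["regions"] if r["chrom"] == chrom
        ) + 2 * neighborhood_bp + 10 * gene_length

    all_chroms = sorted({r["chrom"] for r in cohort_gt["regions"]})
    for e in a_ees[:n_candidate_ees]:
        mid = (e["start"] + e["end"]) // 2
        # two curated genes inside the neighborhood on the same chromosome
        for _ in range(2):
            gidx += 1
            limit = min(neighborhood_bp, _chrom_len(e["chrom"]) - gene_length - 1)
            offset = int(rng.integers(2_000, max(2_001, limit // 2)))
            start = max(0, min(mid + offset, _chrom_len(e["chrom"]) - gene_length))
            genes.append(
                GeneAnnotation(
                    f"GENE_C{gidx:02d}",
                    GenomicInterval(e["chrom"], start, start + gene_length),
                    curated=True,
                )
            )
        # one curated gene on a different chromosome (outside by definition)
        other = [c for c in all_chroms if c != e["chrom"]]
        if other:
            gidx += 1
            chrom = other[0]
            start = int(rng.integers(0, _chrom_len(chrom) - gene_length))
            genes.append(
                GeneAnnotation(
                    f"GENE_C{gidx:02d}",
                    GenomicInterval(chrom, start, start + gene_length),
                    curated=True,
                )
            )
        # boundary pair at exactly +/- (neighborhood_bp, neighborhood_bp + 1)
        if mid + neighborhood_bp + 1 + gene_length < _chrom_len(e["chrom"]):
            gidx += 1
            genes.append(
                GeneAnnotation(
                    f"GENE_C{gidx:02d}",
                    GenomicInterval(
                        e["chrom"], mid + neighborhood_bp,
                        mid + neighborhood_bp + gene_length
                    ),
                    curated=True,
                )
            )
            gidx += 1
            genes.append(
                GeneAnnotation(
                    f"GENE_C{gidx:02d}",
                    GenomicInterval(
                        e["chrom"], mid + neighborhood_bp + 1,
                        mid + neighborhood_bp + 1 + gene_length
                    ),
                    curated=True,
                )
            )

    # non-curated background genes
    for i in range(5):
        chrom = all_chroms[i % len(all_chroms)]
        start = int(rng.integers(0, _chrom_len(chrom) - gene_length))
        genes.append(
            GeneAnnotation(
                f"GENE_B{i + 1:02d}",
                GenomicInterval(chrom, start, start + gene_length),
                curated=False,
            )
        )

    # interaction evidence for the first two candidate enhancers
    interactions = []
    candidate_ids = [e["element_id"] for e in a_ees[:n_candidate_ees]]
    curated_syms = [g.symbol for g in genes if g.curated]
    if candidate_ids and curated_syms:
        interactions.append(
            {"element_id": candidate_ids[0], "gene": curated_syms[0],
             "confidence": "high"}
        )
    if len(candidate_ids) > 1 and len(curated_syms) > 1:
        interactions.append(
            {"element_id": candidate_ids[1], "gene": curated_syms[1],
             "confidence": "low"}
        )

    # expected curated-gene neighborhoods, from placement arithmetic alone
    expected_nearby = {}
    for e in elements_gt:
        if e["class"] != "EE":
            continue
        mid = (e["start"] + e["end"]) // 2
        nearby = []
        for g in genes:
            if not g.curated or g.region.chrom != e["chrom"]:
                continue
            if g.region.start <= mid < g.region.end:
                dist = 0
            else:
                dist = min(abs(g.region.start - mid), abs(g.region.end - 1 - mid))
            if dist <= neighborhood_bp:
                nearby.append(g.symbol)
        expected_nearby[e["element_id"]] = sorted(nearby)

    gt = {
        "class_mix": class_mix,
        "class_counts": class_counts,
        "elements": elements_gt,
        "neighborhood_bp": neighborhood_bp,
        "candidate_ees": candidate_ids,
        "expected_nearby_curated": expected_nearby,
        "genes": [
            {
                "symbol": g.symbol,
                "chrom": g.region.chrom,
                "start": g.region.start,
                "end": g.region.end,
                "curated": g.curated,
            }
            for g in genes
        ],
        "interactions": interactions,
    }
    return annotation_tracks, genes, interactions, gt


# ---------------------------------------------------------------------------
# somatic SNVs and germline decoys
# ---------------------------------------------------------------------------

def _random_alt(ref: str, rng: np.random.Generator) -> str:
    choices = [b for b in BASES if b != ref]
    return choices[int(rng.integers(0, 3))]


def default_recurrent_spec(annotation_gt: dict) -> list[dict]:
    """Paper-like planting plan over the first three A-specific enhancers:
    two elements with two single-patient SNVs in distinct sub-regions, and
    one element with a recurrent SNV shared by three patients."""
    candidates = annotation_gt["candidate_ees"]
    if len(candidates) < 3:
        raise ValueError("need at least 3 A-specific enhancer elements")
    return [
        {"element_id": candidates[0],
         "positions": [
             {"offset_frac": 0.25, "patients": ["P05"]},
             {"offset_frac": 0.75, "patients": ["P06"]},
         ]},
        {"element_id": candidates[1],
         "positions": [
             {"offset_frac": 0.25, "patients": ["P07"]},
             {"offset_frac": 0.75, "patients": ["P08"]},
         ]},
        {"element_id": candidates[2],
         "positions": [
             {"offset_frac": 0.5, "patients": ["P01", "P02", "P03"]},
         ]},
    ]


def generate_snvs(
    genome: Genome,
    annotation_gt: dict,
    n_patients: int = DEFAULT_N_WGS_PATIENTS,
    recurrent_spec: Sequence[dict] | None = None,
    n_germline_decoys: int = 3,
    n_spillover: int = 1,
    seed: int | None = None,
) -> tuple[list[SNVRecord], KnownSNPSet, dict]:
    """Per-patient somatic SNVs planted inside chosen enhancers, plus
    germline known-SNP decoys and spill-over SNVs outside any element.

    ``recurrent_spec`` names target elements and, per planted position,
    the fractional offset within the element and the carrying patients.
    Ref alleles are read from the genome; alt alleles are drawn at random.
    """
    if seed is None:
        raise ValueError("seed is a mandatory parameter")
    rng = np.random.default_rng(seed)
    if recurrent_spec is None:
        recurrent_spec = default_recurrent_spec(annotation_gt)
    elements = {e["element_id"]: e for e in annotation_gt["elements"]}
    patients = [f"P{i + 1:02d}" for i in range(n_patients)]

    snvs: list[SNVRecord] = []
    planted_gt = []
    for entry in recurrent_spec:
        elem = elements.get(entry["element_id"])
        if elem is None:
            raise ValueError(f"unknown element {entry['element_id']!r}")
        length = elem["end"] - elem["start"]
        positions_gt = []
        for pos_spec in entry["positions"]:
            if "offset_frac" in pos_spec:
                offset = int(pos_spec["offset_frac"] * (length - 1))
            else:
                offset = int(pos_spec["offset"])
            if not 0 <= offset < length:
                raise ValueError(
                    f"planted offset {offset} outside element "
                    f"{entry['element_id']} (length {length})"
                )
            pos = elem["start"] + offset + 1  # 1-based
            ref = genome.base_at(elem["chrom"], pos)
            alt = pos_spec.get("alt") or _random_alt(ref, rng)
            for patient in pos_spec["patients"]:
                if patient not in patients:
                    raise ValueError(f"unknown patient {patient!r}")
                snvs.append(
                    SNVRecord(elem["chrom"], pos, ref, alt, patient=patient,
                              origin="somatic")
                )
            positions_gt.append(
                {"chrom": elem["chrom"], "pos": pos, "ref": ref, "alt": alt,
                 "patients": list(pos_spec["patients"])}
            )
        planted_gt.append(
            {
                "element_id": entry["element_id"],
                "positions": positions_gt,
                "n_snvs": sum(len(p["patients"]) for p in positions_gt),
                "n_patients": len(
                    {pt for p in positions_gt for pt in p["patients"]}
                ),
            }
        )

    # spill-over somatic SNVs in shared (non-element) territory
    ee_spans = [
        (e["chrom"], e["start"], e["end"]) for e in annotation_gt["elements"]
    ]

    def _outside_elements(chrom: str, pos: int) -> bool:
        return not any(
            c == chrom and s < pos <= e for c, s, e in ee_spans
        )

    spillover_gt = []
    chroms = genome.chroms
    for i in range(n_spillover):
        while True:
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            pos = int(rng.integers(100, genome.length(chrom) - 100))
            if _outside_elements(chrom, pos):
                break
        ref = genome.base_at(chrom, pos)
        alt = _random_alt(ref, rng)
        patient = patients[min(8 + i, n_patients - 1)]
        snvs.append(SNVRecord(chrom, pos, ref, alt, patient=patient,
                              origin="somatic"))
        spillover_gt.append({"chrom": chrom, "pos": pos, "ref": ref,
                             "alt": alt, "patient": patient})

    # germline decoys: present in VCFs and in the known-SNP catalog;
    # the first decoy is planted inside a candidate enhancer
    decoys_gt = []
    snp_entries = []
    for i in range(n_germline_decoys):
        if i == 0 and planted_gt:
            elem = elements[planted_gt[0]["element_id"]]
            taken = {p["pos"] for p in planted_gt[0]["positions"]}
            while True:
                pos = int(rng.integers(elem["start"] + 1, elem["end"] + 1))
                if all(abs(pos - t) > 10 for t in taken):
                    break
            chrom = elem["chrom"]
        else:
            while True:
                chrom = chroms[int(rng.integers(0, len(chroms)))]
                pos = int(rng.integers(100, genome.length(chrom) - 100))
                if _outside_elements(chrom, pos):
                    break
        ref = genome.base_at(chrom, pos)
        alt = _random_alt(ref, rng)
        patient = patients[int(rng.integers(0, n_patients))]
        snvs.append(SNVRecord(chrom, pos, ref, alt, patient=patient,
                              origin="germline"))
        snp_entries.append((chrom, pos, ref, alt))
        decoys_gt.append({"chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
                          "patient": patient})

    known_snps = KnownSNPSet(snp_entries)
    by_patients = {
        e["element_id"]: e["n_patients"] for e in planted_gt
    }
    expected_top1 = (
        max(sorted(by_patients), key=lambda k: by_patients[k])
        if by_patients
        else None
    )
    gt = {
        "n_patients": n_patients,
        "patients": patients,
        "planted_elements": planted_gt,
        "spillover": spillover_gt,
        "germline_decoys": decoys_gt,
        "expected_top1": expected_top1,
        "n_somatic": sum(e["n_snvs"] for e in planted_gt) + len(spillover_gt),
    }
    return snvs, known_snps, gt


# ---------------------------------------------------------------------------
# PWM library with planted gain/loss motifs
# ---------------------------------------------------------------------------

def _planted_pfm(
    name: str,
    matrix_id: str,
    window: str,
    centre: int,
    motif_len: int = 8,
    strong: float = 100.0,
    weak_major: float = 85.0,
    weak_minor: float = 5.0,
) -> PFM:
    """PFM whose consensus equals the window subsequence spanning the
    centre, with the centre column maximally discriminative (count mass
    entirely on the favoured base) and moderately informative flanking
    columns, so a single-base change at the centre moves the best relative
    score across the site threshold."""
    var_col = motif_len // 2
    start = centre - var_col
    sub = window[start : start + motif_len]
    counts = np.zeros((4, motif_len))
    for j, base in enumerate(sub):
        bi = BASES.index(base)
        if j == var_col:
            counts[bi, j] = strong
        else:
            counts[:, j] = weak_minor
            counts[bi, j] = weak_major
    return PFM(name, matrix_id, counts)


def generate_pwms(
    snv_gt: dict,
    genome: Genome,
    n_background_motifs: int = 8,
    planted: Sequence[tuple[dict, str]] | None = None,
    seed: int | None = None,
    flank: int = 7,
) -> tuple[list[PFM], dict]:
    """JASPAR-style PFM library with planted variant-responsive motifs.

    For ``effect='gain'`` the motif consensus equals the mutant window's
    subsequence spanning the variant (so the alternate allele creates a
    site the wild-type base destroys); ``effect='loss'`` is the mirror
    construction on the wild-type window. Background motifs are random
    and unrelated to the planted windows. ``planted`` pairs position
    records (dicts with chrom/pos/ref/alt) with effects; by default the
    first planted position of the recurrent element gains and the first
    position of the first element loses.
    """
    if seed is None:
        raise ValueError("seed is a mandatory parameter")
    rng = np.random.default_rng(seed)
    if planted is None:
        planted = []
        elems = snv_gt["planted_elements"]
        if elems:
            top = snv_gt.get("expected_top1")
            top_elem = next(
                (e for e in elems if e["element_id"] == top), elems[-1]
            )
            planted.append((top_elem["positions"][0], "gain"))
            first = elems[0]
            if first is not top_elem:
                planted.append((first["positions"][0], "loss"))

    pfms: list[PFM] = []
    planted_gt = []
    for i, (pos_rec, effect) in enumerate(planted, start=1):
        if effect not in ("gain", "loss"):
            raise ValueError(f"invalid planted effect {effect!r}")
        wt_window = extract_window(genome, pos_rec["chrom"], pos_rec["pos"], flank)
        if wt_window[flank] != pos_rec["ref"]:
            raise ValueError(f"planted SNV ref mismatch at "
                             f"{pos_rec['chrom']}:{pos_rec['pos']}")
        mut_window = (
            wt_window[:flank] + pos_rec["alt"] + wt_window[flank + 1 :]
        )
        source = mut_window if effect == "gain" else wt_window
        name = f"TF{effect.upper()}{i}"
        pfms.append(_planted_pfm(name, f"SYN{i:04d}.1", source, flank))
        planted_gt.append(
            {
                "tf_name": name,
                "effect": effect,
                "expected_category": "novel" if effect == "gain" else "lost_site",
                "chrom": pos_rec["chrom"],
                "pos": pos_rec["pos"],
                "ref": pos_rec["ref"],
                "alt": pos_rec["alt"],
            }
        )

    for i in range(n_background_motifs):
        length = int(rng.integers(6, 11))
        counts = np.zeros((4, length))
        for j in range(length):
            major = int(rng.integers(0, 4))
            minor = rng.integers(2, 15, size=4).astype(float)
            minor[major] = float(rng.integers(50, 90))
            counts[:, j] = minor
        pfms.append(PFM(f"TFBG{i + 1:02d}", f"BG{i + 1:04d}.1", counts))

    gt = {
        "planted_motifs": planted_gt,
        "n_background": n_background_motifs,
        "flank": flank,
    }
    return pfms, gt


# ---------------------------------------------------------------------------
# targeted-sequencing genotype table
# ---------------------------------------------------------------------------

def generate_genotype_table(
    regions: dict[str, dict] | None = None,
    n_patients: int = DEFAULT_N_VALIDATION_PATIENTS,
    frequencies: Sequence[float] = DEFAULT_FREQUENCIES,
    callability: Sequence[float] = DEFAULT_CALLABILITY,
    concordance: Sequence[float] = DEFAULT_CONCORDANCE,
    n_multifocal: int = DEFAULT_N_MULTIFOCAL,
    n_cooccurrent: int = DEFAULT_N_COOCCURRENT,
    n_peritumoral: int = DEFAULT_N_PERITUMORAL,
    seed: int | None = None,
    peritumoral_violation: bool = False,
) -> tuple[GenotypeTable, dict]:
    """Multi-section targeted genotype table realizing the planted design.

    Planted per-region mutation frequencies, callability and multifocal
    concordance are hit exactly up to integer rounding (realized values
    are recorded in the ground truth); exactly ``n_cooccurrent`` patients
    carry mutations in two distinct regions; ``n_peritumoral`` peritumoral
    specimens from mutated patients carry no mutation (unless a violation
    is explicitly planted). Infeasible plans (for example a concordance
    target below 1 for a region with zero mutation frequency) raise.

    ``regions`` maps region name to a dict with keys chrom/start/end and
    primary/secondary variant records; a synthetic five-region default on
    a virtual chromosome is used when omitted.
    """
    if seed is None:
        raise ValueError("seed is a mandatory parameter")
    frequencies = list(frequencies)
    callability = list(callability)
    concordance = list(concordance)
    if not (len(frequencies) == len(callability) == len(concordance)):
        raise ValueError("frequencies, callability and concordance must have "
                         "equal lengths")
    for name, values in (("frequency", frequencies), ("callability", callability),
                         ("concordance", concordance)):
        if any(not 0 <= v <= 1 for v in values):
            raise ValueError(f"every planted {name} must lie in [0, 1]")
    rng = np.random.default_rng(seed)

    if regions is None:
        regions = {}
        for i in range(len(frequencies)):
            start = 1_000 + i * 500
            pos = start + 60
            regions[f"EE-R{i + 1}"] = {
                "chrom": "chrV",
                "start": start,
                "end": start + 120,
                "primary": {"pos": pos + 1, "ref": "C", "alt": "G"},
                "secondary": {"pos": pos + 4, "ref": "A", "alt": "T"},
            }
    region_names = list(regions)
    if len(region_names) != len(frequencies):
        raise ValueError("number of regions must match the planted fractions")

    patients = [f"HUSE.{i + 1:03d}" for i in range(n_patients)]
    if n_multifocal > n_patients:
        raise ValueError("n_multifocal exceeds n_patients")
    multifocal = patients[:n_multifocal]
    singles = patients[n_multifocal:]

    specimens: list[Specimen] = []
    for p in patients:
        specimens.append(Specimen(f"{p}-S1", p, "S1", "tumor"))
        if p in multifocal:
            specimens.append(Specimen(f"{p}-S2", p, "S2", "tumor"))
    n_tumor = len(specimens)

    # integer design per region
    design = []
    mf_pool = list(multifocal)
    for r, (freq, call, conc) in enumerate(
        zip(frequencies, callability, concordance)
    ):
        n_callable = _round_half_up(call * n_tumor)
        n_ns = n_tumor - n_callable
        if n_ns > len(singles):
            raise ValueError(
                f"infeasible plan: region {region_names[r]} needs {n_ns} "
                f"non-sequenced cells but only {len(singles)} singleton "
                "specimens are available"
            )
        m = n_multifocal  # all multifocal pairs stay callable
        if m < 2 and conc < 1:
            raise ValueError("infeasible plan: concordance target below 1 "
                             "requires >= 2 multifocal sections")
        n_agree = _round_half_up(conc * m)
        n_discordant = m - n_agree
        n_mut = _round_half_up(freq * n_callable)
        if n_mut == 0 and n_discordant > 0:
            raise ValueError(
                f"infeasible plan: region {region_names[r]} has zero planted "
                "mutation frequency but a concordance target below 1 "
                "(discordance requires a mutant section)"
            )
        if n_discordant > len(mf_pool):
            raise ValueError("infeasible plan: not enough multifocal patients "
                             "for the planted discordance")
        if n_mut < n_discordant:
            raise ValueError(
                f"infeasible plan: region {region_names[r]} plants fewer "
                "mutant cells than discordant section pairs"
            )
        discordant_patients = [mf_pool.pop(0) for _ in range(n_discordant)]
        design.append(
            {
                "region": region_names[r],
                "n_callable": n_callable,
                "n_ns": n_ns,
                "n_mut": n_mut,
                "n_singleton_mut": n_mut - n_discordant,
                "m_multifocal": m,
                "n_discordant": n_discordant,
                "discordant_patients": discordant_patients,
            }
        )

    # singleton mutation sets with exactly n_cooccurrent double-mutated patients
    capacities = {d["region"]: d["n_singleton_mut"] for d in design}
    if sum(capacities.values()) - n_cooccurrent > len(singles):
        raise ValueError("infeasible plan: not enough singleton patients")
    singleton_sets: dict[str, list[str]] = {r: [] for r in region_names}
    next_single = 0
    for _ in range(n_cooccurrent):
        top2 = sorted(
            (r for r in region_names if capacities[r] >= 1),
            key=lambda r: -capacities[r],
        )[:2]
        if len(top2) < 2:
            raise ValueError(
                "infeasible plan: cannot realize the planted co-occurrence "
                "count with the planted per-region mutation counts"
            )
        patient = singles[next_single]
        next_single += 1
        for r in top2:
            singleton_sets[r].append(patient)
            capacities[r] -= 1
    for r in region_names:
        for _ in range(capacities[r]):
            singleton_sets[r].append(singles[next_single])
            next_single += 1

    # build the call matrix
    calls = {
        s.specimen_id: {r: "WT" for r in region_names} for s in specimens
    }
    for d in design:
        r = d["region"]
        spec = regions[r]
        primary = f"{spec['chrom']}:{spec['primary']['pos']}" \
                  f"{spec['primary']['ref']}>{spec['primary']['alt']}"
        secondary = f"{spec['chrom']}:{spec['secondary']['pos']}" \
                    f"{spec['secondary']['ref']}>{spec['secondary']['alt']}"
        # NS cells on singleton specimens not carrying this region's mutations
        protected = set(singleton_sets[r])
        ns_candidates = [p for p in singles if p not in protected]
        if d["n_ns"] > len(ns_candidates):
            raise ValueError(
                f"infeasible plan: region {r} needs {d['n_ns']} non-sequenced "
                f"cells but only {len(ns_candidates)} unmutated singleton "
                "specimens remain"
            )
        order = rng.permutation(len(ns_candidates))
        for idx in order[: d["n_ns"]]:
            calls[f"{ns_candidates[idx]}-S1"][r] = "NS"
        # discordant multifocal pairs: S1 mutant, S2 WT
        for p in d["discordant_patients"]:
            calls[f"{p}-S1"][r] = primary
        # singleton mutations; one secondary (hotspot-shifted) allele per
        # region when at least two singleton mutations are planted
        for k, p in enumerate(singleton_sets[r]):
            allele = secondary if (k == len(singleton_sets[r]) - 1
                                   and len(singleton_sets[r]) >= 2) else primary
            calls[f"{p}-S1"][r] = allele

    # peritumoral specimens from mutated patients
    mutated_patients = sorted(
        {p for d in design for p in d["discordant_patients"]}
        | {p for r in region_names for p in singleton_sets[r]}
    )
    if n_peritumoral > len(mutated_patients):
        raise ValueError("infeasible plan: fewer mutated patients than "
                         "requested peritumoral specimens")
    peri_idx = rng.choice(len(mutated_patients), size=n_peritumoral,
                          replace=False)
    peri_patients = sorted(mutated_patients[i] for i in peri_idx)
    for p in peri_patients:
        specimens.append(Specimen(f"{p}-PT1", p, "PT1", "peritumoral"))
        calls[f"{p}-PT1"] = {r: "WT" for r in region_names}
    violation_cell = None
    if peritumoral_violation:
        p = peri_patients[0]
        mutated_in = next(
            r for r in region_names
            if calls[f"{p}-S1"][r] not in ("WT", "NS")
        )
        calls[f"{p}-PT1"][mutated_in] = calls[f"{p}-S1"][mutated_in]
        violation_cell = {"specimen": f"{p}-PT1", "region": mutated_in}

    import pandas as pd

    region_ivs = {
        name: GenomicInterval(spec["chrom"], spec["start"], spec["end"])
        for name, spec in regions.items()
    }
    frame = pd.DataFrame(
        [[calls[s.specimen_id][r] for r in region_names] for s in specimens],
        index=pd.Index([s.specimen_id for s in specimens]),
        columns=region_names,
    )
    table = GenotypeTable(specimens, region_ivs, frame)

    # realized statistics, by direct counting over the design
    realized_callability = {
        d["region"]: d["n_callable"] / n_tumor for d in design
    }
    realized_frequency = {
        d["region"]: (d["n_mut"] / d["n_callable"]) if d["n_callable"] else None
        for d in design
    }
    realized_concordance = {
        d["region"]: (d["m_multifocal"] - d["n_discordant"]) / d["m_multifocal"]
        if d["m_multifocal"] else None
        for d in design
    }
    cooccurrent_patients = sorted(
        p
        for p in set(singles)
        if sum(p in singleton_sets[r] for r in region_names) >= 2
    )
    patients_callable = {
        s.patient
        for s in specimens
        if s.compartment == "tumor"
        and any(calls[s.specimen_id][r] != "NS" for r in region_names)
    }
    gt = {
        "n_patients": n_patients,
        "n_tumor_specimens": n_tumor,
        "multifocal_patients": multifocal,
        "planted": {
            "frequencies": frequencies,
            "callability": callability,
            "concordance": concordance,
        },
        "realized": {
            "callability": realized_callability,
            "frequency": realized_frequency,
            "concordance": realized_concordance,
            "burden": len(mutated_patients) / len(patients_callable),
            "n_patients_mutated": len(mutated_patients),
            "n_patients_callable": len(patients_callable),
        },
        "cooccurrent_patients": cooccurrent_patients,
        "peritumoral_patients": peri_patients,
        "peritumoral_violation": violation_cell,
        "region_snvs": {
            name: {"primary": spec["primary"], "secondary": spec["secondary"],
                   "chrom": spec["chrom"]}
            for name, spec in regions.items()
        },
    }
    return table, gt


# ---------------------------------------------------------------------------
# ground-truth serialization and the paper-like preset
# ---------------------------------------------------------------------------

def save_ground_truth(gt: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(gt, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_ground_truth(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def simulate_paper_like(out_dir: str | Path, seed: int = 1) -> dict:
    """Generate the full paper-like fixture set into ``out_dir``.

    Numbers mirror the study design: accessibility cohorts of 9 vs 12
    samples with 20 + 30 group-specific and 50 shared planted regions; a
    39-patient SNV cohort with a 3-patient recurrent variant; a PFM
    library with one planted site-creating and one site-destroying motif;
    and a 54-patient validation cohort with 11 multifocal and 9
    peritumoral specimens. Returns the combined ground truth.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    genome = generate_genome(seed=seed)
    write_fasta(genome, out_dir / "genome.fa")

    cohort_a, cohort_b, cohort_gt = generate_cohorts(genome, seed=seed + 1)
    peaks_dir = out_dir / "peaks"
    peaks_dir.mkdir(exist_ok=True)
    with open(peaks_dir / "sample_sheet.tsv", "w") as fh:
        for cohort in (cohort_a, cohort_b):
            for sid, ivs in cohort.samples:
                write_bed(list(ivs), peaks_dir / f"{sid}.bed")
                fh.write(f"{sid}\t{cohort.group}\n")

    tracks, genes, interactions, annot_gt = generate_annotations(
        cohort_gt, seed=seed + 2, genome=genome
    )
    annot_dir = out_dir / "annotations"
    annot_dir.mkdir(exist_ok=True)
    write_bed(list(tracks.promoter), annot_dir / "promoter.bed")
    write_bed(list(tracks.insulator), annot_dir / "insulator.bed")
    write_bed(list(tracks.enhancer), annot_dir / "enhancer.bed")
    write_bed(
        [g.region for g in genes],
        annot_dir / "genes.bed",
        names=[g.symbol for g in genes],
    )
    with open(annot_dir / "curated_genes.tsv", "w") as fh:
        for g in genes:
            if g.curated:
                fh.write(f"{g.symbol}\n")
    with open(annot_dir / "interactions.tsv", "w") as fh:
        fh.write("element_id\tgene\tconfidence\n")
        for link in interactions:
            fh.write(f"{link['element_id']}\t{link['gene']}\t"
                     f"{link['confidence']}\n")

    snvs, known_snps, snv_gt = generate_snvs(genome, annot_gt, seed=seed + 3)
    vcf_dir = out_dir / "vcfs"
    vcf_dir.mkdir(exist_ok=True)
    contigs = {c: genome.length(c) for c in genome.chroms}
    for patient in snv_gt["patients"]:
        write_vcf(
            [s for s in snvs if s.patient == patient],
            vcf_dir / f"{patient}.vcf",
            contig_lengths=contigs,
        )
    write_known_snps(known_snps, out_dir / "known_snps.tsv")

    pfms, pwm_gt = generate_pwms(snv_gt, genome, seed=seed + 4)
    write_jaspar(pfms, out_dir / "motifs.jaspar")

    # validation regions: one sub-region per planted SNV position
    val_regions: dict[str, dict] = {}
    suffix = "ABCDE"
    for elem in snv_gt["planted_elements"]:
        for i, pos_rec in enumerate(elem["positions"]):
            name = (
                f"{elem['element_id']}{suffix[i]}"
                if len(elem["positions"]) > 1
                else elem["element_id"]
            )
            centre = pos_rec["pos"]
            start, end = centre - 61, centre + 60  # 1-based pos inside
            sec_pos = centre + 3
            val_regions[name] = {
                "chrom": pos_rec["chrom"],
                "start": start,
                "end": end,
                "primary": {"pos": centre, "ref": pos_rec["ref"],
                            "alt": pos_rec["alt"]},
                "secondary": {
                    "pos": sec_pos,
                    "ref": genome.base_at(pos_rec["chrom"], sec_pos),
                    "alt": _random_alt(
                        genome.base_at(pos_rec["chrom"], sec_pos),
                        np.random.default_rng(seed + 5),
                    ),
                },
            }
    table, geno_gt = generate_genotype_table(
        regions=val_regions, seed=seed + 5
    )
    table.to_tsv(out_dir / "genotypes.tsv")

    gt = {
        "seed": seed,
        "genome": {"n_chroms": len(genome.chroms),
                   "lengths": {c: genome.length(c) for c in genome.chroms}},
        "cohorts": cohort_gt,
        "annotations": annot_gt,
        "snvs": snv_gt,
        "pwms": pwm_gt,
        "genotypes": geno_gt,
    }
    save_ground_truth(gt, out_dir / "ground_truth.json")
    return gt
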