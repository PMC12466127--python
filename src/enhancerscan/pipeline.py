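"""End-to-end orchestration: specificity -> annotation -> overlap ->
TF-affinity scanning -> cohort validation, with a combined JSON report.

The report is a deterministic function of (config, inputs): no
timestamps, sorted keys. Stage outputs are written under the output
directory together with a MANIFEST recording completion state.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

from .annotation import RegulatoryElement, classify_elements, enrichment_report
from .cohort import (
    GenotypeTable,
    co_occurrence,
    filter_known_snps,
    multifocal_concordance,
    mutation_frequencies,
    peritumoral_exclusivity,
    region_callability,
)
from .config import PipelineConfig
from .genome import read_fasta
from .intervals import read_bed
from .motifs import build_pwm, read_jaspar, scan_variant, write_shift_table
from .overlap import (
    GeneAnnotation,
    map_snvs_to_elements,
    prioritize_candidates,
    write_candidate_table,
)
from .specificity import (
    call_specific_regions,
    read_sample_sheet,
    write_specificity_calls,
)
from .variants import read_known_snps, read_vcf_dir

__all__ = ["run_all", "manifest_from_fixture_dir"]

logger = logging.getLogger(__name__)

MANIFEST_KEYS = (
    "sample_sheet", "promoter_bed", "insulator_bed", "enhancer_bed",
    "genes_bed", "curated_genes", "interactions", "genome_fasta",
    "vcf_dir", "known_snps", "motifs", "genotype_table",
)


def manifest_from_fixture_dir(fixture_dir: str | Path) -> dict[str, str]:
    """Input manifest for the directory layout written by
    :func:`enhancerscan.simulate.simulate_paper_like`."""
    d = Path(fixture_dir)
    return {
        "sample_sheet": str(d / "peaks" / "sample_sheet.tsv"),
        "promoter_bed": str(d / "annotations" / "promoter.bed"),
        "insulator_bed": str(d / "annotations" / "insulator.bed"),
        "enhancer_bed": str(d / "annotations" / "enhancer.bed"),
        "genes_bed": str(d / "annotations" / "genes.bed"),
        "curated_genes": str(d / "annotations" / "curated_genes.tsv"),
        "interactions": str(d / "annotations" / "interactions.tsv"),
        "genome_fasta": str(d / "genome.fa"),
        "vcf_dir": str(d / "vcfs"),
        "known_snps": str(d / "known_snps.tsv"),
        "motifs": str(d / "motifs.jaspar"),
        "genotype_table": str(d / "genotypes.tsv"),
    }


def _read_genes(genes_bed: str, curated_path: str) -> list[GeneAnnotation]:
    curated = set()
    with open(curated_path) as fh:
        for line in fh:
            sym = line.strip().split("\t")[0]
            if sym and not sym.startswith("#"):
                curated.add(sym)
    genes = []
    with open(genes_bed) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 4:
                continue
            from .intervals import GenomicInterval

            genes.append(
                GeneAnnotation(
                    fields[3],
                    GenomicInterval(fields[0], int(fields[1]), int(fields[2])),
                    curated=fields[3] in curated,
                )
            )
    return genes


def _read_interactions(path: str) -> list[dict]:
    links = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            links.append(row)
    return links


def run_all(
    config: PipelineConfig, manifest: dict[str, str], out_dir: str | Path
) -> dict:
    """Run every stage in order and write the combined report.

    The first failing stage aborts the run; outputs of completed stages
    are retained and MANIFEST.json records the completion state.
    """
    config.validate()
    missing = [k for k in MANIFEST_KEYS if k not in manifest]
    if missing:
        raise ValueError(f"manifest missing keys: {missing}")
    for key in MANIFEST_KEYS:
        if not Path(manifest[key]).exists():
            raise FileNotFoundError(f"manifest path for {key!r} does not "
                                    f"exist: {manifest[key]}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": config.to_dict(), "stages": {}}
    state = {k: "pending" for k in
             ("specificity", "annotation", "overlap", "tfscan", "cohort")}

    def _checkpoint() -> None:
        with open(out_dir / "MANIFEST.json", "w") as fh:
            json.dump(state, fh, indent=2, sort_keys=True)

    try:
        # stage 1: group-specific accessible regions
        logger.info("[specificity] calling group-specific regions")
        cohort_a, cohort_b = read_sample_sheet(manifest["sample_sheet"])
        calls = call_specific_regions(
            cohort_a, cohort_b, f_min=config.f_min, f_max=config.f_max,
            min_overlap_frac=config.min_overlap_frac,
        )
        counts = write_specificity_calls(calls, out_dir / "specificity")
        report["stages"]["specificity"] = {
            "group_A": cohort_a.group,
            "group_B": cohort_b.group,
            "n_samples_A": cohort_a.n_samples,
            "n_samples_B": cohort_b.n_samples,
            **counts,
        }
        state["specificity"] = "done"
        _checkpoint()

        # stage 2: element classification and enrichment
        logger.info("[annotation] classifying elements")
        from .annotation import AnnotationTracks

        tracks = AnnotationTracks.from_bed_files(
            manifest["promoter_bed"], manifest["insulator_bed"],
            manifest["enhancer_bed"],
        )
        calls_a = [c.region for c in calls if c.status == "A_specific"]
        calls_b = [c.region for c in calls if c.status == "B_specific"]
        classified_a = classify_elements(calls_a, tracks,
                                         priority=config.class_priority)
        classified_b = classify_elements(calls_b, tracks,
                                         priority=config.class_priority)
        table = enrichment_report(
            classified_a, classified_b,
            group_a=cohort_a.group, group_b=cohort_b.group,
            alpha_sig=config.alpha_sig, alpha_ns=config.alpha_ns,
        )
        table.to_tsv(out_dir / "enrichment.tsv")
        report["stages"]["annotation"] = table.to_dict()
        state["annotation"] = "done"
        _checkpoint()

        # stage 3: SNV-enhancer overlap and candidate prioritization
        logger.info("[overlap] mapping SNVs to enhancer elements")
        genome = read_fasta(manifest["genome_fasta"])
        elements = _elements_from_classified(classified_a, group="A")
        ee_elements = [e for e in elements if e.element_class == "EE"]
        snvs = read_vcf_dir(manifest["vcf_dir"])
        known = read_known_snps(manifest["known_snps"])
        somatic, flagged = filter_known_snps(snvs, known)
        profiles, spillover = map_snvs_to_elements(
            somatic, ee_elements, genome=genome,
            hotspot_gap=config.hotspot_gap,
        )
        genes = _read_genes(manifest["genes_bed"], manifest["curated_genes"])
        interactions = _read_interactions(manifest["interactions"])
        candidates = prioritize_candidates(
            profiles, genes, interactions, top_n=config.top_n,
            neighborhood_bp=config.neighborhood_bp,
        )
        write_candidate_table(candidates, out_dir / "candidates.tsv")
        report["stages"]["overlap"] = {
            "n_snvs_input": len(snvs),
            "n_known_snps_flagged": len(flagged),
            "n_somatic": len(somatic),
            "n_mutated_elements": len(profiles),
            "n_spillover": len(spillover),
            "candidates": [
                {
                    "rank": c.rank,
                    "element_id": c.profile.element.element_id,
                    "n_patients": c.profile.n_patients,
                    "n_snvs": c.profile.n_snvs,
                    "n_hotspots": len(c.profile.hotspots),
                    "nearby_curated_genes": sorted(
                        g.symbol for g in c.nearby_genes
                    ),
                    "high_confidence_interaction":
                        c.has_high_confidence_interaction,
                }
                for c in candidates
            ],
        }
        state["overlap"] = "done"
        _checkpoint()

        # stage 4: TF binding-affinity shifts
        logger.info("[tfscan] scanning variants against the PWM library")
        pfms = read_jaspar(manifest["motifs"])
        pwms = [
            build_pwm(p, pseudocount=config.pseudocount,
                      background=config.background)
            for p in pfms
        ]
        tfscan_dir = out_dir / "tfscan"
        tfscan_dir.mkdir(exist_ok=True)
        scan_results = []
        seen = set()
        for cand in candidates:
            for snv in cand.profile.snvs:
                key = (snv.chrom, snv.pos, snv.ref, snv.alt)
                if key in seen:
                    continue
                seen.add(key)
                full, top = scan_variant(
                    genome, pwms, snv, flank=config.flank,
                    site_threshold=config.site_threshold,
                    delta_min=config.delta_min, top_k=config.top_k,
                )
                tag = f"{snv.chrom}_{snv.pos}_{snv.ref}_{snv.alt}"
                write_shift_table(full, tfscan_dir / f"{tag}.tsv")
                scan_results.append(
                    {
                        "snv": str(snv),
                        "element_id": cand.profile.element.element_id,
                        "top": [
                            {
                                "tf": s.tf_name,
                                "wt_rel": round(s.wt_rel, 6),
                                "mut_rel": round(s.mut_rel, 6),
                                "delta": round(s.delta, 6),
                                "category": s.category,
                            }
                            for s in top
                        ],
                    }
                )
        report["stages"]["tfscan"] = {
            "n_motifs": len(pwms),
            "n_variants_scanned": len(scan_results),
            "scans": scan_results,
        }
        state["tfscan"] = "done"
        _checkpoint()

        # stage 5: validation-cohort summary
        logger.info("[cohort] summarizing the validation cohort")
        table5 = GenotypeTable.from_tsv(manifest["genotype_table"])
        callability = region_callability(
            table5, threshold=config.callability_threshold
        )
        freqs = mutation_frequencies(table5)
        cooc = co_occurrence(table5)
        muts = table5.mutations()
        somatic_m, flagged_m = filter_known_snps(muts, known)
        concordance = multifocal_concordance(
            table5, threshold=config.concordance_threshold
        )
        peri = peritumoral_exclusivity(table5)
        report["stages"]["cohort"] = {
            "callability": callability,
            "frequencies": freqs,
            "co_occurrence": {
                "patients": cooc["patients"],
                "n_patients": len(cooc["patients"]),
            },
            "known_snp_filter": {
                "n_mutations": len(muts),
                "n_flagged": len(flagged_m),
                "n_somatic": len(somatic_m),
            },
            "concordance": concordance,
            "peritumoral": peri,
        }
        state["cohort"] = "done"
        _checkpoint()
    finally:
        _checkpoint()

    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report


def _elements_from_classified(classified, group: str) -> list[RegulatoryElement]:
    """Assign stable element IDs (per class, genomic order) to classified
    regions: ``<class>-<group>-<n>``."""
    counters: dict[str, int] = {}
    elements = []
    for region, cls_name in classified:
        counters[cls_name] = counters.get(cls_name, 0) + 1
        elements.append(
            RegulatoryElement(
                region, cls_name,
                f"{cls_name}-{group}-{counters[cls_name]:03d}", group=group,
            )
        )
    return elements
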