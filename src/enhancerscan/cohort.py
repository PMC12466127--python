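"""Targeted-sequencing validation-cohort summary statistics.

The central object is a :class:`GenotypeTable`: tissue specimens (rows,
with patient / section / tumor-vs-peritumoral metadata) by target
regulatory regions (columns), each cell holding WT, a mutant allele
``chrom:posREF>ALT``, or NS (non-sequenced). Summary operations cover
per-region callability and mutation frequency, patient-level mutation
burden, co-occurrence across regions, known-SNP filtering, concordance
between tumor sections of multifocal patients, and tumor-exclusivity
relative to peritumoral tissue. Non-sequenced cells are excluded from
every denominator.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .intervals import GenomicInterval, vcf_pos_in_interval
from .variants import KnownSNPSet, SNVRecord

__all__ = [
    "Specimen",
    "GenotypeTable",
    "region_callability",
    "mutation_frequencies",
    "co_occurrence",
    "filter_known_snps",
    "multifocal_concordance",
    "peritumoral_exclusivity",
]

DEFAULT_CALLABILITY_THRESHOLD = 0.85
DEFAULT_CONCORDANCE_THRESHOLD = 0.75

_MUT_RE = re.compile(r"^([^:]+):(\d+)([ACGT])>([ACGT])$")


@dataclass(frozen=True)
class Specimen:
    specimen_id: str
    patient: str
    section: str
    compartment: str  # tumor | peritumoral

    def __post_init__(self) -> None:
        if self.compartment not in ("tumor", "peritumoral"):
            raise ValueError(f"invalid compartment {self.compartment!r}")


def parse_call(cell: str) -> SNVRecord | str:
    """Parse a genotype cell: 'WT', 'NS', or 'chrom:posREF>ALT'."""
    if cell in ("WT", "NS"):
        return cell
    m = _MUT_RE.match(cell)
    if not m:
        raise ValueError(f"malformed genotype cell {cell!r}")
    return SNVRecord(m.group(1), int(m.group(2)), m.group(3), m.group(4))


@dataclass
class GenotypeTable:
    """Specimens x target regions genotype matrix.

    ``regions`` maps region name to its genomic interval; every mutant
    cell's position must fall inside its column's region.
    """

    specimens: list[Specimen]
    regions: dict[str, GenomicInterval]
    calls: pd.DataFrame = field(repr=False)  # index specimen_id, columns regions

    def __post_init__(self) -> None:
        if not self.specimens:
            raise ValueError("genotype table has no specimens")
        expected = [s.specimen_id for s in self.specimens]
        if list(self.calls.index) != expected:
            raise ValueError("calls index does not match specimen list")
        if list(self.calls.columns) != list(self.regions):
            raise ValueError("calls columns do not match region list")
        for region_name, iv in self.regions.items():
            for specimen_id, cell in self.calls[region_name].items():
                call = parse_call(cell)
                if isinstance(call, SNVRecord):
                    if call.chrom != iv.chrom or not vcf_pos_in_interval(call.pos, iv):
                        raise ValueError(
                            f"mutation {cell} in specimen {specimen_id} lies "
                            f"outside region {region_name} ({iv})"
                        )

    @property
    def region_names(self) -> list[str]:
        return list(self.regions)

    def tumor_specimens(self) -> list[Specimen]:
        return [s for s in self.specimens if s.compartment == "tumor"]

    def peritumoral_specimens(self) -> list[Specimen]:
        return [s for s in self.specimens if s.compartment == "peritumoral"]

    def cell(self, specimen_id: str, region: str) -> str:
        return self.calls.at[specimen_id, region]

    def mutations(self, tumor_only: bool = True) -> list[SNVRecord]:
        """All distinct mutant alleles observed in the table."""
        specimens = self.tumor_specimens() if tumor_only else self.specimens
        seen: dict[tuple, SNVRecord] = {}
        for s in specimens:
            for region in self.region_names:
                call = parse_call(self.cell(s.specimen_id, region))
                if isinstance(call, SNVRecord):
                    seen[(call.chrom, call.pos, call.ref, call.alt)] = call
        return [seen[k] for k in sorted(seen)]

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenotypeTable":
        """Read the TSV layout: specimen_id, patient, section, compartment,
        then one column per region named ``name@chrom:start-end``."""
        df = pd.read_csv(path, sep="\t", dtype=str)
        meta_cols = ["specimen_id", "patient", "section", "compartment"]
        regions: dict[str, GenomicInterval] = {}
        rename = {}
        for col in df.columns:
            if col in meta_cols:
                continue
            name, _, coords = col.partition("@")
            m = re.match(r"^([^:]+):(\d+)-(\d+)$", coords)
            if not m:
                raise ValueError(f"malformed region column header {col!r}")
            regions[name] = GenomicInterval(m.group(1), int(m.group(2)), int(m.group(3)))
            rename[col] = name
        df = df.rename(columns=rename)
        specimens = [
            Specimen(r.specimen_id, r.patient, r.section, r.compartment)
            for r in df.itertuples()
        ]
        calls = df.set_index(pd.Index([s.specimen_id for s in specimens]))[
            list(regions)
        ]
        return cls(specimens, regions, calls)

    def to_tsv(self, path: str | Path) -> None:
        header = ["specimen_id", "patient", "section", "compartment"] + [
            f"{name}@{iv.chrom}:{iv.start}-{iv.end}"
            for name, iv in self.regions.items()
        ]
        with open(path, "w") as fh:
            fh.write("\t".join(header) + "\n")
            for s in self.specimens:
                row = [s.specimen_id, s.patient, s.section, s.compartment] + [
                    self.cell(s.specimen_id, r) for r in self.region_names
                ]
                fh.write("\t".join(row) + "\n")


def region_callability(
    table: GenotypeTable, threshold: float = DEFAULT_CALLABILITY_THRESHOLD
) -> dict:
    """Per-region fraction of tumor specimens with a sequenced (non-NS)
    call, plus the count of regions exceeding ``threshold``."""
    tumor = table.tumor_specimens()
    if not tumor:
        raise ValueError("genotype table contains no tumor specimens")
    fractions = {}
    for region in table.region_names:
        callable_n = sum(
            1 for s in tumor if table.cell(s.specimen_id, region) != "NS"
        )
        fractions[region] = callable_n / len(tumor)
    return {
        "fractions": fractions,
        "threshold": threshold,
        "n_above_threshold": sum(1 for f in fractions.values() if f > threshold),
    }


def mutation_frequencies(table: GenotypeTable) -> dict:
    """Per-region mutation frequency and patient-level mutation burden.

    Frequency is MUT / (MUT + WT) over tumor specimens (NS excluded from
    the denominator); a region with zero callable cells reports None.
    Burden is the fraction of patients (any tumor section) with >= 1
    mutation, among patients with >= 1 callable region.
    """
    tumor = table.tumor_specimens()
    if not tumor:
        raise ValueError("genotype table contains no tumor specimens")
    freqs: dict[str, float | None] = {}
    for region in table.region_names:
        n_mut = n_wt = 0
        for s in tumor:
            call = table.cell(s.specimen_id, region)
            if call == "WT":
                n_wt += 1
            elif call != "NS":
                n_mut += 1
        freqs[region] = None if n_mut + n_wt == 0 else n_mut / (n_mut + n_wt)
    patients_callable = set()
    patients_mutated = set()
    for s in tumor:
        for region in table.region_names:
            call = table.cell(s.specimen_id, region)
            if call != "NS":
                patients_callable.add(s.patient)
            if call not in ("NS", "WT"):
                patients_mutated.add(s.patient)
    burden = (
        len(patients_mutated) / len(patients_callable) if patients_callable else None
    )
    return {
        "frequencies": freqs,
        "n_patients_mutated": len(patients_mutated),
        "n_patients_callable": len(patients_callable),
        "burden": burden,
    }


def co_occurrence(table: GenotypeTable) -> dict:
    """Patients with mutations in >= 2 distinct regions, plus the
    symmetric pairwise region co-mutation count matrix."""
    tumor = table.tumor_specimens()
    mutated_regions: dict[str, set[str]] = {}
    for s in tumor:
        for region in table.region_names:
            call = table.cell(s.specimen_id, region)
            if call not in ("NS", "WT"):
                mutated_regions.setdefault(s.patient, set()).add(region)
    co_patients = {
        p: sorted(rs) for p, rs in mutated_regions.items() if len(rs) >= 2
    }
    names = table.region_names
    matrix = pd.DataFrame(0, index=names, columns=names)
    for regions in mutated_regions.values():
        rs = sorted(regions)
        for i, r1 in enumerate(rs):
            for r2 in rs[i + 1 :]:
                matrix.at[r1, r2] += 1
                matrix.at[r2, r1] += 1
    return {"patients": co_patients, "matrix": matrix}


def filter_known_snps(
    mutations: Iterable[SNVRecord], snps: KnownSNPSet
) -> tuple[list[SNVRecord], list[SNVRecord]]:
    """Partition mutations into (somatic, flagged-as-known-SNP).

    A mutation is flagged only on an exact allele-aware (chrom, pos, ref,
    alt) match; a different alternate allele at a known SNP position stays
    somatic. The partition conserves the input count.
    """
    somatic, flagged = [], []
    for mut in mutations:
        (flagged if snps.contains(mut) else somatic).append(mut)
    return somatic, flagged


def multifocal_concordance(
    table: GenotypeTable, threshold: float = DEFAULT_CONCORDANCE_THRESHOLD
) -> dict:
    """Per-region agreement between tumor sections of multifocal patients.

    For each region, among patients with >= 2 callable tumor sections,
    concordance is the fraction of such patients whose sections all carry
    an identical call (all WT, or all the same mutant allele). Regions
    strictly exceeding ``threshold`` are flagged. Returns an empty result
    with a warning flag when no patient is multifocal.
    """
    tumor = table.tumor_specimens()
    by_patient: dict[str, list[Specimen]] = {}
    for s in tumor:
        by_patient.setdefault(s.patient, []).append(s)
    multifocal = {p: ss for p, ss in by_patient.items() if len(ss) >= 2}
    if not multifocal:
        return {"fractions": {}, "threshold": threshold,
                "n_above_threshold": 0, "warning": "no multifocal patients"}
    fractions: dict[str, float | None] = {}
    for region in table.region_names:
        n_eval = n_concordant = 0
        for sections in multifocal.values():
            calls = [
                table.cell(s.specimen_id, region)
                for s in sections
                if table.cell(s.specimen_id, region) != "NS"
            ]
            if len(calls) >= 2:
                n_eval += 1
                if len(set(calls)) == 1:
                    n_concordant += 1
        fractions[region] = None if n_eval == 0 else n_concordant / n_eval
    return {
        "fractions": fractions,
        "threshold": threshold,
        "n_above_threshold": sum(
            1 for f in fractions.values() if f is not None and f > threshold
        ),
    }


def peritumoral_exclusivity(table: GenotypeTable) -> dict:
    """For each patient with >= 1 tumor mutation and >= 1 peritumoral
    specimen, report any peritumoral mutant call; the summary flag
    ``tumor_exclusive`` is true iff no peritumoral cell is mutant."""
    peri = table.peritumoral_specimens()
    if not peri:
        raise ValueError("genotype table contains no peritumoral specimens")
    mutated_patients = set()
    for s in table.tumor_specimens():
        for region in table.region_names:
            if table.cell(s.specimen_id, region) not in ("NS", "WT"):
                mutated_patients.add(s.patient)
    per_patient: dict[str, list[str]] = {}
    for s in peri:
        if s.patient not in mutated_patients:
            continue
        offending = [
            f"{s.specimen_id}:{region}:{table.cell(s.specimen_id, region)}"
            for region in table.region_names
            if table.cell(s.specimen_id, region) not in ("NS", "WT")
        ]
        per_patient.setdefault(s.patient, []).extend(offending)
    return {
        "patients_evaluated": sorted(per_patient),
        "violations": {p: v for p, v in per_patient.items() if v},
        "tumor_exclusive": all(not v for v in per_patient.values()),
    }
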