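"""Somatic SNV records, minimal VCF I/O, and known-SNP sets."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pysam

from .genome import Genome

__all__ = [
    "SNVRecord",
    "KnownSNPSet",
    "read_vcf_snvs",
    "read_vcf_dir",
    "write_vcf",
    "read_known_snps",
    "write_known_snps",
]

logger = logging.getLogger(__name__)

_BASES = set("ACGT")


@dataclass(frozen=True, order=True)
class SNVRecord:
    """A single-nucleotide variant: VCF-style 1-based position, single-base
    ref/alt, carrying patient of origin and a somatic/germline flag."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    patient: str = field(default="", compare=True)
    origin: str = field(default="unknown", compare=False)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"VCF positions are 1-based; got {self.pos}")
        if self.ref not in _BASES or self.alt not in _BASES:
            raise ValueError(
                f"ref/alt must be single bases in ACGT; got {self.ref!r}>{self.alt!r}"
            )
        if self.ref == self.alt:
            raise ValueError(f"ref and alt are identical ({self.ref}) at "
                             f"{self.chrom}:{self.pos}")
        if self.origin not in ("somatic", "germline", "unknown"):
            raise ValueError(f"invalid origin flag {self.origin!r}")

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}{self.ref}>{self.alt}"


class KnownSNPSet:
    """Allele-aware set of known germline variants (chrom, pos, ref, alt)."""

    def __init__(self, snps: Iterable[tuple[str, int, str, str]] = ()):
        self._snps = set()
        for chrom, pos, ref, alt in snps:
            if pos < 1 or ref not in _BASES or alt not in _BASES:
                raise ValueError(f"invalid SNP entry {chrom}:{pos}{ref}>{alt}")
            self._snps.add((chrom, pos, ref, alt))

    def __len__(self) -> int:
        return len(self._snps)

    def __iter__(self):
        return iter(sorted(self._snps))

    def contains(self, snv: SNVRecord) -> bool:
        return (snv.chrom, snv.pos, snv.ref, snv.alt) in self._snps


def read_vcf_snvs(path: str | Path, patient: str | None = None) -> list[SNVRecord]:
    """Read SNV records from one VCF; non-SNV records are skipped with a
    logged count. The patient ID defaults to the file stem."""
    patient = patient if patient is not None else Path(path).stem
    out: list[SNVRecord] = []
    skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            alts = rec.alts or ()
            for alt in alts:
                if len(rec.ref) == 1 and len(alt) == 1 and rec.ref in _BASES \
                        and alt in _BASES:
                    out.append(
                        SNVRecord(rec.chrom, rec.pos, rec.ref, alt, patient=patient)
                    )
                else:
                    skipped += 1
    if skipped:
        logger.warning("%s: skipped %d non-SNV allele(s)", path, skipped)
    return out


def read_vcf_dir(vcf_dir: str | Path) -> list[SNVRecord]:
    """Read all ``*.vcf`` files in a directory, one patient per file."""
    paths = sorted(Path(vcf_dir).glob("*.vcf"))
    if not paths:
        raise FileNotFoundError(f"no .vcf files found in {vcf_dir}")
    snvs: list[SNVRecord] = []
    for p in paths:
        snvs.extend(read_vcf_snvs(p))
    return snvs


def write_vcf(
    snvs: Sequence[SNVRecord],
    path: str | Path,
    contig_lengths: dict[str, int] | None = None,
) -> None:
    """Write a minimal VCF 4.2 file (CHROM POS ID REF ALT QUAL FILTER INFO)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if contig_lengths:
            for chrom, length in contig_lengths.items():
                fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for snv in sorted(snvs):
            fh.write(
                f"{snv.chrom}\t{snv.pos}\t.\t{snv.ref}\t{snv.alt}\t.\tPASS\t.\n"
            )


def read_known_snps(path: str | Path) -> KnownSNPSet:
    """Read a known-SNP catalog from a 4-column TSV (chrom, pos, ref, alt)
    or a VCF file."""
    path = Path(path)
    if path.suffix == ".vcf":
        recs = read_vcf_snvs(path, patient="")
        return KnownSNPSet((r.chrom, r.pos, r.ref, r.alt) for r in recs)
    entries = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            chrom, pos, ref, alt = line.split("\t")[:4]
            entries.append((chrom, int(pos), ref, alt))
    return KnownSNPSet(entries)


def write_known_snps(snps: KnownSNPSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tpos\tref\talt\n")
        for chrom, pos, ref, alt in snps:
            fh.write(f"{chrom}\t{pos}\t{ref}\t{alt}\n")


def check_ref_consistency(snvs: Iterable[SNVRecord], genome: Genome) -> None:
    """Raise if any SNV's ref allele disagrees with the genome base."""
    for snv in snvs:
        observed = genome.base_at(snv.chrom, snv.pos)
        if observed != snv.ref:
            raise ValueError(
                f"ref mismatch for {snv} (patient {snv.patient or '?'}): "
                f"genome has {observed!r}"
            )
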