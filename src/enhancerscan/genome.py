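"""Reference sequence container and windowed sequence extraction."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = ["Genome", "read_fasta", "write_fasta", "extract_window", "revcomp"]

_VALID = set("ACGTN")


class Genome:
    """In-memory reference genome: chromosome name -> uppercase DNA.

    Sequences are restricted to the alphabet {A, C, G, T, N}; the ambiguity
    code N is permitted (FFPE-derived references contain Ns) and is handled
    downstream by the motif scanner.
    """

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs: dict[str, str] = {}
        for name, seq in sequences.items():
            if not name:
                raise ValueError("chromosome name must be non-empty")
            seq = seq.upper()
            bad = set(seq) - _VALID
            if bad:
                raise ValueError(
                    f"chromosome {name!r} contains invalid bases {sorted(bad)}"
                )
            self._seqs[name] = seq

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def __getitem__(self, chrom: str) -> str:
        return self._seqs[chrom]

    @property
    def chroms(self) -> list[str]:
        return list(self._seqs)

    def length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def base_at(self, chrom: str, pos: int) -> str:
        """Base at the 1-based position *pos*."""
        self._check(chrom, pos - 1, pos)
        return self._seqs[chrom][pos - 1]

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence of the 0-based half-open span ``[start, end)``."""
        self._check(chrom, start, end)
        return self._seqs[chrom][start:end]

    def _check(self, chrom: str, start: int, end: int) -> None:
        if chrom not in self._seqs:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if start < 0 or end > len(self._seqs[chrom]) or start >= end:
            raise ValueError(
                f"span {chrom}:{start}-{end} outside chromosome of length "
                f"{len(self._seqs[chrom])}"
            )


def read_fasta(path: str | Path) -> Genome:
    """Read a (possibly multi-record, line-wrapped) FASTA file."""
    return Genome({rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")})


def write_fasta(genome: Genome, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in genome.chroms:
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def extract_window(genome: Genome, chrom: str, pos: int, flank: int = 7) -> str:
    """Sequence window of length ``2*flank + 1`` centred on the 1-based
    position *pos*.

    The default flank of 7 yields a 15 bp window with the variant base at
    its centre. The window must lie fully inside the chromosome; no
    padding is applied at the edges.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    start = pos - 1 - flank
    end = pos + flank
    if start < 0 or end > genome.length(chrom):
        raise ValueError(
            f"window [{start}, {end}) around {chrom}:{pos} runs off the "
            f"chromosome edge (length {genome.length(chrom)})"
        )
    return genome.fetch(chrom, start, end)


def revcomp(seq: str) -> str:
    """Reverse complement (N-safe)."""
    return str(Seq(seq).reverse_complement())
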