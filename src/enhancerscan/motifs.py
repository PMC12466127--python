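"""PWM-based wild-type vs mutant TF binding-affinity-shift scanning.

A position frequency matrix (PFM) is converted to a log2 log-odds PWM
with pseudocounts and a background model. For a variant, the wild-type
and mutant sequence windows (default 15 bp, variant at the centre) are
scanned on both strands over every alignment offset whose motif footprint
covers the variant base; the best raw score is min-max normalized to a
*relative score* in [0, 1],

    rel = (S - S_min) / (S_max - S_min),

where S_min/S_max are the least/greatest scores the motif can attain.
The per-TF shift ``delta = mut_rel - wt_rel`` is categorized as a novel
site, a lost site, a gain, a loss, or neutral, and TFs are ranked by the
magnitude of their shift.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .genome import Genome, extract_window, revcomp
from .variants import SNVRecord

__all__ = [
    "PFM",
    "PWM",
    "AffinityShift",
    "read_jaspar",
    "write_jaspar",
    "build_pwm",
    "relative_score",
    "affinity_shift",
    "rank_top_k",
    "scan_variant",
]

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
DEFAULT_PSEUDOCOUNT = 0.25
DEFAULT_BACKGROUND = (0.25, 0.25, 0.25, 0.25)
DEFAULT_SITE_THRESHOLD = 0.80
DEFAULT_DELTA_MIN = 0.05
DEFAULT_FLANK = 7
DEFAULT_TOP_K = 5

CATEGORIES = ("gain", "loss", "novel", "lost_site", "neutral")


@dataclass(frozen=True)
class PFM:
    """Position frequency matrix: per-column base counts for one motif."""

    name: str
    matrix_id: str
    counts: np.ndarray  # shape (4, L), rows A,C,G,T

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2 or counts.shape[0] != 4:
            raise ValueError(f"PFM {self.name}: counts must be 4 x L")
        if counts.shape[1] < 4:
            raise ValueError(f"PFM {self.name}: motif length must be >= 4")
        if (counts < 0).any():
            raise ValueError(f"PFM {self.name}: counts must be non-negative")
        if (counts.sum(axis=0) <= 0).any():
            raise ValueError(f"PFM {self.name}: every column sum must be > 0")

    @property
    def length(self) -> int:
        return self.counts.shape[1]


@dataclass(frozen=True)
class PWM:
    """Log-odds weight matrix with its achievable score range."""

    name: str
    matrix_id: str
    weights: np.ndarray  # shape (4, L)
    s_min: float
    s_max: float

    @property
    def length(self) -> int:
        return self.weights.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.weights.argmax(axis=0))


@dataclass(frozen=True)
class AffinityShift:
    """Per-TF relative-score change between wild-type and mutant windows."""

    tf_name: str
    wt_rel: float
    mut_rel: float
    delta: float
    wt_offset: int
    wt_strand: str
    mut_offset: int
    mut_strand: str
    category: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"invalid category {self.category!r}")


def build_pwm(
    pfm: PFM,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    background: Sequence[float] = DEFAULT_BACKGROUND,
) -> PWM:
    """Convert a PFM to a log2 log-odds PWM.

    ``w[b, j] = log2(((counts[b, j] + pc) / (colsum_j + 4 pc)) / bg[b])``
    with a per-cell pseudocount (default 0.25) and a background base
    distribution (default uniform). Motifs whose score range collapses
    (S_min == S_max, i.e. no column discriminates) are rejected.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    bg = np.asarray(background, dtype=float)
    if bg.shape != (4,) or (bg <= 0).any() or abs(bg.sum() - 1.0) > 1e-9:
        raise ValueError("background must be 4 positive frequencies summing to 1")
    colsums = pfm.counts.sum(axis=0)
    probs = (pfm.counts + pseudocount) / (colsums + 4 * pseudocount)
    weights = np.log2(probs / bg[:, None])
    s_min = float(weights.min(axis=0).sum())
    s_max = float(weights.max(axis=0).sum())
    if not s_min < s_max:
        raise ValueError(
            f"degenerate motif {pfm.name}: S_min == S_max == {s_min:.4g}"
        )
    return PWM(pfm.name, pfm.matrix_id, weights, s_min, s_max)


def _encode(window: str) -> np.ndarray:
    """Map a DNA string to row indices 0-3 (A,C,G,T) or 4 for N."""
    idx = np.empty(len(window), dtype=np.int64)
    n_count = 0
    for i, base in enumerate(window.upper()):
        if base in _BASE_INDEX:
            idx[i] = _BASE_INDEX[base]
        elif base == "N":
            idx[i] = 4
            n_count += 1
        else:
            raise ValueError(f"invalid base {base!r} in window {window!r}")
    if n_count:
        logger.warning("window %s contains %d N base(s); scored as background",
                       window, n_count)
    return idx


def _best_covering_score(
    weights5: np.ndarray, idx: np.ndarray, must_cover: int
) -> tuple[float, int]:
    """Best raw score over offsets whose footprint covers ``must_cover``.

    ``weights5`` has a fifth row of zeros so that N positions contribute
    the background expectation (weight 0). Returns (score, offset).
    """
    length = weights5.shape[1]
    lo = max(0, must_cover - length + 1)
    hi = min(len(idx) - length, must_cover)
    best, best_off = -np.inf, -1
    cols = np.arange(length)
    for off in range(lo, hi + 1):
        score = float(weights5[idx[off : off + length], cols].sum())
        if score > best:
            best, best_off = score, off
    return best, best_off


def relative_score(
    pwm: PWM, window: str, must_cover: int | None = None
) -> tuple[float, int, str]:
    """Min-max-normalized best PWM score over variant-covering alignments.

    Both strands are scanned; on the minus strand the window is
    reverse-complemented and coverage of the variant base is assessed in
    the reverse-complemented coordinates. Returns ``(rel, offset,
    strand)`` where ``offset`` is the footprint start in the forward
    window's coordinates. ``must_cover`` defaults to the centre index.
    """
    length = pwm.length
    if length > len(window):
        raise ValueError(
            f"motif {pwm.name} (L={length}) longer than window "
            f"({len(window)} bp)"
        )
    if must_cover is None:
        must_cover = len(window) // 2
    if not 0 <= must_cover < len(window):
        raise ValueError("must_cover outside window")
    weights5 = np.vstack([pwm.weights, np.zeros((1, length))])
    idx_fwd = _encode(window)
    fwd_score, fwd_off = _best_covering_score(weights5, idx_fwd, must_cover)
    rc = revcomp(window)
    idx_rev = _encode(rc)
    rc_cover = len(window) - 1 - must_cover
    rev_score, rev_off = _best_covering_score(weights5, idx_rev, rc_cover)
    if fwd_score >= rev_score:
        best, offset, strand = fwd_score, fwd_off, "+"
    else:
        # footprint start mapped back to forward-window coordinates
        best, offset, strand = rev_score, len(window) - length - rev_off, "-"
    rel = (best - pwm.s_min) / (pwm.s_max - pwm.s_min)
    return float(min(1.0, max(0.0, rel))), offset, strand


def _categorize(wt_rel: float, mut_rel: float, site_threshold: float,
                delta_min: float) -> str:
    delta = mut_rel - wt_rel
    if wt_rel < site_threshold <= mut_rel:
        return "novel"
    if mut_rel < site_threshold <= wt_rel:
        return "lost_site"
    if delta >= delta_min:
        return "gain"
    if delta <= -delta_min:
        return "loss"
    return "neutral"


def affinity_shift(
    pwms: Sequence[PWM],
    wt_window: str,
    mut_window: str,
    site_threshold: float = DEFAULT_SITE_THRESHOLD,
    delta_min: float = DEFAULT_DELTA_MIN,
) -> list[AffinityShift]:
    """Per-TF relative-score shift between two windows differing only at
    their centre base.

    Categories: *novel* when the mutant allele lifts the best relative
    score across the site threshold, *lost_site* for the reverse, *gain*
    / *loss* for shifts of at least ``delta_min`` that do not cross the
    threshold, else *neutral*. Categories are mutually exclusive and
    exhaustive.
    """
    wt, mut = wt_window.upper(), mut_window.upper()
    if len(wt) != len(mut):
        raise ValueError("wild-type and mutant windows differ in length")
    centre = len(wt) // 2
    diff = [i for i in range(len(wt)) if wt[i] != mut[i]]
    if diff != [centre]:
        raise ValueError(
            "windows must be identical except at the centre base "
            f"(differing positions: {diff}, centre: {centre})"
        )
    shifts = []
    for pwm in pwms:
        wt_rel, wt_off, wt_strand = relative_score(pwm, wt, centre)
        mut_rel, mut_off, mut_strand = relative_score(pwm, mut, centre)
        shifts.append(
            AffinityShift(
                tf_name=pwm.name,
                wt_rel=wt_rel,
                mut_rel=mut_rel,
                delta=mut_rel - wt_rel,
                wt_offset=wt_off,
                wt_strand=wt_strand,
                mut_offset=mut_off,
                mut_strand=mut_strand,
                category=_categorize(wt_rel, mut_rel, site_threshold, delta_min),
            )
        )
    return shifts


def rank_top_k(shifts: Sequence[AffinityShift], k: int = DEFAULT_TOP_K) -> list[AffinityShift]:
    """Top-k shifts by |delta| descending; ties broken by the larger of
    the two relative scores (descending), then TF name (ascending)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ordered = sorted(
        shifts,
        key=lambda s: (-abs(s.delta), -max(s.wt_rel, s.mut_rel), s.tf_name),
    )
    return ordered[:k]


def scan_variant(
    genome: Genome,
    pwms: Sequence[PWM],
    snv: SNVRecord,
    flank: int = DEFAULT_FLANK,
    site_threshold: float = DEFAULT_SITE_THRESHOLD,
    delta_min: float = DEFAULT_DELTA_MIN,
    top_k: int = DEFAULT_TOP_K,
) -> tuple[list[AffinityShift], list[AffinityShift]]:
    """Score one SNV against a PWM library.

    Extracts the ``2*flank + 1`` bp window centred on the variant,
    substitutes the centre base with the alternate allele, computes all
    per-TF shifts and returns ``(full_table, top_k_table)``. The genome
    base at the variant position must equal the SNV's ref allele.
    """
    wt_window = extract_window(genome, snv.chrom, snv.pos, flank)
    observed = wt_window[flank]
    if observed != snv.ref:
        raise ValueError(
            f"ref mismatch for {snv}: genome has {observed!r}"
        )
    mut_window = wt_window[:flank] + snv.alt + wt_window[flank + 1 :]
    shifts = affinity_shift(pwms, wt_window, mut_window,
                            site_threshold=site_threshold, delta_min=delta_min)
    return shifts, rank_top_k(shifts, k=top_k)


# ---------------------------------------------------------------------------
# JASPAR-style PFM text I/O
# ---------------------------------------------------------------------------

def read_jaspar(path: str | Path) -> list[PFM]:
    """Read a JASPAR-style PFM text file.

    Format: a ``>ID NAME`` header followed by four rows ``A [ 1 2 3 ]``
    (brackets optional), in A/C/G/T order.
    """
    from Bio import motifs as bio_motifs

    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "jaspar")
    out = []
    for motif in parsed:
        counts = np.array([list(motif.counts[b]) for b in BASES], dtype=float)
        out.append(
            PFM(
                name=motif.name or motif.matrix_id,
                matrix_id=motif.matrix_id or motif.name,
                counts=counts,
            )
        )
    return out


def write_jaspar(pfms: Sequence[PFM], path: str | Path) -> None:
    with open(path, "w") as fh:
        for pfm in pfms:
            fh.write(f">{pfm.matrix_id} {pfm.name}\n")
            for i, base in enumerate(BASES):
                row = " ".join(f"{v:g}" for v in pfm.counts[i])
                fh.write(f"{base} [ {row} ]\n")


def write_shift_table(shifts: Sequence[AffinityShift], path: str | Path) -> None:
    """TSV: TF, wt_rel, mut_rel, delta, category, offsets/strands."""
    with open(path, "w") as fh:
        fh.write("tf\twt_rel\tmut_rel\tdelta\tcategory\t"
                 "wt_offset\twt_strand\tmut_offset\tmut_strand\n")
        for s in shifts:
            fh.write(
                f"{s.tf_name}\t{s.wt_rel:.6f}\t{s.mut_rel:.6f}\t"
                f"{s.delta:.6f}\t{s.category}\t{s.wt_offset}\t{s.wt_strand}\t"
                f"{s.mut_offset}\t{s.mut_strand}\n"
            )
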