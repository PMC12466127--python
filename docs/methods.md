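# Methods

`enhancerscan` implements a five-stage analysis of non-coding somatic
single-nucleotide variants (SNVs) in tumor-type-specific enhancer
elements, together with a synthetic-data generator that plants a known
truth through every stage. This note records the models, the parameters
that matter, the numerical conventions, and the limits of what the
synthetic experiments can show.

## Coordinates

All intervals are BED-style 0-based half-open `[start, end)`; variant
positions are VCF-style 1-based. The two conventions meet in exactly one
predicate, `vcf_pos_in_interval(pos, iv) := iv.start <= pos - 1 < iv.end`.
A consequence worth spelling out: a VCF position numerically equal to a
BED start coordinate lies one base *before* the interval and is not
contained. Abutting intervals merge — regulatory regions are treated as
closed genomic segments, so `[0,10)` and `[10,20)` become `[0,20)`.

## Group-specific accessible regions

Given per-sample peak sets for two cohorts (e.g. GBM, n = 9 vs LGG,
n = 12 accessibility profiles), the consensus regions are the merged
union of all peaks from both cohorts. For each consensus region the
*recurrence* in a group is the fraction of that group's samples with at
least a 1 bp overlapping peak (a minimum-overlap fraction of the sample
peak is available via `min_overlap_frac`, default 0). Statuses:

- **A-specific**: recurrence_A ≥ `f_min` (default 0.5) and
  recurrence_B ≤ `f_max` (default 0.1);
- **B-specific**: symmetric;
- **shared**: recurrent (≥ `f_min`) in at least one group and specific
  to neither.

Regions recurrent in neither group are dropped as inactive. The third
clause is deliberately wider than "recurrent in both": it makes the
partition exhaustive, so a region recurrent in one group whose other-group
recurrence falls between `f_max` and `f_min` is reported as shared rather
than silently vanishing, and swapping the cohort arguments swaps the two
specific sets exactly. This recurrence-threshold consensus is a declared
stand-in for count-based differential-accessibility testing; it is the
simplest rule that reproduces the specific/specific/common partition and
is exactly testable against planted truth.

## Element classification and enrichment

Regions are classified promoter / insulator element (IE) / enhancer
element (EE) by ≥ 1 bp overlap with the corresponding annotation track,
first hit in priority order winning (default promoter > IE > EE,
configurable); no overlap means "other". Promoters rank first because
they are the most confidently mapped class.

Per-class composition of the two groups is compared with a Pearson
chi-square on the 2×2 table `[[a, A−a], [b, B−b]]` using the closed form
`chi2 = N(ad−bc)² / ((a+b)(c+d)(a+c)(b+d))`, one degree of freedom, no
continuity correction (immaterial at n ≈ 20,000 per group; omitted for
bit-reproducibility), p-value from the chi-square survival function.
A zero marginal raises rather than returning a silent 0. No
multiple-testing correction is applied across the three classes; the
report carries a two-tier flag (significant at α = 0.001, non-significant
at α = 0.05). In tests the closed form is cross-checked against
`scipy.stats.chi2_contingency` to 1e-9 relative tolerance, and its
permutation-null rejection rate at α = 0.05 is verified to sit inside the
binomial 95% CI over 1000 label permutations. The calibration fixture
uses 2000 regions per group: the asymptotic chi-square reference requires
expected counts large enough that discreteness is negligible, which
matches the study-scale inputs this test stands in for.

## SNV-enhancer overlap and prioritization

Somatic SNVs (after allele-aware exclusion of known SNPs) are intersected
with one group's EE-class specific regions. SNVs hitting no element go to
an explicit spill-over list, so counts are conserved. Per mutated element
the profile records its SNVs, distinct patients, and hotspot clusters.

*Hotspots* are single-linkage clusters per chromosome: two SNVs join one
cluster iff their positions differ by ≤ `hotspot_gap` (default 7 bp,
the window within which independently discovered variants are treated as
one mutational hotspot), directly or transitively. With gap 0 every
distinct position is its own cluster; increasing the gap can only merge
clusters.

Candidates are ranked lexicographically: distinct patients (descending)
— recurrence outranks raw SNV count — then SNV count, then curated genes
within ±`neighborhood_bp` (default 1 Mb) of the element midpoint, then
presence of a high-confidence enhancer-gene interaction, with element ID
ascending as the final deterministic tiebreak. Gene distance is measured
midpoint-to-nearest-gene-edge with an inclusive threshold; the midpoint
anchor is a declared choice (the anchor is otherwise underdetermined).
Interactions are supporting evidence only, never a filter. The top
`top_n` (default 3) are returned.

## PWM affinity-shift scanning

A position frequency matrix (counts, 4 × L, L ≥ 4) becomes a log-odds
weight matrix

    w[b, j] = log2( ((counts[b, j] + pc) / (colsum_j + 4 pc)) / bg[b] )

with per-cell pseudocount `pc` = 0.25 and uniform background (both
configurable). `S_min`/`S_max` are the column-wise worst/best sums; a
motif with `S_min == S_max` (no discriminating column) is rejected as
degenerate.

For a variant, the wild-type window is the `2*flank + 1` bp sequence
centred on the position (default flank 7, window 15 bp, variant at the
centre); the mutant window substitutes the centre base. Each motif is
scanned over *both strands* but only over alignment offsets whose
footprint covers the variant base (on the minus strand, coverage is
assessed after reverse-complementing the window) — an alignment that
does not cover the variant cannot report a variant effect, and this
constraint is what guarantees delta = 0 when the variant cannot matter.
The best raw score is min-max normalized to the *relative score*
`rel = (S − S_min) / (S_max − S_min) ∈ [0, 1]`, comparable across motifs
of different lengths. `N` bases contribute weight 0 (the background
expectation) at any scored position, logged per occurrence, rather than
failing; with a non-uniform background the normalized score is clamped
to [0, 1] since 0 need not lie between the column extremes.

Per TF, `delta = mut_rel − wt_rel` and the category is:

- **novel**: wt_rel < `site_threshold` ≤ mut_rel (default threshold
  0.80, a conventional motif-match cutoff);
- **lost_site**: the mirror image;
- **gain** / **loss**: |delta| ≥ `delta_min` (default 0.05) without
  crossing the threshold;
- **neutral** otherwise.

Categories are mutually exclusive and exhaustive; swapping the alleles
negates every delta exactly. Rankings order by |delta| descending, ties
by the larger of the two relative scores, then TF name; the top
`top_k` (default 5) are reported per variant. The scanner is verified
against an exhaustive offset × strand brute force for all motif lengths
≤ 6 over thousands of random windows.

## Validation-cohort statistics

The genotype table holds tissue specimens (patient, section,
tumor/peritumoral) by target regions, cells in {WT, mutant allele, NS}.
Non-sequenced (NS) cells are excluded from **every** denominator —
treating NS as WT would bias frequencies downward. Conventions:

- *Callability*: per region, fraction of tumor specimens with a non-NS
  call; regions strictly above `callability_threshold` (default 0.85)
  are flagged.
- *Mutation frequency*: per region, MUT / (MUT + WT) over tumor
  specimens; a region with zero callable cells reports missing, not 0.
- *Burden*: patient-level — fraction of patients (any tumor section)
  with ≥ 1 mutation among patients with ≥ 1 callable region.
  Multifocal sections belong to one sample for this purpose.
- *Co-occurrence*: patients with mutations in ≥ 2 distinct regions,
  plus a symmetric zero-diagonal region × region co-mutation matrix.
- *Known-SNP filter*: exact (chrom, pos, ref, alt) matches only; a
  different alternate allele at a known SNP position stays somatic.
  The partition conserves the input count.
- *Multifocal concordance*: per region, among patients with ≥ 2
  callable tumor sections, the fraction whose sections all carry an
  identical call (all WT, or all the same allele) — the strictest
  defensible reading of section agreement. "Over 75%" is a strict
  inequality: exactly 0.75 is not flagged.
- *Peritumoral exclusivity*: for patients with ≥ 1 tumor mutation and
  ≥ 1 peritumoral specimen, any mutant peritumoral cell is reported
  with the offending specimen named; the summary flag is true iff none
  exists.

All summaries are invariant under row permutation of the table.

## Synthetic data: what it emulates, and what it does not

Every generator is a pure function of (parameters, seed); identical
calls are byte-identical. Planted fractions are realized by exact
integer arithmetic — counts rounded half-up to the nearest achievable
integer and the *realized* values recorded in a JSON ground-truth
sidecar — rather than Bernoulli draws, so recovery assertions can be
exact. The paper-like preset uses, as its study conditions: a 2 × 100 kb
genome at GC 0.41; accessibility cohorts of 9 vs 12 samples with 20
A-specific, 30 B-specific and 50 shared regions (300–800 bp, ≥ 150 bp
apart); class mix 35% promoter / 20% IE / 35% EE / 10% other; a
39-patient SNV cohort planting five somatic SNVs across three enhancers
(one variant recurrent in three patients), one spill-over SNV, and three
germline known-SNP decoys (one inside an enhancer); a PFM library of
eight random background motifs plus one planted site-creating and one
site-destroying motif; and a 54-patient validation cohort (11 multifocal,
9 peritumoral) with planted per-region frequencies
(0.30, 0.15, 0, 0.12, 0.18), callability (0.95, 0.90, 0.90, 0.88, 0.50)
and concordance (0.90, 0.82, 1.0, 0.78, 0.60). The region with zero
planted frequency carries concordance 1.0 — a discordant section pair
requires a mutant section, so any other pairing is infeasible and the
generator raises on it. These scales keep the full suite in seconds
while preserving every structural feature the statistics depend on.

Peak dropout is planted per region as *exactly* `round(d · n_group)`
missing samples, so with dropout ≤ 1 − `f_min` the planted statuses
remain exactly recoverable by construction — the dropout experiments
test the calling logic, not sampling luck.

The planted gain motif (length 8) takes its consensus from the mutant
window spanning the variant; the variant column carries its entire count
mass on the favoured base (so the wild-type allele is strongly
unfavourable there) while flanking columns are moderately informative
(85 : 5). This puts the mutant consensus at relative score 1.0 and the
wild-type best match near 0.77, below the 0.80 site threshold — a
*novel* call. The loss construction is the mirror image on the wild-type
window.

What the generator does **not** emulate: read-level data (no FASTQ/BAM,
no peak calling from coverage), count-based differential accessibility,
linkage between germline decoys and population allele frequencies,
FFPE artifacts, sub-clonal allele fractions, or real motif databases.
Passing the planted-recovery suite therefore demonstrates that the
*computational* contracts hold exactly; it says nothing about the
sensitivity of the recurrence rule or the scanner on real, noisy peak
sets and whole genomes.

## Numerical and degenerate-input conventions

- Rounding of planted counts: half-up (`floor(x + 0.5)`).
- Largest-remainder apportionment for class mixes, ties broken by class
  name, remainder to "other".
- All orderings carry a deterministic final tiebreak (element ID or TF
  name), so outputs are total orders and reports byte-reproducible.
- Empty inputs: an empty SNV list, an empty profile list, or zero
  planted regions propagate to empty outputs without error; an empty
  cohort, a genotype table without tumor (or, for exclusivity,
  peritumoral) specimens, and a zero chi-square marginal raise.
- The pipeline report contains no timestamps; rerunning with identical
  config and seed produces byte-identical reports.

## Known limitations

- The recurrence-threshold consensus has no notion of peak strength or
  width; a 1 bp overlap counts unless `min_overlap_frac` is raised.
- The enhancer set used for SNV overlap is the EE-class subset of one
  group's specific regions; any further filtering to a "dynamic" subset
  is out of scope and not implemented.
- Motif hits are not calibrated to p-values and the background model is
  mononucleotide only.
- The assembly of input coordinates is never validated; all inputs must
  share one reference.
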