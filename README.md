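# enhancerscan

Non-coding somatic single-nucleotide variants (SNVs) that land in
tumor-type-specific enhancer elements can rewire transcription-factor
(TF) binding and with it the regulatory programs of a tumor.
`enhancerscan` is a Python toolkit for the full analysis path from
chromatin-accessibility peak sets to TF binding-affinity shifts, built
for regulatory-genomics analysts working with glioma-style two-cohort
designs (e.g. glioblastoma vs lower-grade glioma):

1. **Group-specific accessible regions** — from two cohorts of
   per-sample peak BEDs, call A-specific / B-specific / shared consensus
   regions by a recurrence rule (present in ≥ 50% of one group's
   samples, ≤ 10% of the other's; both thresholds configurable).
2. **Element classification and enrichment** — label regions promoter /
   insulator (IE) / enhancer (EE) by annotation-track overlap and
   compare per-class composition between groups with a Pearson
   chi-square on the 2×2 table, χ² = N(ad−bc)²/((a+b)(c+d)(a+c)(b+d)).
3. **SNV-enhancer overlap** — intersect per-patient somatic SNVs (VCF)
   with one group's specific EEs, cluster mutational hotspots
   (single-linkage, ≤ 7 bp), and rank candidate enhancers by patient
   recurrence, SNV count, curated genes within ±1 Mb, and enhancer-gene
   interaction evidence.
4. **TF affinity-shift scanning** — score the 15 bp wild-type and mutant
   windows (variant centred) against a JASPAR-style PWM library over
   both strands, restricted to alignments covering the variant; report
   per-TF relative scores rel = (S − S_min)/(S_max − S_min) ∈ [0, 1],
   the shift Δ = rel_mut − rel_wt, and gain / loss / novel-site /
   lost-site calls (site threshold 0.80).
5. **Validation-cohort summaries** — per-region callability and
   mutation frequency, patient-level burden, co-occurrence, allele-aware
   known-SNP filtering, multifocal section concordance, and peritumoral
   exclusivity from a targeted-sequencing genotype table.

A synthetic-data module generates every input with machine-readable
planted ground truth (genome FASTA, peak BEDs, annotation tracks,
per-patient VCFs, PFM library, genotype TSV), so the whole pipeline is
testable end to end without any external data. See `docs/methods.md`
for the models, conventions and limitations.

## Worked example

```python
from enhancerscan import PipelineConfig
from enhancerscan.pipeline import manifest_from_fixture_dir, run_all
from enhancerscan.simulate import simulate_paper_like

simulate_paper_like("fixture", seed=1)          # synthetic inputs + truth
report = run_all(PipelineConfig(seed=1),
                 manifest_from_fixture_dir("fixture"), "out")

s = report["stages"]
print(s["specificity"])
top = s["overlap"]["candidates"][0]
print(top["element_id"], top["n_patients"], "patients")
scan = s["tfscan"]["scans"][0]
print(scan["snv"], scan["top"][0])
print("burden %.1f%%" % (100 * s["cohort"]["frequencies"]["burden"]))
```

prints

```
{'group_A': 'A', 'group_B': 'B', 'n_samples_A': 9, 'n_samples_B': 12,
 'A_specific': 20, 'B_specific': 30, 'shared': 50}
EE-A-003 3 patients
chr1:30801G>T {'tf': 'TFGAIN1', 'wt_rel': 0.764993, 'mut_rel': 1.0,
 'delta': 0.235007, 'category': 'novel'}
burden 63.0%
```

Reading this: the 20/30/50 split recovers the planted group-specific and
shared accessible regions exactly; the top-ranked candidate enhancer is
the one carrying the variant recurrent in 3 of 39 patients; at that
variant the planted motif's best relative score rises from 0.76 to 1.00
— crossing the 0.80 site threshold, hence a *novel* binding-site call;
and 63% of validation-cohort patients carry at least one mutation in the
targeted regions.

The same stages are available from the shell:

```bash
enhancerscan run-all --preset paper-like --seed 1 --out demo_out
enhancerscan cohort --table fixture/genotypes.tsv \
    --snps fixture/known_snps.tsv --out cohort.json
```

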