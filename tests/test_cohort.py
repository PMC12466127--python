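"""Validation-cohort summary statistics."""

import numpy as np
import pandas as pd
import pytest

from enhancerscan import (
    GenomicInterval,
    GenotypeTable,
    KnownSNPSet,
    SNVRecord,
    co_occurrence,
    filter_known_snps,
    multifocal_concordance,
    mutation_frequencies,
    peritumoral_exclusivity,
    region_callability,
)
from enhancerscan.cohort import Specimen
from enhancerscan.simulate import generate_genotype_table


def build_table(rows, regions=None):
    """rows: list of (specimen_id, patient, section, compartment, calls...)"""
    if regions is None:
        regions = {
            "R1": GenomicInterval("chr9", 1000, 1200),
            "R2": GenomicInterval("chr9", 5000, 5200),
        }
    specimens = [Specimen(*r[:4]) for r in rows]
    calls = pd.DataFrame(
        [list(r[4:]) for r in rows],
        index=pd.Index([r[0] for r in rows]),
        columns=list(regions),
    )
    return GenotypeTable(specimens, regions, calls)


MUT1 = "chr9:1100C>T"
MUT1B = "chr9:1103A>G"
MUT2 = "chr9:5100G>A"


class TestGenotypeTable:
    def test_mutation_outside_column_region_rejected(self):
        with pytest.raises(ValueError, match="outside region"):
            build_table([("s1", "p1", "S1", "tumor", "chr9:4999G>A", "WT")],
                        regions={"R1": GenomicInterval("chr9", 1000, 1200),
                                 "R2": GenomicInterval("chr9", 5000, 5200)})

    def test_malformed_cell_rejected(self):
        with pytest.raises(ValueError, match="malformed"):
            build_table([("s1", "p1", "S1", "tumor", "mut", "WT")])

    def test_tsv_round_trip(self, tmp_path):
        table = build_table([
            ("p1-S1", "p1", "S1", "tumor", MUT1, "WT"),
            ("p2-S1", "p2", "S1", "tumor", "NS", MUT2),
        ])
        path = tmp_path / "geno.tsv"
        table.to_tsv(path)
        back = GenotypeTable.from_tsv(path)
        assert back.regions == table.regions
        assert back.calls.equals(table.calls)
        assert back.specimens == table.specimens


class TestRegionCallability:
    def test_no_ns_gives_all_one(self):
        table = build_table([
            ("p1-S1", "p1", "S1", "tumor", "WT", MUT2),
            ("p2-S1", "p2", "S1", "tumor", MUT1, "WT"),
        ])
        result = region_callability(table)
        assert result["fractions"] == {"R1": 1.0, "R2": 1.0}
        assert result["n_above_threshold"] == 2

    def test_hand_counted_fraction_below_flag(self):
        rows = [(f"p{i}-S1", f"p{i}", "S1", "tumor",
                 "NS" if i < 4 else "WT", "WT") for i in range(10)]
        result = region_callability(build_table(rows))
        assert result["fractions"]["R1"] == pytest.approx(0.6)
        assert result["n_above_threshold"] == 1

    def test_peritumoral_rows_excluded_from_denominator(self):
        table = build_table([
            ("p1-S1", "p1", "S1", "tumor", MUT1, "WT"),
            ("p1-PT", "p1", "PT1", "peritumoral", "NS", "NS"),
        ])
        assert region_callability(table)["fractions"] == {"R1": 1.0, "R2": 1.0}

    def test_tumor_free_table_rejected(self):
        table = build_table(
            [("p1-PT", "p1", "PT1", "peritumoral", "WT", "WT")]
        )
        with pytest.raises(ValueError):
            region_callability(table)


class TestMutationFrequencies:
    def test_all_wt(self):
        rows = [(f"p{i}-S1", f"p{i}", "S1", "tumor", "WT", "WT")
                for i in range(5)]
        result = mutation_frequencies(build_table(rows))
        assert result["frequencies"] == {"R1": 0.0, "R2": 0.0}
        assert result["burden"] == 0.0

    def test_ns_excluded_from_denominator(self):
        # region R1: 3 MUT, 6 WT, 1 NS -> frequency 1/3
        rows = []
        for i in range(10):
            call = MUT1 if i < 3 else ("NS" if i == 9 else "WT")
            rows.append((f"p{i}-S1", f"p{i}", "S1", "tumor", call, "WT"))
        result = mutation_frequencies(build_table(rows))
        assert result["frequencies"]["R1"] == pytest.approx(1 / 3)

    def test_zero_callable_region_reports_missing(self):
        rows = [(f"p{i}-S1", f"p{i}", "S1", "tumor", "NS", "WT")
                for i in range(4)]
        result = mutation_frequencies(build_table(rows))
        assert result["frequencies"]["R1"] is None

    def test_burden_is_patient_level(self):
        rows = [
            ("p1-S1", "p1", "S1", "tumor", MUT1, "WT"),
            ("p1-S2", "p1", "S2", "tumor", MUT1, "WT"),  # same patient
            ("p2-S1", "p2", "S1", "tumor", "WT", "WT"),
        ]
        result = mutation_frequencies(build_table(rows))
        assert result["n_patients_mutated"] == 1
        assert result["burden"] == pytest.approx(0.5)


class TestCoOccurrence:
    def test_single_region_table_empty(self):
        table = build_table(
            [("p1-S1", "p1", "S1", "tumor", MUT1)],
            regions={"R1": GenomicInterval("chr9", 1000, 1200)},
        )
        assert co_occurrence(table)["patients"] == {}

    def test_double_mutated_patient_found(self):
        table = build_table([
            ("p1-S1", "p1", "S1", "tumor", MUT1, MUT2),
            ("p2-S1", "p2", "S1", "tumor", MUT1, "WT"),
        ])
        result = co_occurrence(table)
        assert result["patients"] == {"p1": ["R1", "R2"]}

    def test_matrix_symmetric_zero_diagonal(self):
        table = build_table([
            ("p1-S1", "p1", "S1", "tumor", MUT1, MUT2),
            ("p2-S1", "p2", "S1", "tumor", MUT1, MUT2),
        ])
        m = co_occurrence(table)["matrix"]
        assert (m.values == m.values.T).all()
        assert (np.diag(m.values) == 0).all()
        assert m.at["R1", "R2"] == 2


class TestFilterKnownSnps:
    def test_empty_snp_set_all_somatic(self):
        muts = [SNVRecord("chr9", 1100, "C", "T")]
        somatic, flagged = filter_known_snps(muts, KnownSNPSet())
        assert somatic == muts and flagged == []

    def test_allele_aware_not_position_only(self):
        snps = KnownSNPSet([("chr9", 1100, "C", "G")])
        mut = SNVRecord("chr9", 1100, "C", "T")  # same position, other alt
        somatic, flagged = filter_known_snps([mut], snps)
        # position-only matching would flag this record; allele-aware keeps it
        assert somatic == [mut] and flagged == []

    def test_planted_decoys_flagged_and_count_conserved(self):
        muts = [
            SNVRecord("chr9", int(1001 + i), "C", "T", patient=f"p{i}")
            for i in range(10)
        ]
        decoys = [muts[2], muts[7]]
        snps = KnownSNPSet([(m.chrom, m.pos, m.ref, m.alt) for m in decoys])
        somatic, flagged = filter_known_snps(muts, snps)
        assert flagged == decoys
        assert len(somatic) + len(flagged) == len(muts)


class TestMultifocalConcordance:
    def test_identical_sections_fully_concordant(self):
        table = build_table([
            ("p1-S1", "p1", "S1", "tumor", MUT1, "WT"),
            ("p1-S2", "p1", "S2", "tumor", MUT1, "WT"),
        ])
        result = multifocal_concordance(table)
        assert result["fractions"] == {"R1": 1.0, "R2": 1.0}

    def test_different_alleles_are_discordant(self):
        table = build_table([
            ("p1-S1", "p1", "S1", "tumor", MUT1, "WT"),
            ("p1-S2", "p1", "S2", "tumor", MUT1B, "WT"),
        ])
        assert multifocal_concordance(table)["fractions"]["R1"] == 0.0

    def test_exactly_75pct_not_flagged_strict_inequality(self):
        rows = []
        for i in range(4):
            r1_second = MUT1 if i == 0 else "WT"  # one discordant patient
            rows.append((f"p{i}-S1", f"p{i}", "S1", "tumor", "WT", "WT"))
            rows.append((f"p{i}-S2", f"p{i}", "S2", "tumor", r1_second, "WT"))
        result = multifocal_concordance(build_table(rows))
        assert result["fractions"]["R1"] == pytest.approx(0.75)
        assert result["fractions"]["R2"] == 1.0
        assert result["n_above_threshold"] == 1

    def test_no_multifocal_patients_warns_not_errors(self):
        table = build_table([("p1-S1", "p1", "S1", "tumor", "WT", "WT")])
        result = multifocal_concordance(table)
        assert result["fractions"] == {} and "warning" in result

    def test_ns_sections_drop_from_denominator(self):
        table = build_table([
            ("p1-S1", "p1", "S1", "tumor", MUT1, "WT"),
            ("p1-S2", "p1", "S2", "tumor", "NS", "WT"),
        ])
        # only one callable section in R1 -> patient not evaluable there
        assert multifocal_concordance(table)["fractions"]["R1"] is None


class TestPeritumoralExclusivity:
    def test_no_peritumoral_specimens_rejected(self):
        table = build_table([("p1-S1", "p1", "S1", "tumor", MUT1, "WT")])
        with pytest.raises(ValueError):
            peritumoral_exclusivity(table)

    def test_clean_peritumoral_is_exclusive(self):
        table = build_table([
            ("p1-S1", "p1", "S1", "tumor", MUT1, "WT"),
            ("p1-PT", "p1", "PT1", "peritumoral", "WT", "NS"),
        ])
        result = peritumoral_exclusivity(table)
        assert result["tumor_exclusive"] is True
        assert result["patients_evaluated"] == ["p1"]

    def test_planted_violation_names_specimen(self):
        table = build_table([
            ("p1-S1", "p1", "S1", "tumor", MUT1, "WT"),
            ("p1-PT", "p1", "PT1", "peritumoral", MUT1, "WT"),
        ])
        result = peritumoral_exclusivity(table)
        assert result["tumor_exclusive"] is False
        assert "p1-PT:R1:" + MUT1 in result["violations"]["p1"]


class TestRowPermutationInvariance:
    def test_summaries_invariant_under_row_order(self):
        table, _ = generate_genotype_table(seed=5)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(table.specimens))
        shuffled = GenotypeTable(
            [table.specimens[i] for i in perm],
            table.regions,
            table.calls.iloc[perm],
        )
        assert region_callability(table) == region_callability(shuffled)
        assert mutation_frequencies(table) == mutation_frequencies(shuffled)
        assert co_occurrence(table)["patients"] == \
            co_occurrence(shuffled)["patients"]
        assert multifocal_concordance(table) == multifocal_concordance(shuffled)


class TestPlantedCohortRecovery:
    def test_planted_design_recovered_exactly(self):
        table, gt = generate_genotype_table(seed=5)
        realized = gt["realized"]

        callability = region_callability(table, threshold=0.85)
        assert callability["fractions"] == realized["callability"]
        assert callability["n_above_threshold"] == 4  # four of five regions

        freqs = mutation_frequencies(table)
        assert freqs["frequencies"] == realized["frequency"]
        assert freqs["burden"] == pytest.approx(realized["burden"])
        assert freqs["burden"] > 0.46

        cooc = co_occurrence(table)
        assert sorted(cooc["patients"]) == gt["cooccurrent_patients"]
        assert len(cooc["patients"]) == 7

        concordance = multifocal_concordance(table, threshold=0.75)
        assert concordance["fractions"] == realized["concordance"]
        assert concordance["n_above_threshold"] == 4

        peri = peritumoral_exclusivity(table)
        assert peri["tumor_exclusive"] is True
        assert peri["patients_evaluated"] == gt["peritumoral_patients"]

    def test_planted_violation_detected(self):
        table, gt = generate_genotype_table(seed=5,
                                            peritumoral_violation=True)
        peri = peritumoral_exclusivity(table)
        assert peri["tumor_exclusive"] is False
        cell = gt["peritumoral_violation"]
        assert any(
            v.startswith(cell["specimen"] + ":" + cell["region"])
            for v in peri["violations"][cell["specimen"].rsplit("-", 1)[0]]
        )

    def test_callability_all_one_and_zero_frequencies(self):
        table, _ = generate_genotype_table(
            frequencies=(0.0, 0.0), callability=(1.0, 1.0),
            concordance=(1.0, 1.0), n_multifocal=4, n_cooccurrent=0,
            n_peritumoral=0, n_patients=20, seed=8,
        )
        assert region_callability(table)["fractions"] == {"EE-R1": 1.0,
                                                          "EE-R2": 1.0}
        freqs = mutation_frequencies(table)
        assert freqs["frequencies"] == {"EE-R1": 0.0, "EE-R2": 0.0}
        assert freqs["burden"] == 0.0
        assert co_occurrence(table)["patients"] == {}
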