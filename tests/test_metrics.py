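"""Counts/CPM/CV, end precision, profiles, composition, classifiers."""

import numpy as np
import pandas as pd
import pytest

from ottr_endqc.metrics import (
    apply_median_filter,
    classify_alignment_mechanism,
    classify_junction,
    coefficient_of_variation,
    composition_summary,
    end_coverage_profile,
    end_precision,
    mirna_counts_cpm,
    stratification_medians,
    terminal_nt_stratification,
)
from ottr_endqc.references import MiRNAEntry, MiRNAReference, OligoScheme


def make_ref(*seqs):
    return MiRNAReference(
        MiRNAEntry(f"m{i}", s) for i, s in enumerate(seqs)
    )


def alignment_table(rows):
    """rows: (read_id, reference_id, start, end [, multi])"""
    recs = []
    for row in rows:
        read_id, ref_id, start, end = row[:4]
        multi = row[4] if len(row) > 4 else False
        recs.append(
            {"read_id": read_id, "category": "mirna", "subcategory": None,
             "reference_id": ref_id, "start": start, "end": end, "strand": "+",
             "mismatches": 0, "multi_mapping": multi, "read_length": end - start}
        )
    columns = ["read_id", "category", "subcategory", "reference_id", "start",
               "end", "strand", "mismatches", "multi_mapping", "read_length"]
    return pd.DataFrame(recs, columns=columns)


REF2 = make_ref("ACGTACGTACGTACGTACGT", "TTGGCCAATTGGCCAATTGG")  # m0, m1 (20 nt)


class TestCountsCpm:
    def test_cpm_arithmetic(self):
        aln = alignment_table(
            [("r1", "m0", 0, 20), ("r2", "m0", 0, 20), ("r3", "m0", 0, 20),
             ("r4", "m1", 0, 20)]
        )
        table = mirna_counts_cpm(aln, REF2)
        assert table.loc["m0", "cpm"] == pytest.approx(750_000)
        assert table.loc["m1", "cpm"] == pytest.approx(250_000)
        assert table["cpm"].sum() == pytest.approx(1e6)

    def test_zero_count_mirnas_present(self):
        aln = alignment_table([("r1", "m0", 0, 20)])
        table = mirna_counts_cpm(aln, REF2)
        assert table.loc["m1", "count"] == 0

    def test_multimapping_excluded_when_requested(self):
        aln = alignment_table(
            [("r1", "m0", 0, 20), ("r2", "m0", 0, 20, True)]
        )
        strict = mirna_counts_cpm(aln, REF2, single_mapping_only=True)
        loose = mirna_counts_cpm(aln, REF2, single_mapping_only=False)
        assert strict.loc["m0", "count"] == 1
        assert loose.loc["m0", "count"] == 2

    def test_zero_total_flagged_not_fatal(self):
        table = mirna_counts_cpm(alignment_table([]), REF2)
        assert (table["count"] == 0).all()
        assert table["cpm"].isna().all()


class TestMedianFilter:
    def test_threshold_on_median(self):
        counts = pd.DataFrame(
            {"lib1": [10, 10], "lib2": [60, 20], "lib3": [70, 70]},
            index=["keep", "drop"],
        )
        assert apply_median_filter(counts, 50) == {"keep"}

    def test_zero_threshold_is_identity(self):
        counts = pd.DataFrame({"lib1": [0, 5]}, index=["a", "b"])
        assert apply_median_filter(counts, 0) == {"a", "b"}


class TestCV:
    @pytest.mark.parametrize(
        "values,expected",
        [([5, 5, 5], 0.0), ([10, 20, 30], 0.5), ([100, 300], 0.7071067811865476)],
    )
    def test_known_values(self, values, expected):
        assert coefficient_of_variation(values) == pytest.approx(expected)

    def test_zero_mean_errors(self):
        with pytest.raises(ValueError):
            coefficient_of_variation([0, 0, 0])


class TestEndPrecision:
    def _fixture(self):
        # miRNA m0: 8/10 alignments reach the final nucleotide; m1: 6/10
        rows = []
        for i in range(10):
            end = 20 if i < 8 else 19
            rows.append((f"a{i}", "m0", 0, end))
        for i in range(10):
            end = 20 if i < 6 else 19
            rows.append((f"b{i}", "m1", 0, end))
        return alignment_table(rows)

    def test_hand_tally_3p(self):
        summary = end_precision(self._fixture(), REF2, end="3p")
        assert summary.mean_precision == pytest.approx(0.7)
        assert summary.m == 2

    def test_hand_tally_5p(self):
        rows = [(f"r{i}", "m0", 0 if i < 3 else 1, 20) for i in range(4)]
        summary = end_precision(alignment_table(rows), REF2, end="5p")
        assert summary.mean_precision == pytest.approx(0.75)

    def test_full_coverage_is_unity(self):
        rows = [(f"r{i}", "m0", 0, 20) for i in range(5)]
        s3 = end_precision(alignment_table(rows), REF2, end="3p")
        s5 = end_precision(alignment_table(rows), REF2, end="5p")
        assert s3.mean_precision == 1.0 and s5.mean_precision == 1.0

    def test_restricted_to_reliable_ids(self):
        summary = end_precision(self._fixture(), REF2, reliable_ids={"m0"},
                                end="3p")
        assert summary.m == 1
        assert summary.mean_precision == pytest.approx(0.8)

    def test_literal_double_normalisation_variant(self):
        summary = end_precision(self._fixture(), REF2, end="3p", per_mirna=False)
        # (1/T)(1/m) sum b = 14 / (20 * 2)
        assert summary.mean_precision == pytest.approx(14 / 40)

    def test_no_alignments_errors(self):
        with pytest.raises(ValueError):
            end_precision(alignment_table([]), REF2)


class TestEndCoverageProfile:
    def test_full_length_mass_at_zero(self):
        aln = alignment_table([(f"r{i}", "m0", 0, 20) for i in range(4)])
        profile = end_coverage_profile(aln, REF2, "m0", anchor="3p")
        assert profile.to_dict() == {0: 4}

    def test_truncation_offsets(self):
        aln = alignment_table(
            [("r1", "m0", 0, 19), ("r2", "m0", 0, 19), ("r3", "m0", 0, 18)]
        )
        profile = end_coverage_profile(aln, REF2, "m0", anchor="3p")
        assert profile.to_dict() == {-2: 1, -1: 2}

    def test_5p_anchor_mirror(self):
        aln = alignment_table([("r1", "m0", 1, 20), ("r2", "m0", 0, 20)])
        profile = end_coverage_profile(aln, REF2, "m0", anchor="5p")
        assert profile.to_dict() == {-1: 1, 0: 1}

    def test_unknown_id_errors(self):
        with pytest.raises(KeyError):
            end_coverage_profile(alignment_table([]), REF2, "nope")

    def test_mixture_proportions_recovered(self):
        rng = np.random.default_rng(8)
        rows = []
        for i in range(400):
            off = 0 if rng.random() < 0.7 else 2
            rows.append((f"r{i}", "m0", 0, 20 - off))
        profile = end_coverage_profile(alignment_table(rows), REF2, "m0")
        frac0 = profile.get(0, 0) / profile.sum()
        assert frac0 == pytest.approx(0.7, abs=3 * np.sqrt(0.7 * 0.3 / 400))


class TestComposition:
    def _records(self):
        rows = []
        for i, (cat, length) in enumerate(
            [("mirna", 22)] * 6 + [("genome", 25)] * 2 + [("unmapped", 30)]
            + [("mirna", 17), ("mirna", 18)]
        ):
            rows.append({"read_id": f"r{i}", "category": cat, "subcategory": None,
                         "reference_id": None, "start": None, "end": None,
                         "strand": None, "mismatches": None,
                         "multi_mapping": False, "read_length": length})
        return pd.DataFrame(rows)

    def test_17nt_reads_excluded_18_included(self):
        fractions, hists = composition_summary(self._records(), min_len=17)
        total = 6 + 2 + 1 + 1  # the 17-nt read is excluded
        assert fractions["mirna"] == pytest.approx(7 / total)
        assert 17 not in hists["mirna"].index
        assert 18 in hists["mirna"].index

    def test_fractions_partition_to_one(self):
        fractions, _ = composition_summary(self._records())
        assert fractions.sum() == pytest.approx(1.0, abs=1e-12)

    def test_pure_library(self):
        recs = self._records()
        fractions, _ = composition_summary(recs[recs["category"] == "mirna"])
        assert fractions.to_dict() == {"mirna": 1.0}


class TestTerminalStratification:
    def test_groups_and_zero_imputation(self):
        ref = make_ref("ACGTACGTACGTACGTACGA", "ACGTACGTACGTACGTACGC")
        aln = alignment_table([(f"r{i}", "m0", 0, 20) for i in range(4)])
        counts = mirna_counts_cpm(aln, ref)
        strat = terminal_nt_stratification(counts, ref)
        assert strat.loc["m0", "group"] == "purine"
        assert strat.loc["m1", "group"] == "pyrimidine"
        assert bool(strat.loc["m1", "zero_imputed"]) is True
        assert strat.loc["m1", "log2_cpm"] == pytest.approx(np.log2(0.5 * 1e6 / 4))

    def test_single_entry_distribution(self):
        ref = make_ref("ACGTACGTACGTACGTACGA")
        aln = alignment_table([("r0", "m0", 0, 20)])
        strat = terminal_nt_stratification(mirna_counts_cpm(aln, ref), ref)
        med = stratification_medians(strat)
        assert list(med.index) == ["purine"]


class TestMechanismClassifier:
    def test_purine_terminal_full_length_is_unambiguously_precise(self):
        assert classify_alignment_mechanism(0, "A", "T") == {"I_precise"}

    def test_pyrimidine_terminal_full_length_is_ambiguous(self):
        assert classify_alignment_mechanism(0, "T") == {
            "I_precise", "III_plus2_apparent_precise"
        }

    def test_one_nt_offset_on_purine(self):
        assert classify_alignment_mechanism(1, "G", "C") == {
            "II_overcapture", "IV_plus2_internal"
        }

    def test_pd_base_filters_overcapture(self):
        # +1 T cannot have paired a terminal G
        assert classify_alignment_mechanism(1, "G", "T") == {"IV_plus2_internal"}

    def test_two_nt_offset(self):
        assert classify_alignment_mechanism(2, "T", penultimate_nt="A") == {
            "V_plus1_penultimate"
        }

    def test_larger_offsets_are_other(self):
        assert classify_alignment_mechanism(3, "T") == {"OTHER"}


# Every printed adapter-dimer junction observation: (junction, +1 base,
# expected primer-duplex dependence, NTA dependence, Read1 detectability),
# with the number of independent clones observed.
NO_UMI_SCHEME = OligoScheme(umi_pattern="C")
UMI_SCHEME = OligoScheme(umi_pattern="NNNNNRC")
JUNCTION_TABLE = [
    # UMI-less adapter template
    (NO_UMI_SCHEME, "C|GAGATCGG", "C", False, True, True, 2),
    (NO_UMI_SCHEME, "T|GAGATCGG", "T", False, True, True, 1),
    (NO_UMI_SCHEME, "C|-AGATCGG", "C", False, True, True, 2),
    (NO_UMI_SCHEME, "T|-AGATCGG", "T", False, True, True, 13),
    (NO_UMI_SCHEME, "C|------GG", "C", True, False, False, 4),
    (NO_UMI_SCHEME, "T|------GG", "T", False, True, False, 1),
    (NO_UMI_SCHEME, "T|-------G", "T", False, True, False, 8),
    # UMI-encoding adapter template
    (UMI_SCHEME, "T|GTTTTCTAGATCGG", "T", False, True, True, 1),
    (UMI_SCHEME, "C|GCGGCCCAGATCGG", "C", False, True, True, 1),
    (UMI_SCHEME, "T|--AGCTTAGATCGG", "T", True, True, True, 1),
    (UMI_SCHEME, "T|--AACTTAGATCGG", "T", True, True, True, 1),
    (UMI_SCHEME, "C|--GGCTAAGATCGG", "C", True, True, True, 1),
    (UMI_SCHEME, "T|--GGGCTAGATCGG", "T", True, True, True, 1),
    (UMI_SCHEME, "C|--GGTACAGATCGG", "C", True, True, True, 1),
    (UMI_SCHEME, "T|--GTCATAGATCGG", "T", True, True, True, 1),
    (UMI_SCHEME, "T|--GCGTAAGATCGG", "T", True, True, True, 1),
    (UMI_SCHEME, "T|--GAGAAAGATCGG", "T", True, True, True, 1),
    (UMI_SCHEME, "T|--GGGTTAGATCGG", "T", True, True, True, 1),
    (UMI_SCHEME, "T|---GGTTAGATCGG", "T", True, True, True, 1),
]


class TestJunctionClassifier:
    @pytest.mark.parametrize(
        "scheme,junction,pd_base,pd_dep,nta_dep,detectable,_n", JUNCTION_TABLE
    )
    def test_reproduces_observed_junctions(
        self, scheme, junction, pd_base, pd_dep, nta_dep, detectable, _n
    ):
        call = classify_junction(junction, pd_base, scheme)
        assert call.pd_dependent is pd_dep
        assert call.nta_dependent is nta_dep
        assert call.read1_detectable is detectable

    def test_offset_and_pairing_position(self):
        call = classify_junction("C|------GG", "C", NO_UMI_SCHEME)
        assert call.offset == 6
        assert call.first_base_paired_position == -6
        assert call.first_cdna_base == "G"

    def test_unicode_hyphen_variants_accepted(self):
        call = classify_junction("C|‐‐‐‐‐‐GG", "C",
                                 NO_UMI_SCHEME)
        assert call.offset == 6 and call.pd_dependent

    def test_unparseable_junction_errors(self):
        with pytest.raises(ValueError):
            classify_junction("GAGATCGG", "C", NO_UMI_SCHEME)
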