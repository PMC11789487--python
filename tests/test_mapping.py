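"""Ungapped aligner correctness and cascade classification contracts."""

import numpy as np
import pandas as pd
import pytest

from ottr_endqc.mapping import (
    Cascade,
    CascadeConfig,
    WindowIndex,
    align_ungapped,
    cascade_classify,
    read_bed,
    write_bed,
)
from ottr_endqc.references import (
    MiRNAEntry,
    MiRNAReference,
    revcomp,
)
from ottr_endqc.simulate import CaptureModel, simulate_library
from ottr_endqc.trimming import TrimScheme, run_trim_pipeline


def brute_force_align(read, references, max_mismatches, both_strands=False):
    """Exhaustive sliding-window mismatch scan (the independent oracle)."""
    best = max_mismatches + 1
    hits = []
    queries = [("+", read)]
    if both_strands:
        queries.append(("-", revcomp(read)))
    for strand, q in queries:
        for ref_id, seq in references.items():
            for s in range(len(seq) - len(q) + 1):
                mm = sum(a != b for a, b in zip(q, seq[s : s + len(q)]))
                if mm < best:
                    best, hits = mm, [(ref_id, s, s + len(q), strand, mm)]
                elif mm == best and mm <= max_mismatches:
                    hits.append((ref_id, s, s + len(q), strand, mm))
    return {h for h in hits if h[4] <= max_mismatches}


def as_tuples(placements):
    return {(p.reference_id, p.start, p.end, p.strand, p.mismatches)
            for p in placements}


class TestAlignUngapped:
    REFS = {
        "r1": "ACGTACGTAAGGCCTTACGGATCCAAGGTTCCAACCGGTTAA",
        "r2": "TTGACCTGATTGACCAGTTGACCTGATTGACCAGCCGGAATT",
    }

    def test_unique_exact_substring(self):
        hits = align_ungapped("AAGGCCTTACGGATCC", self.REFS, 2)
        assert as_tuples(hits) == {("r1", 8, 24, "+", 0)}

    def test_repeated_substring_reports_both(self):
        hits = align_ungapped("TTGACCTGATTGACCAG", self.REFS, 2)
        assert as_tuples(hits) == {("r2", 0, 17, "+", 0), ("r2", 17, 34, "+", 0)}

    def test_single_substitution_found(self):
        read = "AAGGCCTTACGGATCC"
        mutated = read[:5] + "A" + read[6:]
        hits = align_ungapped(mutated, self.REFS, 2)
        assert as_tuples(hits) == brute_force_align(mutated, self.REFS, 2)
        assert hits[0].mismatches == 1

    def test_beyond_tolerance_unplaced(self):
        assert align_ungapped("T" * 16, self.REFS, 2) == []

    @pytest.mark.parametrize("both_strands", [False, True])
    def test_matches_brute_force_on_random_reads(self, both_strands):
        rng = np.random.default_rng(42)
        refs = {
            "a": "".join("ACGT"[i] for i in rng.integers(0, 4, 300)),
            "b": "".join("ACGT"[i] for i in rng.integers(0, 4, 200)),
        }
        for _ in range(120):
            src = refs["a" if rng.random() < 0.6 else "b"]
            L = int(rng.integers(15, 31))
            s = int(rng.integers(0, len(src) - L + 1))
            read = list(src[s : s + L])
            for j in rng.choice(L, size=rng.integers(0, 4), replace=False):
                read[j] = "ACGT"[rng.integers(4)]
            read = "".join(read)
            if both_strands and rng.random() < 0.5:
                read = revcomp(read)
            got = as_tuples(align_ungapped(read, refs, 2, both_strands))
            assert got == brute_force_align(read, refs, 2, both_strands)

    def test_seeded_and_exhaustive_paths_agree(self):
        rng = np.random.default_rng(3)
        refs = {"g": "".join("ACGT"[i] for i in rng.integers(0, 4, 2000))}
        seeded = WindowIndex(refs, both_strands=True)
        full = WindowIndex(refs, both_strands=True)
        full.SEED_THRESHOLD = 10**12  # force the window-matrix scan
        for _ in range(60):
            L = int(rng.integers(16, 40))
            s = int(rng.integers(0, 2000 - L))
            read = list(refs["g"][s : s + L])
            for j in rng.choice(L, size=rng.integers(0, 3), replace=False):
                read[j] = "ACGT"[rng.integers(4)]
            read = "".join(read)
            assert as_tuples(seeded.align(read, 2)) == as_tuples(full.align(read, 2))


class TestCascade:
    def test_adapter_priority_over_mirna(self, small_contaminants, scheme):
        # a pool entry identical to an adapter fragment must classify as adapter
        fragment = scheme.read2_adapter[:20]
        pool = MiRNAReference(
            [MiRNAEntry("decoy", fragment), MiRNAEntry("real", "ACGTACGTACGTACGTACGT")]
        )
        rec = cascade_classify([("r1", fragment)], pool, small_contaminants)
        assert rec.loc[0, "category"] == "adapter"

    def test_simulated_contaminants_fully_recalled(
        self, small_pool, small_contaminants, mapping_config=None
    ):
        model = CaptureModel(p_label=1.0, contaminant_molar_load=30.0,
                             dimer_rate=0.0)
        lib = simulate_library(small_pool, small_contaminants, model, 30, 3000, 17)
        trimmed, _ = run_trim_pipeline(
            ((r.read_id, r.raw_sequence, r.raw_qualities) for r in lib.reads),
            TrimScheme(),
        )
        rec = cascade_classify(
            [(t.read_id, t.insert_sequence) for t in trimmed],
            small_pool, small_contaminants,
        ).set_index("read_id")
        truth = lib.truth.set_index("read_id")
        expected_by_mech = {
            "CONTAMINANT_expression_plasmid": "plasmid",
            "CONTAMINANT_genome": "genome",
            "I_precise": "mirna",
        }
        n_checked = 0
        for rid, row in rec.iterrows():
            mech = truth.loc[rid, "mechanism"]
            assert row["category"] == expected_by_mech[mech]
            n_checked += 1
        assert n_checked == len(trimmed) > 2000

    def test_genome_subcategories_follow_annotation(self, small_pool,
                                                    small_contaminants):
        genome = small_contaminants.category("genome")["genome"]
        reads = []
        for iv in small_contaminants.annotations:
            reads.append((f"{iv.feature}:{iv.start}", genome[iv.start : iv.start + 20]))
        reads.append(("other:0", genome[0:20]))
        rec = cascade_classify(reads, small_pool, small_contaminants)
        for row in rec.itertuples():
            assert row.category == "genome"
            assert row.subcategory == row.read_id.split(":")[0]

    def test_short_reads_excluded(self, small_pool, small_contaminants):
        cfg = CascadeConfig(min_alignment_length=17)
        rec = cascade_classify(
            [("short", "ACGTACGTACGTACGT")], small_pool, small_contaminants, cfg
        )
        assert rec.loc[0, "category"] == "too_short"

    def test_every_read_in_exactly_one_category(self, small_pool,
                                                small_contaminants):
        model = CaptureModel(contaminant_molar_load=5.0)
        lib = simulate_library(small_pool, small_contaminants, model, 50, 1500, 19)
        trimmed, _ = run_trim_pipeline(
            ((r.read_id, r.raw_sequence, r.raw_qualities) for r in lib.reads),
            TrimScheme(),
        )
        rec = cascade_classify(
            [(t.read_id, t.insert_sequence) for t in trimmed],
            small_pool, small_contaminants,
        )
        assert len(rec) == len(trimmed)
        assert rec["read_id"].is_unique
        assert rec["category"].value_counts().sum() == len(trimmed)

    def test_missing_stage_reference_is_config_error(self, small_pool):
        with pytest.raises(ValueError, match="stage"):
            Cascade(small_pool, None, stages=("adapter", "mirna"))

    def test_within_stage_order_invariance(self):
        seqs = {"m1": "ACGTACGTACGTACGTACGTAC", "m2": "TTGGCCAATTGGCCAATTGGCA"}
        fwd = MiRNAReference([MiRNAEntry(k, v) for k, v in seqs.items()])
        rev = MiRNAReference([MiRNAEntry(k, v) for k, v in reversed(seqs.items())])
        read = seqs["m1"][:18]
        a = cascade_classify([("r", read)], fwd, None, stages=("mirna",))
        b = cascade_classify([("r", read)], rev, None, stages=("mirna",))
        assert a.loc[0, "category"] == b.loc[0, "category"] == "mirna"
        assert a.loc[0, "multi_mapping"] == b.loc[0, "multi_mapping"]


class TestBed:
    def test_bed6_convention(self, tmp_path):
        rec = pd.DataFrame(
            [
                {"read_id": "read1", "category": "mirna", "subcategory": None,
                 "reference_id": "ref", "start": 0, "end": 21, "strand": "+",
                 "mismatches": 0, "multi_mapping": False, "read_length": 21},
                {"read_id": "read2", "category": "genome", "subcategory": "other",
                 "reference_id": "genome", "start": 100, "end": 125, "strand": "-",
                 "mismatches": 1, "multi_mapping": False, "read_length": 25},
            ]
        )
        path = tmp_path / "out.bed"
        write_bed(rec, path)
        lines = path.read_text().splitlines()
        assert lines[0] == "ref\t0\t21\tread1\t0\t+"
        again = read_bed(path)
        assert list(again["start"]) == [0, 100]
        assert list(again["strand"]) == ["+", "-"]
        assert (again["start"] < again["end"]).all()

    def test_unmapped_records_omitted(self, tmp_path):
        rec = pd.DataFrame(
            [{"read_id": "r", "category": "unmapped", "subcategory": None,
              "reference_id": None, "start": None, "end": None, "strand": None,
              "mismatches": None, "multi_mapping": False, "read_length": 20}]
        )
        path = tmp_path / "out.bed"
        write_bed(rec, path)
        assert path.read_text() == ""
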