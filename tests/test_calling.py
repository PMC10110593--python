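"""UMI extraction, consensus, barcode annotation, matrix building/filtering."""

import numpy as np
import pandas as pd
import pytest

from dragtrace.calling import (
    BarcodeCall,
    CallRejection,
    ReadLayout,
    build_matrix,
    call_barcode,
    consensus_by_umi,
    extract_umi,
    filter_matrix,
    normalize_and_transform,
    replicate_concordance,
)
from dragtrace.matrix import BarcodeCountMatrix
from dragtrace.model import Bounds
from dragtrace.recombination import (
    RecombinationScenario,
    enumerate_scenarios,
    realize_scenario,
)

LAYOUT = ReadLayout(umi_length=8, anchor="GAGGGTATCTTA", anchor_max_mismatch=1)


class TestExtractUmi:
    def test_umi_and_insert_split(self):
        read = "A" * 8 + LAYOUT.anchor + "ACGTACGT"
        res = extract_umi(read, LAYOUT)
        assert res.ok and res.umi == "A" * 8 and res.insert == "ACGTACGT"

    def test_anchor_mismatch_beyond_tolerance_rejected(self):
        bad_anchor = "TT" + LAYOUT.anchor[2:]
        res = extract_umi("A" * 8 + bad_anchor + "ACGT", LAYOUT)
        assert not res.ok and res.reason == "anchor_mismatch"

    def test_single_mismatch_tolerated(self):
        anchor1 = "T" + LAYOUT.anchor[1:]
        assert extract_umi("A" * 8 + anchor1 + "ACGT", LAYOUT).ok

    def test_short_read_rejected(self):
        res = extract_umi("ACGTACG", ReadLayout(umi_length=8, anchor="AC"))
        assert not res.ok and res.reason == "too_short"


class TestConsensus:
    def test_identical_reads_give_consensus_with_full_support(self):
        out, qc = consensus_by_umi({"U": ["ACGT"] * 3}, min_reads=2)
        assert out["U"] == ("ACGT", 3) and qc["accepted"] == 1

    def test_low_support_group_dropped(self):
        out, qc = consensus_by_umi({"U": ["ACGT"]}, min_reads=2)
        assert out == {} and qc["low_support"] == 1

    def test_positional_tie_discards_group(self):
        out, qc = consensus_by_umi({"U": ["ACGT", "AGGT"]}, min_reads=2)
        assert out == {} and qc["tie_discarded"] == 1

    def test_majority_overrides_single_error(self):
        out, _ = consensus_by_umi({"U": ["ACGT", "ACGT", "AAGT"]}, min_reads=2)
        assert out["U"][0] == "ACGT"


class TestCallBarcode:
    def test_germline_concatenation_gets_all_zero_annotation(self, full_ref, full_model):
        call = call_barcode(full_ref.germline_barcode(), full_ref, full_model.bounds)
        assert isinstance(call, BarcodeCall)
        assert (call.del_v, call.del_d5, call.del_d3, call.del_j) == (0, 0, 0, 0)
        assert call.n_ins_vd == call.n_ins_dj == 0 and not call.inverted

    def test_missing_v_anchor_rejected(self, full_ref, full_model):
        seq = "T" * 40 + full_ref.j_seq
        call = call_barcode(seq, full_ref, full_model.bounds)
        assert isinstance(call, CallRejection) and call.reason == "v_anchor"

    def test_ambiguous_base_rejected(self, full_ref, full_model):
        seq = full_ref.germline_barcode()[:-1] + "N"
        call = call_barcode(seq, full_ref, full_model.bounds)
        assert isinstance(call, CallRejection) and call.reason == "ambiguous_base"

    def test_parsimony_matches_enumerate_and_minimize_oracle(self, full_ref, full_model, rng):
        # ambiguous junctions: the reported annotation must equal the optimum of
        # (max germline retention, then fewest insertions, then lexicographic)
        # over the exhaustively enumerated scenario set
        from dragtrace.recombination import sample_recombinations

        bounds = full_model.bounds
        _, seqs = sample_recombinations(full_model, full_ref, 25, rng)
        for seq in seqs:
            call = call_barcode(seq, full_ref, bounds)
            assert isinstance(call, BarcodeCall)
            scenarios = enumerate_scenarios(full_ref, seq, bounds)
            best = min(scenarios, key=lambda sc: (sc.total_deletions, sc.total_insertions, sc))
            got = RecombinationScenario(
                call.inverted, call.del_v, call.del_d5, call.del_d3, call.del_j, "", ""
            )
            assert (got.inverted, got.del_v, got.del_d5, got.del_d3, got.del_j) == (
                best.inverted, best.del_v, best.del_d5, best.del_d3, best.del_j
            )
            assert (call.n_ins_vd, call.n_ins_dj) == (len(best.ins_vd), len(best.ins_dj))

    def test_inserted_base_coinciding_with_germline_prefers_fewer_insertions(self):
        from dragtrace.reference import CassetteReference

        ref = CassetteReference(v_seq="ACGTA", d_seq="AGT", j_seq="GCAAT", left_const="A", right_const="T")
        bounds = Bounds(max_del_v=2, max_del_d5=1, max_del_d3=2, max_del_j=2, max_ins=2)
        # 'A' inserted after full V equals germline V end after del_v=1 + ins 'AA'
        seq = realize_scenario(ref, RecombinationScenario(False, 0, 0, 0, 0, "A", ""))
        call = call_barcode(seq, ref, bounds)
        scenarios = enumerate_scenarios(ref, seq, bounds)
        best = min(scenarios, key=lambda sc: (sc.total_deletions, sc.total_insertions, sc))
        assert call.n_ins_vd == len(best.ins_vd)


def _toy_matrix():
    counts = pd.DataFrame(
        {
            "s1_R1": [5, 1, 0, 4],
            "s1_R2": [6, 0, 3, 4],
        },
        index=pd.Index(["b1", "b2", "b3", "b4"], name="barcode"),
    )
    samples = pd.DataFrame(
        {
            "mouse": ["m1", "m1"],
            "compartment": ["M", "M"],
            "timepoint_months": [15.0, 15.0],
            "replicate": [1, 2],
            "sorted_cells": [2000, 2000],
            "gfp_fraction": [0.5, 0.5],
        },
        index=pd.Index(["s1_R1", "s1_R2"], name="sample_id"),
    )
    return BarcodeCountMatrix(counts, samples)


class TestMatrixOps:
    def test_build_matrix_counts_umis(self):
        calls = {
            "s1": [BarcodeCall("AAA", False, 0, 0, 0, 0, 0, 0)] * 5,
            "s2": [],
        }
        samples = pd.DataFrame(
            {"mouse": ["m1", "m1"], "compartment": ["M", "M"], "timepoint_months": [1, 1],
             "replicate": [1, 2], "sorted_cells": [10, 10], "gfp_fraction": [1, 1]},
            index=pd.Index(["s1", "s2"], name="sample_id"),
        )
        mat = build_matrix(calls, samples)
        assert mat.counts.loc["AAA", "s1"] == 5 and mat.counts.loc["AAA", "s2"] == 0
        assert mat.counts.sum().sum() == sum(len(v) for v in calls.values())

    def test_filter_requires_min_umis_in_both_replicates(self):
        filt, report = filter_matrix(_toy_matrix(), min_umis=3, require_both_replicates=True)
        # b1 (5,6) and b4 (4,4) survive; b2 absent in R2; b3 absent in R1
        assert set(filt.barcodes) == {"b1", "b4"}
        assert filt.counts.loc["b1"].iloc[0] == 11  # replicates summed
        assert report["dropped_entries"] == 2

    def test_min_umis_threshold_drops_weak_entries(self):
        counts = pd.DataFrame({"s1_R1": [1], "s1_R2": [5]}, index=pd.Index(["b"], name="barcode"))
        samples = _toy_matrix().samples
        filt, _ = filter_matrix(BarcodeCountMatrix(counts, samples), min_umis=2)
        assert filt.n_barcodes == 0

    def test_normalize_and_transform_closed_forms(self):
        filt, _ = filter_matrix(_toy_matrix(), min_umis=1)
        frac, tr = normalize_and_transform(filt)
        assert np.allclose(frac.sum(axis=0), 1.0)
        one = pd.DataFrame({"s": [7]}, index=pd.Index(["b"], name="barcode"))
        samples = pd.DataFrame(
            {"mouse": ["m"], "compartment": ["M"], "timepoint_months": [1], "replicate": [1],
             "sorted_cells": [1], "gfp_fraction": [1]}, index=pd.Index(["s"], name="sample_id"))
        frac1, tr1 = normalize_and_transform(BarcodeCountMatrix(one, samples))
        assert frac1.iloc[0, 0] == 1.0
        assert tr1.iloc[0, 0] == pytest.approx(np.log(1 + np.sqrt(2)))  # asinh(1)

    def test_all_zero_sample_errors_on_normalize(self):
        counts = pd.DataFrame({"s1_R1": [0], "s1_R2": [1]}, index=pd.Index(["b"], name="barcode"))
        mat = BarcodeCountMatrix(counts, _toy_matrix().samples)
        with pytest.raises(ValueError):
            normalize_and_transform(mat)

    def test_replicate_concordance_identical_and_disjoint(self):
        mat = _toy_matrix()
        ident = BarcodeCountMatrix(
            pd.DataFrame({"s1_R1": [3, 2], "s1_R2": [3, 2]}, index=pd.Index(["a", "b"], name="barcode")),
            mat.samples,
        )
        row = replicate_concordance(ident).iloc[0]
        assert row["overlap"] == 1.0 and row["correlation"] == pytest.approx(1.0)
        disjoint = BarcodeCountMatrix(
            pd.DataFrame({"s1_R1": [3, 0], "s1_R2": [0, 2]}, index=pd.Index(["a", "b"], name="barcode")),
            mat.samples,
        )
        assert replicate_concordance(disjoint).iloc[0]["overlap"] == 0.0

    def test_replicate_concordance_hand_computed(self):
        counts = pd.DataFrame(
            {"s1_R1": [4, 2, 0], "s1_R2": [4, 0, 2]},
            index=pd.Index(["a", "b", "c"], name="barcode"),
        )
        mat = BarcodeCountMatrix(counts, _toy_matrix().samples)
        row = replicate_concordance(mat).iloc[0]
        assert row["overlap"] == pytest.approx(1 / 3)
        fa = np.arcsinh(np.array([4 / 6, 2 / 6, 0.0]))
        fb = np.arcsinh(np.array([4 / 6, 0.0, 2 / 6]))
        expected_r = np.corrcoef(fa, fb)[0, 1]
        assert row["correlation"] == pytest.approx(expected_r, abs=1e-12)
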