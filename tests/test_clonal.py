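"""Fate classification, clone sizes, chao2 and diversity indices."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dragtrace.clonal import (
    chao2,
    chao2_from_counts,
    classify_fates,
    clone_sizes,
    diversity_profile,
    renyi_entropy,
    replicate_incidence,
    simpson_indices,
)
from dragtrace.matrix import BarcodeCountMatrix


def _mouse_matrix():
    counts = pd.DataFrame(
        {
            "HSPC_s": [3, 0, 0, 5],
            "MP_s": [4, 6, 0, 5],
            "M_s": [2, 8, 9, 0],
        },
        index=pd.Index(["b1", "b2", "b3", "b4"], name="barcode"),
    )
    samples = pd.DataFrame(
        {
            "mouse": ["m1"] * 3,
            "compartment": ["HSPC", "MP", "M"],
            "timepoint_months": [15.0] * 3,
            "replicate": ["pooled"] * 3,
            "sorted_cells": [1000, 2000, 4000],
            "gfp_fraction": [0.5] * 3,
        },
        index=pd.Index(["HSPC_s", "MP_s", "M_s"], name="sample_id"),
    )
    return BarcodeCountMatrix(counts, samples)


class TestFateClasses:
    def test_presence_pattern_maps_to_class(self):
        classes, summary = classify_fates(_mouse_matrix())
        assert classes["b1"] == "HSPC+MP+M"
        assert classes["b2"] == "MP+M"
        assert classes["b3"] == "M"
        assert classes["b4"] == "HSPC+MP"

    def test_compartment_contributions_sum_to_hundred(self):
        _, summary = classify_fates(_mouse_matrix())
        for comp in ("HSPC", "MP", "M"):
            assert summary[f"pct_{comp}_output"].sum() == pytest.approx(100.0, abs=1e-9)
        assert summary["pct_barcodes"].sum() == pytest.approx(100.0, abs=1e-9)

    def test_missing_compartment_raises(self):
        mat = _mouse_matrix().subset_samples(["HSPC_s", "MP_s"])
        with pytest.raises(ValueError):
            classify_fates(mat)

    def test_simulated_class_fractions_recover_truth(self, full_ref, full_model):
        from dragtrace.simulate import simulate_clone_population

        n = 600
        pop = simulate_clone_population(n, full_model, full_ref, np.random.default_rng(21))
        df = pop.to_frame()
        frac = (df["fate_class"] == "HSPC+MP+M").mean()
        p = 0.137
        half_ci = 1.96 * np.sqrt(p * (1 - p) / n)
        assert abs(frac - p) < half_ci


class TestCloneSizes:
    def test_fraction_times_sorted_cells(self):
        sizes = clone_sizes(_mouse_matrix())
        # b3 is 9/19 of the M sample of 4000 cells
        assert sizes.loc["b3", "M_s"] == pytest.approx(9 / 19 * 4000)
        assert np.allclose(sizes.sum(axis=0), [1000, 2000, 4000])

    def test_labeling_scale_up(self):
        plain = clone_sizes(_mouse_matrix())
        scaled = clone_sizes(_mouse_matrix(), scale_by_labeling=True)
        assert np.allclose(scaled, plain / 0.5)

    def test_missing_cell_count_errors(self):
        mat = _mouse_matrix()
        mat.samples.loc["M_s", "sorted_cells"] = np.nan
        with pytest.raises(ValueError):
            clone_sizes(mat)


class TestChao2:
    def test_no_singletons_estimate_equals_observed(self):
        inc = np.array([[1, 1]] * 5)
        assert chao2(inc).value == 5.0

    def test_hand_example_classic_form(self):
        # S_obs=5, Q1=2, Q2=1, m=2 -> 5 + (1/2)*4/2 = 6.0
        est = chao2_from_counts(5, 2, 1, 2, form="classic")
        assert est.value == pytest.approx(6.0, abs=1e-12)

    def test_incidence_table_route_agrees_with_counts_route(self):
        inc = np.array([[1, 1], [1, 1], [1, 1], [1, 0], [0, 1]])  # S=5, Q1=2, Q2=3
        assert chao2(inc).value == chao2_from_counts(5, 2, 3, 2).value

    def test_labeling_fraction_scales_estimate(self):
        est = chao2_from_counts(5, 2, 1, 2, labeling_fraction=0.5)
        assert est.value == pytest.approx(12.0) and est.labeling_corrected

    def test_bias_corrected_form_used_when_no_doubletons(self):
        inc = np.array([[1, 0], [0, 1], [1, 1, ]])
        inc = np.array([[1, 0], [0, 1]])
        est = chao2(inc)  # Q1=2, Q2=0 -> bias-corrected: 2 + (1/2)*2*1/2 = 2.5
        assert est.value == pytest.approx(2.5)

    def test_estimate_never_below_observed_richness(self, rng):
        for _ in range(50):
            inc = rng.integers(0, 2, size=(rng.integers(2, 30), rng.integers(2, 5)))
            if not inc.any():
                continue
            s_obs = int((inc.sum(axis=1) > 0).sum())
            assert chao2(inc).value >= s_obs - 1e-12

    def test_single_unit_errors(self):
        with pytest.raises(ValueError):
            chao2(np.array([[1], [1]]))

    def test_coverage_of_true_richness_on_subsampled_population(self, rng):
        # chao2 over duplicate low-capture draws covers true richness often
        true_s = 300
        hits = 0
        n_sim = 200
        for _ in range(n_sim):
            inc = rng.random((true_s, 2)) < 0.35
            est = chao2(inc.astype(int)).value
            if est >= true_s * 0.7:
                hits += 1
        assert hits / n_sim >= 0.8

    def test_replicate_incidence_table(self):
        mat = _mouse_matrix()
        counts = pd.DataFrame(
            {"r1": [2, 0, 1], "r2": [1, 3, 0]}, index=pd.Index(["a", "b", "c"], name="barcode")
        )
        samples = pd.DataFrame(
            {"mouse": ["m1", "m1"], "compartment": ["M", "M"], "timepoint_months": [15.0, 15.0],
             "replicate": [1, 2], "sorted_cells": [1, 1], "gfp_fraction": [1, 1]},
            index=pd.Index(["r1", "r2"], name="sample_id"),
        )
        inc = replicate_incidence(BarcodeCountMatrix(counts, samples), "m1", "M")
        assert inc.to_numpy().tolist() == [[1, 1], [0, 1], [1, 0]]


class TestDiversity:
    def test_uniform_distribution_gives_log_k_for_all_q(self):
        k = 17
        p = np.full(k, 1 / k)
        for q in (0.0, 0.5, 1.0, 2.0, 5.0, np.inf):
            assert renyi_entropy(p, q) == pytest.approx(np.log(k), abs=1e-12)

    def test_single_clone_zero_entropy_full_concentration(self):
        p = np.array([1.0])
        assert renyi_entropy(p, 2.0) == 0.0
        assert simpson_indices(p)["simpson_concentration"] == 1.0

    def test_hand_computed_simpson_values(self):
        p = np.array([0.5, 0.3, 0.2])
        lam = 0.25 + 0.09 + 0.04
        out = simpson_indices(p)
        assert out["simpson_concentration"] == pytest.approx(lam, abs=1e-15)
        assert out["inverse_simpson"] == pytest.approx(1 / lam, abs=1e-12)
        assert renyi_entropy(p, 2.0) == pytest.approx(-np.log(lam), abs=1e-12)

    @settings(max_examples=150, derandomize=True)
    @given(
        st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=1, max_size=40),
    )
    def test_renyi_profile_non_increasing_in_q_and_simpson_identity(self, raw):
        p = np.array(raw)
        p = p / p.sum()
        qs = [0.0, 0.5, 1.0, 2.0, 4.0, 8.0]
        h = [renyi_entropy(p, q) for q in qs]
        assert all(a >= b - 1e-9 for a, b in zip(h, h[1:]))
        lam = simpson_indices(p)["simpson_concentration"]
        assert np.exp(renyi_entropy(p, 2.0)) * lam == pytest.approx(1.0, abs=1e-12)

    def test_profile_table_shapes_and_warning_on_unnormalized(self):
        with pytest.warns(UserWarning):
            prof = diversity_profile([2.0, 1.0, 1.0])
        rich = prof.loc[prof["index"] == "richness", "value"].iloc[0]
        assert rich == 3
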