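"""Synthetic clone populations, read simulation and diversity time courses."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dragtrace.calling import ReadLayout
from dragtrace.simulate import (
    COMPARTMENTS,
    BreakpointDynamics,
    SampleSpec,
    simulate_clone_population,
    simulate_diversity_observations,
    simulate_reads,
    simulate_timecourse,
    write_fastq,
)


class TestClonePopulation:
    def test_empty_population_is_valid(self, full_ref, full_model, rng):
        pop = simulate_clone_population(0, full_model, full_ref, rng)
        assert pop.clones == [] and pop.to_frame().empty

    def test_pure_hspc_class_means_no_mp_or_m_cells(self, full_ref, full_model, rng):
        props = {"HSPC": 1.0}
        pop = simulate_clone_population(50, full_model, full_ref, rng, class_proportions=props)
        df = pop.to_frame()
        assert (df["MP"] == 0).all() and (df["M"] == 0).all() and (df["HSPC"] > 0).all()

    def test_default_triple_class_proportion_matches_observed_sharing(self, full_ref, full_model):
        from dragtrace.simulate import DEFAULT_CLASS_PROPORTIONS

        assert DEFAULT_CLASS_PROPORTIONS["HSPC+MP+M"] == pytest.approx(0.137)
        assert sum(DEFAULT_CLASS_PROPORTIONS.values()) == pytest.approx(1.0)
        # the HSPC+M class (skipping MP) is never generated, as observed
        assert DEFAULT_CLASS_PROPORTIONS["HSPC+M"] == 0.0

    def test_cells_zero_exactly_outside_fate_class(self, full_ref, full_model, rng):
        pop = simulate_clone_population(80, full_model, full_ref, rng)
        for clone in pop.clones:
            members = set(clone.fate_class.split("+"))
            for comp in COMPARTMENTS:
                assert (clone.cells.get(comp, 0) > 0) == (comp in members)

    def test_barcodes_unique_and_producible(self, full_ref, full_model, rng):
        from dragtrace.pgen import compute_pgen_many

        pop = simulate_clone_population(60, full_model, full_ref, rng)
        barcodes = [c.barcode for c in pop.clones]
        assert len(set(barcodes)) == len(barcodes)
        assert (compute_pgen_many(full_model, full_ref, barcodes) > 0).all()

    def test_default_m_sizes_span_hundred_to_ten_thousand(self, full_ref, full_model):
        pop = simulate_clone_population(
            400, full_model, full_ref, np.random.default_rng(0), class_proportions={"M": 1.0}
        )
        sizes = np.array([c.cells["M"] for c in pop.clones])
        assert np.quantile(sizes, 0.05) < 200 and np.quantile(sizes, 0.95) > 5000


class TestReads:
    def _pop(self, full_ref, full_model, seed=0, n=60):
        return simulate_clone_population(
            n, full_model, full_ref, np.random.default_rng(seed), labeling_efficiency=1.0
        )

    def test_truth_table_read_sums_match_emitted_records(self, full_ref, full_model):
        pop = self._pop(full_ref, full_model)
        spec = SampleSpec("s", "m1", "M", 15.0, cells_sampled=2000)
        reads, truth = simulate_reads(pop, spec, ReadLayout(), np.random.default_rng(1))
        per_rep = truth.groupby("sample_id")["reads"].sum().to_dict()
        assert {k: len(v) for k, v in reads.items()} == per_rep

    def test_zero_error_reads_carry_exact_barcode(self, full_ref, full_model):
        pop = self._pop(full_ref, full_model, n=10)
        spec = SampleSpec("s", "m1", "M", 15.0, cells_sampled=200, seq_error_rate=0.0)
        layout = ReadLayout()
        reads, truth = simulate_reads(pop, spec, layout, np.random.default_rng(2))
        barcodes = set(truth["barcode"])
        for recs in reads.values():
            for _, seq in recs:
                assert seq[layout.barcode_start :] in barcodes
                assert seq[layout.umi_length : layout.barcode_start] == layout.anchor

    def test_zero_cell_clone_emits_no_reads(self, full_ref, full_model):
        pop = self._pop(full_ref, full_model)
        spec = SampleSpec("s", "m1", "M", 15.0, cells_sampled=50)
        _, truth = simulate_reads(pop, spec, ReadLayout(), np.random.default_rng(3))
        sampled_total = truth.groupby("clone_id")["cells"].sum()
        assert (sampled_total > 0).all()  # only sampled clones appear in the truth table

    def test_oversampling_raises(self, full_ref, full_model):
        pop = self._pop(full_ref, full_model, n=5)
        total = sum(c.cells["M"] for c in pop.clones if c.cells.get("M"))
        spec = SampleSpec("s", "m1", "M", 15.0, cells_sampled=total + 1)
        with pytest.raises(ValueError):
            simulate_reads(pop, spec, ReadLayout(), np.random.default_rng(0))

    def test_umi_counts_track_sampled_cells(self, full_ref, full_model):
        pop = simulate_clone_population(
            200, full_model, full_ref, np.random.default_rng(5), labeling_efficiency=1.0
        )
        spec = SampleSpec("s", "m1", "M", 15.0, cells_sampled=10_000, pcr_replicates=1)
        _, truth = simulate_reads(pop, spec, ReadLayout(), np.random.default_rng(6))
        rho = stats.spearmanr(truth["cells"], truth["umis"])[0]
        assert rho > 0.99

    def test_identical_seed_reproduces_fastq_bytes(self, full_ref, full_model, tmp_path):
        pop = self._pop(full_ref, full_model, n=15)
        spec = SampleSpec("s", "m1", "M", 15.0, cells_sampled=300)
        out = []
        for run in range(2):
            reads, _ = simulate_reads(pop, spec, ReadLayout(), np.random.default_rng(9))
            path = tmp_path / f"run{run}.fastq"
            write_fastq(reads["s_R1"], path)
            out.append(path.read_bytes())
        assert out[0] == out[1]


class TestTimecourse:
    def test_flat_dynamics_give_constant_expected_diversity(self):
        dyn = BreakpointDynamics(slope_before=0.0, slope_change=0.0, mouse_sd=0.0)
        mu = dyn.mean(np.arange(4, 13))
        assert np.allclose(mu, mu[0])

    def test_full_capture_no_noise_recovers_active_clone_count(self, full_ref, full_model):
        dyn = BreakpointDynamics(mouse_sd=0.0)
        mat, truth = simulate_timecourse(
            dyn, 2, [4, 7, 10], full_model, full_ref, np.random.default_rng(0), capture=1.0, replicates=1
        )
        for _, row in truth.iterrows():
            sid = f"{row['mouse']}|blood-M|t{row['t']}|R1"
            assert int((mat.counts[sid] > 0).sum()) == row["n_active"]

    def test_default_dynamics_dip_near_month_seven(self):
        dyn = BreakpointDynamics()
        rng = np.random.default_rng(12)
        obs = simulate_diversity_observations(dyn, 100, np.arange(4, 13), 1, rng)
        means = obs.groupby("t")["y"].mean()
        t_min = means.idxmin()
        assert 6.0 <= t_min <= 8.0
        assert means.loc[12.0] > means.loc[7.0] and means.loc[4.0] > means.loc[7.0]

    def test_blood_capture_gap_reproduces_replicate_overlap_contrast(self, full_ref, full_model):
        # low-capture blood duplicates overlap far less than deep marrow duplicates
        from dragtrace.calling import replicate_concordance
        from dragtrace.matrix import BarcodeCountMatrix

        dyn = BreakpointDynamics(mouse_sd=0.0)
        rng = np.random.default_rng(3)
        blood, _ = simulate_timecourse(dyn, 1, [6.0], full_model, full_ref, rng, capture=0.05)
        deep, _ = simulate_timecourse(dyn, 1, [6.0], full_model, full_ref, rng, capture=0.9)
        ov_blood = replicate_concordance(blood)["overlap"].mean()
        ov_deep = replicate_concordance(deep)["overlap"].mean()
        assert ov_blood < 0.25 < 0.5 < ov_deep
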