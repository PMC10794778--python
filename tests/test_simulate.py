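"""The synthetic WGBS generator: determinism and model contracts."""

import numpy as np
import pandas as pd
import pytest

from methylandscape import simulate as sim
from methylandscape.binning import enumerate_cpgs


class TestSimulateGenome:
    def test_seed_determinism_bit_identical(self):
        config = sim.SimulationConfig(seed=5, n_chromosomes=2, chrom_length=1_000_000,
                                      bin_width=100_000, emit_sequence=True)
        a, b = sim.simulate_genome(config), sim.simulate_genome(config)
        assert a.sequences == b.sequences
        pd.testing.assert_frame_equal(a.bins, b.bins)
        for chrom in a.cpg_positions:
            np.testing.assert_array_equal(a.cpg_positions[chrom], b.cpg_positions[chrom])

    def test_uniform_gc_target_realized_within_tolerance(self):
        config = sim.SimulationConfig(seed=1, n_chromosomes=1, chrom_length=1_000_000,
                                      bin_width=100_000, emit_sequence=True)
        truth = sim.simulate_genome(config, gc_profile=np.full(10, 0.5))
        assert truth.bins["gc_fraction"].between(0.48, 0.52).all()

    def test_gc_gradient_is_realized_in_order(self):
        config = sim.SimulationConfig(seed=2, n_chromosomes=1, chrom_length=2_000_000,
                                      bin_width=100_000, emit_sequence=True)
        grad = np.linspace(0.35, 0.55, 20)
        truth = sim.simulate_genome(config, gc_profile=grad)
        realized = truth.bins["gc_fraction"].to_numpy()
        assert (np.diff(realized) > -0.02).all()
        np.testing.assert_allclose(realized, grad, atol=0.02)

    def test_sequence_cpgs_match_enumeration(self):
        config = sim.SimulationConfig(seed=3, n_chromosomes=1, chrom_length=200_000,
                                      bin_width=50_000, emit_sequence=True)
        truth = sim.simulate_genome(config)
        np.testing.assert_array_equal(
            truth.cpg_positions["chr1"], enumerate_cpgs(truth.sequences, "chr1")
        )

    def test_cpg_density_scales_with_gc(self, desk_truth):
        bins = desk_truth.bins
        lo = bins.nsmallest(50, "gc_fraction")["cpg_count"].mean()
        hi = bins.nlargest(50, "gc_fraction")["cpg_count"].mean()
        assert hi > lo

    def test_invalid_density_rejected(self):
        with pytest.raises(ValueError):
            sim.simulate_genome(sim.SimulationConfig(mean_cpg_density=0.9))

    def test_fasta_roundtrip(self, tmp_path):
        config = sim.SimulationConfig(seed=4, n_chromosomes=1, chrom_length=10_000,
                                      bin_width=5_000, emit_sequence=True)
        truth = sim.simulate_genome(config)
        path = tmp_path / "g.fa"
        sim.write_fasta(truth, path)
        from pyfaidx import Fasta

        fa = Fasta(str(path), as_raw=True)
        assert str(fa["chr1"][:]) == truth.sequences["chr1"]

    def test_fasta_requires_sequence(self, desk_truth, tmp_path):
        with pytest.raises(ValueError):
            sim.write_fasta(desk_truth, tmp_path / "no.fa")


class TestSimulateMethylome:
    def test_seed_determinism(self, small_seq_truth):
        a, _ = sim.simulate_methylome(small_seq_truth, sim.CLASS_I, seed=9)
        b, _ = sim.simulate_methylome(small_seq_truth, sim.CLASS_I, seed=9)
        pd.testing.assert_frame_equal(a.sites, b.sites)

    def test_class_slope_sign_enforced(self):
        with pytest.raises(ValueError):
            sim.ClassModel("I", 0.8, +0.3)
        with pytest.raises(ValueError):
            sim.ClassModel("III", 0.5, -0.3)

    def test_class_i_at_rich_bins_more_methylated(self, desk_truth):
        _, mt = sim.simulate_methylome(desk_truth, sim.CLASS_I, seed=11)
        gc = desk_truth.bins["gc_fraction"].to_numpy()
        at_mean = mt.bin_means[gc <= np.median(gc)].mean()
        gc_mean = mt.bin_means[gc > np.median(gc)].mean()
        assert at_mean > gc_mean

    def test_injected_pmd_depresses_bin_levels(self, desk_truth):
        pmds = pd.DataFrame({"chrom": ["chr1"], "start": [1_000_000],
                             "end": [2_000_000], "level": [0.3]})
        meth, _ = sim.simulate_methylome(
            desk_truth, sim.ClassModel("I", 0.8, 0.0), seed=12,
            depth_model=sim.DepthModel(mean=30), pmd_intervals=pmds,
        )
        from methylandscape.io import bin_methylation

        bm = bin_methylation(meth, desk_truth.tile(100_000))
        inside = bm[(bm["chrom"] == "chr1") & (bm["start"] >= 1_000_000) & (bm["end"] <= 2_000_000)]
        assert (inside["level"] < 0.5).all()

    def test_realized_global_near_model_expectation(self, desk_truth):
        meth, mt = sim.simulate_methylome(desk_truth, sim.CLASS_II, seed=13)
        from methylandscape.io import global_methylation

        glob = global_methylation(meth, depth_min=1).level
        # expected global is the CpG-weighted mean of bin means
        w = desk_truth.bins["cpg_count"].to_numpy()
        expected = np.average(mt.bin_means, weights=w)
        assert glob == pytest.approx(expected, abs=0.01)


class TestSimulatePmdIntervals:
    def test_on_grid_and_non_overlapping(self, desk_truth):
        pmds = sim.simulate_pmd_intervals(desk_truth, seed=14)
        assert (pmds["start"] % 10_000 == 0).all() and (pmds["end"] % 10_000 == 0).all()
        lengths = pmds["end"] - pmds["start"]
        assert lengths.between(150_000, 2_000_000).all()
        for _, sub in pmds.groupby("chrom"):
            s = sub.sort_values("start")
            assert (s["start"].to_numpy()[1:] >= s["end"].to_numpy()[:-1]).all()

    def test_infeasible_request_errors(self, small_seq_truth):
        with pytest.raises(ValueError):
            sim.simulate_pmd_intervals(small_seq_truth, seed=1, n_domains=500)


class TestSimulateStagePair:
    def test_truth_construction_dr_mr_is_at_rich(self, desk_truth):
        _, _, truth = sim.simulate_stage_pair(desk_truth, seed=15)
        gc = desk_truth.bins["gc_fraction"].to_numpy()
        drmr = (truth.labels["true_demeth"] == "DR") & (truth.labels["true_meth"] == "MR")
        dsms = (truth.labels["true_demeth"] == "DS") & (truth.labels["true_meth"] == "MS")
        assert drmr.any() and dsms.any()
        assert gc[drmr.to_numpy()].mean() < gc[dsms.to_numpy()].mean()
        assert not truth.degenerate

    def test_zero_variance_latent_flagged_degenerate(self, desk_truth):
        _, _, truth = sim.simulate_stage_pair(
            desk_truth, seed=16, latent_noise_sd=0.0, hypo_span=0.0, remeth_span=0.0
        )
        assert truth.degenerate

    def test_seed_determinism(self, small_seq_truth):
        a = sim.simulate_stage_pair(small_seq_truth, seed=17)
        b = sim.simulate_stage_pair(small_seq_truth, seed=17)
        pd.testing.assert_frame_equal(a[0].sites, b[0].sites)
        pd.testing.assert_frame_equal(a[1].sites, b[1].sites)


class TestSimulateGametes:
    def test_seed_determinism_and_expected_mean(self, small_seq_truth):
        a_sp, a_oo, _ = sim.simulate_gametes(small_seq_truth, seed=18)
        b_sp, _, _ = sim.simulate_gametes(small_seq_truth, seed=18)
        pd.testing.assert_frame_equal(a_sp.sites, b_sp.sites)
        lv = a_sp.sites["meth"].sum() / a_sp.total_counts()
        assert lv == pytest.approx(0.85, abs=0.01)
        lv_o = a_oo.sites["meth"].sum() / a_oo.total_counts()
        assert lv_o == pytest.approx(0.40, abs=0.01)
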