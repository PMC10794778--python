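"""G/C groups, stage deltas, nine-group susceptibility, overlaps, ranks."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methylandscape import simulate as sim
from methylandscape.classify import rank_bins
from methylandscape.dynamics import (
    assign_gc_groups,
    classify_susceptibility,
    compare_chromosome_ranks,
    overlap_fraction,
    stage_delta,
)
from methylandscape.intervals import merge_intervals, union_coverage
from methylandscape.io import bin_methylation, filter_bins

from conftest import brute_force_rank_sum_p


def binmeth_frame(gc, levels, chrom=None, depth=1000, covered=50):
    n = len(gc)
    levels = np.asarray(levels, dtype=float)
    meth = np.round(levels * depth).astype(int)
    return pd.DataFrame(
        {
            "chrom": chrom if chrom is not None else ["c"] * n,
            "start": np.arange(n) * 500_000,
            "end": (np.arange(n) + 1) * 500_000,
            "gc_fraction": gc,
            "n_fraction": 0.0,
            "cpg_count": covered,
            "partial": False,
            "meth_sum": meth,
            "total_sum": depth,
            "covered_cpgs": covered,
            "level": meth / depth,
        }
    )


class TestAssignGcGroups:
    def test_equal_groups_with_divisibility_drop(self):
        rng = np.random.default_rng(0)
        bm = binmeth_frame(rng.uniform(0.3, 0.6, 25), rng.uniform(0, 1, 25))
        out = assign_gc_groups(bm, n_groups=12)
        counts = out["gc_group"].value_counts()
        assert (counts == 2).all() and len(counts) == 12
        assert out["gc_group"].isna().sum() == 1

    def test_group_boundaries_monotone_in_gc(self):
        rng = np.random.default_rng(1)
        bm = binmeth_frame(rng.uniform(0.3, 0.6, 48), rng.uniform(0, 1, 48))
        out = assign_gc_groups(bm, n_groups=12)
        by_group = out.dropna(subset=["gc_group"]).groupby("gc_group")["gc_fraction"]
        maxima, minima = by_group.max().to_numpy(), by_group.min().to_numpy()
        assert (maxima[:-1] <= minima[1:]).all()

    def test_order_invariance(self):
        rng = np.random.default_rng(2)
        bm = binmeth_frame(rng.uniform(0.3, 0.6, 36), rng.uniform(0, 1, 36))
        a = assign_gc_groups(bm, 12)["gc_group"]
        b = assign_gc_groups(bm.sample(frac=1, random_state=3), 12)["gc_group"].sort_index()
        assert a.equals(b)

    def test_mouse_like_group_size(self, landscape_truth):
        meth, _ = sim.simulate_methylome(landscape_truth, sim.CLASS_I, seed=1)
        bm, _ = filter_bins(bin_methylation(meth, landscape_truth.bins))
        out = assign_gc_groups(bm, 12)
        assert (out["gc_group"].value_counts() == 400).all()

    def test_too_few_bins(self):
        bm = binmeth_frame([0.4] * 5, [0.5] * 5)
        with pytest.raises(ValueError):
            assign_gc_groups(bm, 12)


class TestStageDelta:
    def test_identical_stages_zero_delta(self):
        rng = np.random.default_rng(4)
        bm = binmeth_frame(rng.uniform(0.3, 0.6, 24), rng.uniform(0.1, 0.9, 24))
        grouped = assign_gc_groups(bm, 12)
        table, _ = stage_delta(bm, bm, grouped)
        assert (table["delta"] == 0).all()

    def test_single_group_arithmetic(self):
        bm_a = binmeth_frame([0.4, 0.41], [0.8, 0.6], depth=10)
        bm_b = binmeth_frame([0.4, 0.41], [0.4, 0.5], depth=10)
        grouped = assign_gc_groups(bm_a, n_groups=1)
        table, _ = stage_delta(bm_a, bm_b, grouped)
        assert table.iloc[0]["mean_bin_delta"] == pytest.approx(-0.25)
        assert table.iloc[0]["delta"] == pytest.approx((0.9 - 1.4) / 2)

    def test_swapped_inputs_negate_deltas(self):
        rng = np.random.default_rng(5)
        bm_a = binmeth_frame(rng.uniform(0.3, 0.6, 24), rng.uniform(0.1, 0.9, 24))
        bm_b = binmeth_frame(bm_a["gc_fraction"], rng.uniform(0.1, 0.9, 24))
        grouped = assign_gc_groups(bm_a, 6)
        t_ab, _ = stage_delta(bm_a, bm_b, grouped)
        t_ba, _ = stage_delta(bm_b, bm_a, grouped)
        np.testing.assert_allclose(t_ab["delta"], -t_ba["delta"], atol=1e-15)

    def test_mismatched_bins_error(self):
        bm_a = binmeth_frame([0.4, 0.5], [0.5, 0.5])
        bm_b = bm_a.copy()
        bm_b["start"] = bm_b["start"] + 1
        with pytest.raises(ValueError, match="differ"):
            stage_delta(bm_a, bm_b, assign_gc_groups(bm_a, 1))

    def test_gc_coupled_loss_is_monotone_in_group(self, desk_truth):
        """A demethylation wave hitting G/C-rich bins harder shows group
        deltas whose magnitude grows along the G/C gradient."""
        m_hypo, m_remeth, _ = sim.simulate_stage_pair(desk_truth, seed=6, latent_noise_sd=0.0)
        bm_h, _ = filter_bins(bin_methylation(m_hypo, desk_truth.bins))
        bm_r, _ = filter_bins(bin_methylation(m_remeth, desk_truth.bins))
        grouped = assign_gc_groups(bm_r, 12)
        # remethylated -> hypomethylated: losses largest in G/C-rich groups
        table, test = stage_delta(bm_r, bm_h, grouped)
        deltas = table.sort_values("gc_group")["delta"].to_numpy()
        assert (np.diff(deltas) < 0).all() and deltas[-1] < deltas[0]
        assert test.p_value < 0.005


class TestClassifySusceptibility:
    def test_extreme_bin_is_dr_ms(self):
        rng = np.random.default_rng(7)
        gc = rng.uniform(0.3, 0.6, 9)
        hypo = np.array([0.9] + list(rng.uniform(0.1, 0.5, 8)))
        remeth = np.array([0.95] + list(rng.uniform(0.3, 0.8, 8)))
        labels, _ = classify_susceptibility(
            binmeth_frame(gc, hypo), binmeth_frame(gc, remeth), tertile_size=3
        )
        assert labels.iloc[0]["nine_group"] == "DR-MS"

    def test_tertile_margins_exact(self):
        rng = np.random.default_rng(8)
        n = 48
        gc = rng.uniform(0.3, 0.6, n)
        labels, summary = classify_susceptibility(
            binmeth_frame(gc, rng.uniform(0, 1, n)),
            binmeth_frame(gc, rng.uniform(0, 1, n)),
            tertile_size=16,
        )
        assert labels["demeth_class"].value_counts().tolist() == [16, 16, 16]
        assert labels["meth_class"].value_counts().tolist() == [16, 16, 16]
        assert summary["n"].sum() == 48
        tab = pd.crosstab(labels["demeth_class"], labels["meth_class"])
        assert (tab.sum(axis=0) == 16).all() and (tab.sum(axis=1) == 16).all()

    def test_size_mismatch_errors(self):
        rng = np.random.default_rng(9)
        gc = rng.uniform(0.3, 0.6, 10)
        with pytest.raises(ValueError, match="tertile_size"):
            classify_susceptibility(
                binmeth_frame(gc, rng.uniform(0, 1, 10)),
                binmeth_frame(gc, rng.uniform(0, 1, 10)),
                tertile_size=4,
            )

    def test_lamina_coupled_truth_gives_at_rich_dr_mr(self, desk_truth):
        m_hypo, m_remeth, truth = sim.simulate_stage_pair(desk_truth, seed=10)
        bm_h, _ = filter_bins(bin_methylation(m_hypo, desk_truth.bins))
        bm_r, _ = filter_bins(bin_methylation(m_remeth, desk_truth.bins))
        labels, summary = classify_susceptibility(bm_h, bm_r)
        gc_by_group = summary.set_index("nine_group")["gc_fraction"]
        assert gc_by_group.idxmin() == "DR-MR"


class TestCompareChromosomeRanks:
    def test_extreme_separation_matches_enumeration(self):
        bm = binmeth_frame(
            [0.4] * 7,
            [0.1, 0.2, 0.3, 0.6, 0.7, 0.8, 0.9],
            chrom=["c1"] * 3 + ["c2"] * 4,
        )
        ranks = rank_bins(bm)
        res = compare_chromosome_ranks(bm, ranks, "c2", "c1")
        x = ranks[bm["chrom"] == "c2"].to_numpy()
        y = ranks[bm["chrom"] == "c1"].to_numpy()
        assert res["p_value"] == pytest.approx(brute_force_rank_sum_p(x, y))
        assert res["median_rank_a"] > res["median_rank_b"]

    def test_same_chromosome_p_one(self):
        bm = binmeth_frame([0.4] * 4, [0.1, 0.2, 0.3, 0.4])
        ranks = rank_bins(bm)
        res = compare_chromosome_ranks(bm, ranks, "c", "c")
        assert res["p_value"] == 1.0

    def test_absent_chromosome_errors(self):
        bm = binmeth_frame([0.4] * 4, [0.1, 0.2, 0.3, 0.4])
        with pytest.raises(ValueError, match="chrZ"):
            compare_chromosome_ranks(bm, rank_bins(bm), "c", "chrZ")

    def test_gc_rich_chromosome_ranks_higher_under_class_iii(self):
        """A chromosome built G/C-rich gets higher methylation ranks when the
        landscape is inverted (Class III)."""
        config = sim.SimulationConfig(seed=30, n_chromosomes=2, chrom_length=30_000_000)
        hits = 0
        for seed in range(5):
            truth = sim.simulate_genome(
                sim.SimulationConfig(seed=seed, n_chromosomes=2, chrom_length=30_000_000)
            )
            # shift chr2's G/C upward to emulate a G/C-rich chromosome
            bins = truth.bins.copy()
            bins.loc[bins["chrom"] == "chr2", "gc_fraction"] += 0.06
            truth.bins = bins
            meth, _ = sim.simulate_methylome(truth, sim.CLASS_III, seed=50 + seed)
            bm, _ = filter_bins(bin_methylation(meth, truth.bins))
            ranks = rank_bins(bm)
            res = compare_chromosome_ranks(bm, ranks, "chr2", "chr1")
            hits += res["median_rank_a"] > res["median_rank_b"]
        assert hits == 5


class TestOverlapFraction:
    bins = pd.DataFrame({"chrom": ["c"], "start": [0], "end": [500_000]})

    def iv(self, *pairs, chrom="c"):
        return pd.DataFrame(
            {"chrom": chrom, "start": [p[0] for p in pairs], "end": [p[1] for p in pairs]}
        )

    def test_half_covered(self):
        out = overlap_fraction(self.bins, self.iv((0, 250_000)))
        assert out.iloc[0]["overlap_fraction"] == pytest.approx(0.5)
        assert not out.iloc[0]["overlap_gt_50"] and not out.iloc[0]["overlap_gt_70"]

    def test_union_not_sum(self):
        out = overlap_fraction(self.bins, self.iv((0, 100_000), (50_000, 200_000)))
        assert out.iloc[0]["overlap_fraction"] == pytest.approx(0.4)

    def test_no_intervals(self):
        out = overlap_fraction(self.bins, self.iv().iloc[0:0])
        assert out.iloc[0]["overlap_fraction"] == 0.0

    def test_threshold_flags(self):
        out = overlap_fraction(self.bins, self.iv((0, 495_001)))
        assert bool(out.iloc[0]["overlap_gt_98"])

    def test_interval_beyond_chromosome_end_clipped(self):
        out = overlap_fraction(self.bins, self.iv((400_000, 700_000)))
        assert out.iloc[0]["overlap_fraction"] == pytest.approx(0.2)

    @settings(max_examples=100, derandomize=True)
    @given(
        st.lists(st.tuples(st.integers(0, 195), st.integers(5, 200)), min_size=0, max_size=12),
        st.integers(10, 60),
    )
    def test_union_coverage_matches_bitmap_oracle(self, raw, width):
        pairs = [(a, a + b) for a, b in raw]
        iv = self.iv(*pairs) if pairs else self.iv().iloc[0:0]
        starts = np.arange(0, 200, width)
        bins = pd.DataFrame({"chrom": "c", "start": starts, "end": np.minimum(starts + width, 200)})
        got = union_coverage(bins, iv)
        bitmap = np.zeros(200, dtype=bool)
        for a, b in pairs:
            bitmap[a : min(b, 200)] = True
        expected = [bitmap[s:e].sum() for s, e in bins[["start", "end"]].to_numpy()]
        assert got.tolist() == expected


def test_merge_intervals_basic():
    s, e = merge_intervals(np.array([5, 0, 10]), np.array([8, 6, 12]))
    assert s.tolist() == [0, 10] and e.tolist() == [8, 12]
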