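import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from methylresponse.dmr import (
    Dmr,
    call_dmrs,
    per_cpg_stats,
    recover_planted,
    smooth_stats,
)
from methylresponse.preprocess import beta_to_m
from methylresponse.simulate import (
    SimulationConfig,
    generate_annotation,
    simulate_methylation,
)


def _stats_frame(small_world):
    beta = small_world["beta"]
    m = beta_to_m(beta)
    return per_cpg_stats(m, beta.values, small_world["config"].groups), beta


class TestPerCpgStats:
    def test_delta_beta_arithmetic(self):
        # responders all 0.9, non-responders all 0.1 at one CpG
        cols = [f"R{i}" for i in range(3)] + [f"N{i}" for i in range(4)]
        beta = pd.DataFrame(
            [[0.9] * 3 + [0.1] * 4, [0.5] * 7], index=["cgA", "cgB"], columns=cols
        )
        groups = pd.Series(["R"] * 3 + ["NR"] * 4, index=cols)
        m = beta_to_m(beta)
        out = per_cpg_stats(m, beta, groups)
        assert out.loc["cgA", "delta_beta"] == pytest.approx(0.8)
        assert out.loc["cgA", "var_floored"].item()  # zero within-group variance

    def test_bh_hand_computation(self):
        # BH on p = (0.01, 0.02, 0.03, 0.04) over 4 tests gives all 0.04
        fdr = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        assert np.allclose(fdr, 0.04)

    def test_null_world_fdr_near_one(self):
        # identical group distributions everywhere: nothing BH-significant
        # and the bulk of the fdr values sit at 1
        cfg = SimulationConfig(seed=21, n_cpgs=4000, n_genes=20, n_enhancers=10)
        ann, pos = generate_annotation(cfg)
        beta, _ = simulate_methylation(cfg, ann, pos)
        beta = beta.sort_by_position()
        out = per_cpg_stats(beta_to_m(beta), beta.values, cfg.groups)
        assert (out["fdr"] < 0.01).sum() == 0
        assert out["fdr"].median() > 0.9

    def test_requires_two_groups(self, small_world):
        beta = small_world["beta"]
        groups = pd.Series("R", index=beta.sample_ids)
        with pytest.raises(ValueError, match="two groups"):
            per_cpg_stats(beta_to_m(beta), beta.values, groups)


class TestSmoothStats:
    def _frame(self, chroms, poss, ts, ps):
        stats_df = pd.DataFrame(
            {"t": ts, "p": ps, "delta_beta": 0.0},
            index=[f"cg{i}" for i in range(len(ts))],
        )
        positions = pd.DataFrame(
            {"chrom": chroms, "pos": poss}, index=stats_df.index
        )
        return stats_df, positions

    def test_single_cpg_keeps_own_statistic(self):
        stats_df, positions = self._frame(["chr1"], [100], [2.0], [0.04])
        out = smooth_stats(stats_df, positions)
        # probit-standardized: z = qnorm(1 - p/2), squared
        from scipy.stats import norm

        z2 = norm.isf(0.04 / 2) ** 2
        assert out["smoothed_stat"].iloc[0] == pytest.approx(z2)
        assert out["eff_df"].iloc[0] == pytest.approx(1.0)

    def test_constant_block_is_fixed_point(self):
        n = 30
        stats_df, positions = self._frame(
            ["chr1"] * n, list(range(0, n * 50, 50)), [1.7] * n, [0.09] * n
        )
        out = smooth_stats(stats_df, positions)
        assert np.allclose(
            out["smoothed_stat"], out["smoothed_stat"].iloc[0], atol=1e-9
        )

    def test_unsorted_input_raises(self):
        stats_df, positions = self._frame(
            ["chr1", "chr1"], [200, 100], [1.0, 1.0], [0.3, 0.3]
        )
        with pytest.raises(ValueError, match="sorted"):
            smooth_stats(stats_df, positions)

    def test_planted_block_smaller_p_than_background(self, small_world):
        stats_df, beta = _stats_frame(small_world)
        out = smooth_stats(stats_df, beta.positions)
        iv = small_world["truth"].true_dmr_intervals[0]
        pos = beta.positions
        inside = (
            (pos["chrom"] == iv["chrom"])
            & (pos["pos"] >= iv["start"])
            & (pos["pos"] < iv["end"])
        ).to_numpy()
        assert out.loc[inside, "smoothed_p"].median() < out.loc[
            ~inside, "smoothed_p"
        ].median()


class TestCallDmrs:
    def test_no_significant_cpgs_empty(self):
        stats_df = pd.DataFrame(
            {
                "t": [1.0, 1.0],
                "p": [0.3, 0.3],
                "delta_beta": [0.0, 0.0],
                "smoothed_fdr": [0.9, 0.9],
            },
            index=["cg0", "cg1"],
        )
        positions = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "pos": [0, 100]}, index=stats_df.index
        )
        assert call_dmrs(stats_df, positions) == []

    def test_planted_block_called_and_matches_oracle(self, small_world):
        stats_df, beta = _stats_frame(small_world)
        out = smooth_stats(stats_df, beta.positions)
        dmrs = call_dmrs(out, beta.positions)
        truth_iv = small_world["truth"].true_dmr_intervals
        res = recover_planted(
            dmrs, [(d["chrom"], d["start"], d["end"]) for d in truth_iv]
        )
        assert res["recall"] == 1.0
        # oracle: each planted block is marked by the smoothed significance
        # run and by exactly one called region within gap tolerance
        sig = out["smoothed_fdr"].to_numpy() < 0.01
        pos = beta.positions
        for iv in truth_iv:
            inside = (
                (pos["chrom"] == iv["chrom"])
                & (pos["pos"] >= iv["start"])
                & (pos["pos"] < iv["end"])
            ).to_numpy()
            assert sig[inside].mean() > 0.8  # block significant after smoothing
            covering = [
                d
                for d in dmrs
                if d.chrom == iv["chrom"]
                and min(d.end, iv["end"]) > max(d.start, iv["start"])
            ]
            assert len(covering) == 1
            d = covering[0]
            # boundary extension is bounded by the kernel support (3 bandwidths)
            assert d.start >= iv["start"] - 3000 and d.end <= iv["end"] + 3000

    def test_meanbetafc_is_mean_of_member_deltas(self):
        stats_df = pd.DataFrame(
            {
                "t": [5.0, 5.0],
                "p": [1e-8, 1e-8],
                "delta_beta": [0.2, 0.1],
                "smoothed_fdr": [1e-6, 1e-6],
            },
            index=["cg0", "cg1"],
        )
        positions = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "pos": [0, 100]}, index=stats_df.index
        )
        (dmr,) = call_dmrs(stats_df, positions)
        assert dmr.meanbetafc == pytest.approx(0.15)
        assert dmr.n_cpgs == 2

    def test_threshold_monotonicity(self, small_world):
        stats_df, beta = _stats_frame(small_world)
        out = smooth_stats(stats_df, beta.positions)
        counts = [
            len(call_dmrs(out, beta.positions, min_fdr_threshold=thr))
            for thr in (1e-6, 1e-4, 0.01, 0.05)
        ]
        assert counts == sorted(counts)


class TestRecoverPlanted:
    def test_perfect_calls(self):
        dmrs = [Dmr("chr1", 0, 100, 5, 1e-4, 0.3)]
        res = recover_planted(dmrs, [("chr1", 0, 100)])
        assert res == {"recall": 1.0, "precision": 1.0, "n_called": 1}

    def test_empty_calls(self):
        res = recover_planted([], [("chr1", 0, 100)])
        assert res["recall"] == 0.0
        assert res["precision"] is None

    def test_half_overlap_rule(self):
        # called region covers only 40% of the planted interval: not recovered
        dmrs = [Dmr("chr1", 0, 40, 2, 1e-4, 0.3)]
        res = recover_planted(dmrs, [("chr1", 0, 100)])
        assert res["recall"] == 0.0
        assert res["precision"] == 1.0  # still overlaps => true positive call


class TestDmrInvariants:
    def test_dmr_requires_two_cpgs(self):
        with pytest.raises(ValueError, match="2 CpGs"):
            Dmr("chr1", 0, 10, 1, 0.001, 0.2)

    def test_called_dmrs_disjoint(self, small_world):
        stats_df, beta = _stats_frame(small_world)
        out = smooth_stats(stats_df, beta.positions)
        dmrs = sorted(call_dmrs(out, beta.positions), key=lambda d: (d.chrom, d.start))
        for a, b in zip(dmrs, dmrs[1:]):
            if a.chrom == b.chrom:
                assert a.end <= b.start
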