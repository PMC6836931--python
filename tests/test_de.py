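"""Differential-expression machinery against hand and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import gammaln
from scipy.stats import f as f_dist
from statsmodels.stats.power import FTestAnovaPower

from retrodyn import de, simulate


class TestSizeFactors:
    def test_identical_columns_get_equal_factors(self):
        counts = pd.DataFrame([[5, 5], [7, 7], [2, 2]], columns=["a", "b"])
        sf = de.size_factors(counts)
        assert np.allclose(sf, 1.0)

    def test_hand_computed_median_of_ratios(self, toy_counts):
        # per-gene geometric means: sqrt(8), sqrt(18), sqrt(200);
        # every ratio in column 1 is 1/sqrt(2), in column 2 sqrt(2)
        sf = de.size_factors(toy_counts)
        assert np.allclose(sf.to_numpy(), [1 / np.sqrt(2), np.sqrt(2)])

    def test_global_scaling_invariance(self, toy_counts):
        sf1 = de.size_factors(toy_counts)
        sf2 = de.size_factors(toy_counts * 7)
        assert np.allclose(sf1, sf2)

    def test_no_always_positive_transcript_raises(self):
        counts = pd.DataFrame([[0, 5], [3, 0]], columns=["a", "b"])
        with pytest.raises(ValueError, match="pseudo"):
            de.size_factors(counts)
        assert de.size_factors(counts, pseudo_reference=True).notna().all()


def _meta(groups, n_per_group):
    rows, idx = [], []
    for g in groups:
        for r in range(n_per_group):
            idx.append(f"{g}_r{r}")
            rows.append({"time": g})
    return pd.DataFrame(rows, index=idx)


def _grid_oracle_p(y, groups_cols, alpha_grid):
    """Brute-force reference for the NB LRT with unit size factors.

    Maximizes the Cox-Reid-adjusted full-model likelihood over a dense
    dispersion grid (group means are the analytic MLEs, the sample means,
    when size factors are one), then evaluates the LRT at that dispersion
    and refers LRT/df to F(df, S - k).
    """

    def nll_cr(alpha):
        total, pen = 0.0, 0.0
        for cols in groups_cols:
            yg = y[cols]
            mu = yg.mean()
            r = 1.0 / alpha
            total += np.sum(
                gammaln(yg + r) - gammaln(r) - gammaln(yg + 1)
                + r * np.log(r / (r + mu)) + yg * np.log(np.maximum(mu, 1e-12) / (r + mu))
            )
            w = mu / (1 + alpha * mu)
            pen += 0.5 * np.log(max(w * len(cols), 1e-300))
        return -(total - pen)

    def loglik(alpha, groups_for_fit):
        total = 0.0
        for cols in groups_for_fit:
            yg = y[cols]
            mu = max(yg.mean(), 1e-12)
            r = 1.0 / alpha
            total += np.sum(
                gammaln(yg + r) - gammaln(r) - gammaln(yg + 1)
                + r * np.log(r / (r + mu)) + yg * np.log(mu / (r + mu))
            )
        return total

    alpha_hat = min(alpha_grid, key=nll_cr)
    ll_full = loglik(alpha_hat, groups_cols)
    ll_red = loglik(alpha_hat, [np.concatenate(groups_cols)])
    lrt = max(2 * (ll_full - ll_red), 0.0)
    df = len(groups_cols) - 1
    return f_dist.sf(lrt / df, df, len(y) - len(groups_cols))


class TestNbLrt:
    def test_flat_transcript_is_null(self):
        counts = pd.DataFrame(
            [[30] * 6, [30, 31, 29, 30, 31, 29]],
            index=["flat", "nearly"],
            columns=_meta(["a", "b", "c"], 2).index,
        )
        res = de.nb_lrt(counts, _meta(["a", "b", "c"], 2), sf=pd.Series(1.0, index=counts.columns))
        assert res.table.loc["flat", "lrt_stat"] == pytest.approx(0.0, abs=1e-4)
        assert res.table.loc["flat", "p"] > 0.99

    @pytest.mark.parametrize(
        "row",
        [
            [10, 10, 10, 10, 40, 40],
            [10, 12, 11, 9, 18, 22],
            [5, 8, 30, 24, 7, 6],
        ],
    )
    def test_matches_brute_force_grid_oracle(self, row):
        meta = _meta(["g1", "g2", "g3"], 2)
        counts = pd.DataFrame([row, [50, 52, 48, 51, 49, 50]], index=["x", "ref"], columns=meta.index)
        res = de.nb_lrt(counts, meta, sf=pd.Series(1.0, index=meta.index))
        y = np.asarray(row, dtype=float)
        oracle_p = _grid_oracle_p(
            y, [np.array([0, 1]), np.array([2, 3]), np.array([4, 5])],
            np.logspace(-8, np.log10(50), 6000),
        )
        assert res.table.loc["x", "p"] == pytest.approx(oracle_p, abs=1e-3)

    def test_all_zero_transcripts_are_dropped(self):
        meta = _meta(["a", "b"], 2)
        counts = pd.DataFrame(
            [[0, 0, 0, 0], [5, 6, 7, 8]], index=["zero", "ok"], columns=meta.index
        )
        res = de.nb_lrt(counts, meta)
        assert res.dropped_all_zero == ["zero"]
        assert list(res.table.index) == ["ok"]

    def test_invariant_to_relabeling_within_groups(self):
        design = simulate.SimulationDesign(
            n_transcripts=150,
            modules=(simulate.PlantedModule("m", 30, "up_24h", log2_effect=1.5),),
            seed=12,
        )
        counts, meta, _ = simulate.simulate_counts(design)
        res1 = de.nb_lrt(counts, meta)
        # swap two replicates inside the same time group
        cols = list(counts.columns)
        i, j = 0, 3  # both 0min replicates
        cols[i], cols[j] = cols[j], cols[i]
        res2 = de.nb_lrt(counts[cols], meta)
        assert np.allclose(
            res1.table["lrt_stat"], res2.table["lrt_stat"], rtol=1e-6, atol=1e-8
        )

    def test_fdr_never_below_p(self):
        design = simulate.SimulationDesign(n_transcripts=200, modules=(), seed=13)
        counts, meta, _ = simulate.simulate_counts(design)
        t = de.nb_lrt(counts, meta).table
        assert (t["fdr"] >= t["p"] - 1e-12).all()


class TestBhAdjust:
    def test_all_ones_stay_ones(self):
        assert np.allclose(de.bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_worked_step_up_example(self):
        assert np.allclose(de.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            de.bh_adjust([0.5, 1.5])

    def test_matches_direct_step_up_on_random_vectors(self, rng):
        """Oracle: adj_i = min over ranks j >= rank(i) of p_(j) * m / j."""
        for _ in range(1000):
            m = int(rng.integers(1, 40))
            p = rng.uniform(size=m)
            adj = de.bh_adjust(p)
            order = np.argsort(p)
            expected = np.empty(m)
            running = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                running = min(running, p[i] * m / rank)
                expected[i] = running
            assert np.allclose(adj, expected)

    @settings(max_examples=200, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    def test_adjusted_dominates_raw(self, ps):
        adj = de.bh_adjust(ps)
        assert (adj >= np.asarray(ps) - 1e-12).all()
        assert (adj <= 1.0 + 1e-12).all()


class TestVstAndPca:
    def test_zero_count_maps_to_zero(self):
        counts = pd.DataFrame([[0, 4]], columns=["a", "b"])
        out = de.vst(counts, pd.Series([1.0, 1.0], index=["a", "b"]))
        assert out.iloc[0, 0] == 0.0

    def test_depth_scaling_cancels(self):
        counts = pd.DataFrame([[10, 20], [30, 60]], columns=["a", "b"])
        sf = pd.Series([1.0, 2.0], index=["a", "b"])
        out = de.vst(counts, sf)
        assert np.allclose(out["a"], out["b"])

    def test_variance_roughly_flat_across_mean_deciles(self):
        counts, _, _ = simulate.simulate_counts(
            simulate.SimulationDesign(n_transcripts=2000, modules=(), seed=14)
        )
        sf = de.size_factors(counts)
        expr = de.vst(counts, sf)
        mean = counts.mean(axis=1)
        keep = mean > 5
        deciles = pd.qcut(mean[keep], 10, labels=False, duplicates="drop")
        decile_var = expr[keep].var(axis=1).groupby(deciles).mean()
        assert decile_var.max() / decile_var.min() < 10

    def test_duplicated_sample_has_identical_coordinates(self):
        expr = pd.DataFrame(
            np.random.default_rng(0).normal(size=(50, 3)), columns=["a", "b", "c"]
        )
        expr["d"] = expr["a"]
        scores, frac = de.pca_embedding(expr, n_components=2)
        assert np.allclose(scores.loc["a"], scores.loc["d"])
        assert (np.diff(frac) <= 1e-12).all() and frac.sum() <= 1 + 1e-9

    def test_planted_24h_shift_dominates_pc1(self, default_run):
        scores = default_run.pca_scores
        meta_time = pd.Series(
            [s.rsplit("_", 1)[0] for s in scores.index], index=scores.index
        )
        c24 = scores.loc[meta_time == "24h", "PC1"].mean()
        c0 = scores.loc[meta_time == "0min", "PC1"].mean()
        within = scores.groupby(meta_time)["PC1"].std().mean()
        assert abs(c24 - c0) > within

    def test_too_many_components_rejected(self):
        expr = pd.DataFrame(np.ones((5, 3)), columns=["a", "b", "c"])
        with pytest.raises(ValueError):
            de.pca_embedding(expr, n_components=4)


class TestPowerSampleSize:
    @pytest.mark.parametrize("f", [0.25, 0.4, 0.7])
    def test_matches_independent_power_scan(self, f):
        """Oracle: statsmodels' noncentral-F ANOVA power evaluated on a scan."""
        pw = FTestAnovaPower()
        k = 3
        mine = de.power_sample_size(f, alpha=0.05, power=0.8, k_groups=k)
        scan = next(
            n for n in range(2, 500)
            if pw.power(effect_size=f, nobs=k * n, alpha=0.05, k_groups=k) >= 0.8
        )
        assert mine == scan

    def test_larger_effect_never_needs_more_samples(self):
        ns = [de.power_sample_size(f, 0.05, 0.8, 3) for f in (0.3, 0.5, 0.7, 1.0)]
        assert ns == sorted(ns, reverse=True)

    def test_vanishing_power_target_hits_minimum(self):
        assert de.power_sample_size(0.7, 0.05, 1e-9, 3) == 2
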