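import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import spearmanr

from cellvol3d import phantoms
from cellvol3d.stats import (alp_positive_fraction, binned_positive_fraction,
                             fit_volume_response, group_compare, spearman)


class TestAlpPositiveFraction:
    def test_all_positive(self):
        table = pd.DataFrame({"alp_positive": [1] * 20})
        out = alp_positive_fraction(table)
        assert out["percent"] == 100.0

    def test_cutoff_above_max_gives_zero(self):
        out = alp_positive_fraction([10.0, 20.0, 30.0], cutoff=99.0)
        assert out["percent"] == 0.0

    def test_bernoulli_simulation_within_binomial_ci(self, rng):
        pos = rng.random(200) < 0.3
        out = alp_positive_fraction(pd.DataFrame({"alp_positive": pos}))
        assert out["ci_low_percent"] <= 30.0 <= out["ci_high_percent"]

    def test_estimator_unbiased_over_replicates(self):
        ests = []
        for s in range(40):
            t, _ = phantoms.make_population_table(
                60, link={"form": "flat", "p": 0.35}, seed=s)
            ests.append(alp_positive_fraction(t)["percent"])
        se = 100 * math.sqrt(0.35 * 0.65 / (40 * 180))
        assert np.mean(ests) == pytest.approx(35.0, abs=4 * se)

    def test_zero_cells_rejected(self):
        with pytest.raises(ValueError):
            alp_positive_fraction(pd.DataFrame({"alp_positive": []}))


def _brute_force_spearman_p(x, y):
    """Oracle: exhaustive permutation distribution of scipy's rho."""
    obs = abs(spearmanr(x, y).statistic)
    count = total = 0
    for perm in itertools.permutations(y):
        r = spearmanr(x, perm).statistic
        count += abs(r) >= obs - 1e-12
        total += 1
    return count / total


class TestSpearman:
    def test_strictly_increasing_is_one(self):
        out = spearman([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        assert out["rho"] == pytest.approx(1.0)

    def test_reversed_is_minus_one(self):
        out = spearman([1, 2, 3, 4, 5], [5, 4, 3, 2, 1])
        assert out["rho"] == pytest.approx(-1.0)

    def test_n6_exact_p_matches_full_enumeration(self):
        x = [3.1, 1.2, 5.6, 2.2, 4.9, 0.3]
        y = [12.0, 3.0, 9.0, 6.0, 14.0, 1.0]
        out = spearman(x, y)
        assert out["method"] == "exact-permutation"
        assert out["p"] == pytest.approx(_brute_force_spearman_p(x, y))

    def test_ties_use_midranks_matching_scipy(self, rng):
        x = rng.integers(0, 5, 30).astype(float)
        y = rng.integers(0, 5, 30).astype(float)
        out = spearman(x, y)
        ref = spearmanr(x, y)
        assert out["rho"] == pytest.approx(ref.statistic, abs=1e-12)
        assert out["p"] == pytest.approx(ref.pvalue, rel=1e-6)

    @given(st.integers(1, 6), st.floats(0.1, 3.0))
    @settings(max_examples=25, deadline=None)
    def test_invariant_under_monotone_transform(self, seed, power):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        base = spearman(x, y)
        warped = spearman(np.sign(x) * np.abs(x) ** power, np.exp(y))
        assert warped["rho"] == pytest.approx(base["rho"], abs=1e-12)
        assert warped["p"] == pytest.approx(base["p"], rel=1e-9)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 2], [1, 2])


class TestFitVolumeResponse:
    def test_exact_line_machine_precision(self):
        v = np.linspace(100, 5000, 40)
        fit = fit_volume_response(v, 3.0 + 0.01 * v, "linear")
        assert fit.params["slope"] == pytest.approx(0.01, abs=1e-12)
        assert fit.params["intercept"] == pytest.approx(3.0, abs=1e-9)

    def test_constant_response_zero_slope(self):
        v = np.linspace(100, 5000, 20)
        fit = fit_volume_response(v, np.full(20, 7.0), "linear")
        assert fit.params["slope"] == pytest.approx(0.0, abs=1e-12)

    def test_saturating_recovery_at_5pct_noise(self, rng):
        v = rng.uniform(200, 10000, 100)
        r = 60.0 * v / (2000.0 + v) * (1 + rng.normal(0, 0.05, 100))
        fit = fit_volume_response(v, r, "saturating")
        assert fit.params["a"] == pytest.approx(60.0, rel=0.10)
        assert fit.params["k"] == pytest.approx(2000.0, rel=0.10)
        assert fit.stderr["a"] > 0

    def test_predict_matches_params(self):
        v = np.linspace(100, 5000, 30)
        r = 50.0 * v / (1500.0 + v)
        fit = fit_volume_response(v, r, "saturating")
        a, k = fit.params["a"], fit.params["k"]
        assert fit.predict(1000.0) == pytest.approx(a * 1000 / (k + 1000))

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            fit_volume_response([1, 2, 3], [1, 2, 3], "quadratic")


class TestBinnedPositiveFraction:
    def test_bins_partition_all_cells(self):
        t, _ = phantoms.make_population_table(80, seed=2)
        b = binned_positive_fraction(t["volume_um3"], t["alp_positive"], 6)
        assert b["n"].sum() == len(t)
        assert np.all(np.diff(b["volume_um3"]) > 0)


class TestGroupCompare:
    def test_identical_groups_non_significant(self, rng):
        x = rng.normal(size=30)
        table = pd.DataFrame({
            "v": np.concatenate([x, x, x]),
            "g": ["a"] * 30 + ["b"] * 30 + ["c"] * 30,
        })
        out = group_compare(table, "v", "g", test="anova")
        overall = out[out["comparison"] == "overall"].iloc[0]
        assert overall["statistic"] == pytest.approx(0.0, abs=1e-9)
        assert overall["p"] == pytest.approx(1.0)

    def test_five_sd_shift_detected(self, rng):
        table = pd.DataFrame({
            "v": np.concatenate([rng.normal(0, 1, 30), rng.normal(5, 1, 30)]),
            "g": ["a"] * 30 + ["b"] * 30,
        })
        out = group_compare(table, "v", "g", test="t")
        assert out["p"].iloc[0] < 1e-3

    def test_bonferroni_adjustment_applied(self, rng):
        table = pd.DataFrame({
            "v": rng.normal(size=45),
            "g": ["a"] * 15 + ["b"] * 15 + ["c"] * 15,
        })
        out = group_compare(table, "v", "g", test="anova")
        pw = out[out["test"] == "pairwise-t"]
        assert len(pw) == 3
        assert np.all(pw["p_adjusted"] >= pw["p"] - 1e-15)

    def test_single_group_anova_rejected(self):
        table = pd.DataFrame({"v": [1.0, 2.0], "g": ["a", "a"]})
        with pytest.raises(ValueError):
            group_compare(table, "v", "g", test="anova")

    def test_t_requires_two_groups(self):
        table = pd.DataFrame({"v": [1, 2, 3.0], "g": ["a", "b", "c"]})
        with pytest.raises(ValueError, match="2 groups"):
            group_compare(table, "v", "g", test="t")


class TestEndToEndRecovery:
    def test_monotone_link_yields_significant_positive_spearman(self):
        table, _ = phantoms.make_population_table(100, seed=21)
        out = spearman(table["volume_um3"], table["alp_positive"])
        assert out["rho"] > 0
        assert out["p"] < 0.01
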