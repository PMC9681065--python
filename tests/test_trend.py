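"""Pooling, DerSimonian-Laird estimation, loess trends and comparisons."""

import json
import math
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from declinemeta.trend import (
    DeclineTrend,
    compare_trends,
    floor_zero_variances,
    loess_trend,
    pool_effects,
    yearly_weighted_means,
)


def effects_frame(y, v, years=None, ids=None):
    y = np.asarray(y, dtype=float)
    years = np.full(len(y), 2012) if years is None else np.asarray(years)
    return pd.DataFrame(
        {
            "record_id": ids or [f"e{i}" for i in range(len(y))],
            "year": years,
            "lnrr": y,
            "variance": np.asarray(v, dtype=float),
            "magnitude": np.abs(y),
        }
    )


class TestPoolEffects:
    def test_single_effect_passthrough(self):
        est = pool_effects([2.0], [0.25], model="fixed")
        assert est.mean == 2.0
        assert est.se == 0.5

    def test_equal_weights_reduce_to_arithmetic_mean(self):
        est = pool_effects([1.0, 3.0], [1.0, 1.0], model="fixed")
        assert est.mean == pytest.approx(2.0)

    def test_hand_derived_weighted_mean(self):
        # w = (10, 1.111...): mean = (10*1 + 1.111*3) / 11.111 = 1.2
        est = pool_effects([1.0, 3.0], [0.1, 0.9], model="fixed")
        assert est.mean == pytest.approx(1.2)

    def test_dl_truncates_to_fixed_when_homogeneous(self):
        y, v = [1.0, 1.01, 0.99, 1.0], [1.0, 1.2, 0.9, 1.1]
        fixed = pool_effects(y, v, model="fixed")
        random = pool_effects(y, v, model="random_dl")
        assert random.q <= len(y) - 1
        assert random.tau2 == 0.0
        assert random.mean == fixed.mean
        assert random.se == fixed.se

    def test_dl_widens_se_under_heterogeneity(self):
        y, v = [0.0, 2.0, -2.0, 3.0], [0.05, 0.05, 0.05, 0.05]
        fixed = pool_effects(y, v, model="fixed")
        random = pool_effects(y, v, model="random_dl")
        assert random.tau2 > 0
        assert random.se > fixed.se

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="floor"):
            pool_effects([1.0], [0.0])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pool_effects([], [])

    @given(
        y=st.lists(st.floats(min_value=-5, max_value=5), min_size=1, max_size=12),
        seed=st.integers(min_value=0, max_value=2**16),
    )
    def test_fixed_matches_brute_force_and_convexity(self, y, seed):
        rng = np.random.default_rng(seed)
        v = rng.uniform(0.05, 2.0, size=len(y))
        est = pool_effects(y, v, model="fixed")
        oracle = math.fsum(yi / vi for yi, vi in zip(y, v)) / math.fsum(1 / vi for vi in v)
        assert est.mean == pytest.approx(oracle, abs=1e-12)
        assert min(y) - 1e-12 <= est.mean <= max(y) + 1e-12
        # random-effects mean is convex too
        est_r = pool_effects(y, v, model="random_dl")
        assert min(y) - 1e-12 <= est_r.mean <= max(y) + 1e-12


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not on PATH")
def test_dl_matches_metafor_oracle():
    """Cross-check DerSimonian-Laird pooling against metafor::rma(method='DL')."""
    y = [0.3, 1.2, -0.4, 0.8, 1.9, 0.1]
    v = [0.11, 0.05, 0.32, 0.08, 0.41, 0.14]
    script = (
        "suppressMessages(library(metafor));"
        f"res <- rma(yi=c({','.join(map(str, y))}), vi=c({','.join(map(str, v))}),"
        " method='DL', test='z');"
        "cat(sprintf('{\"b\": %.12f, \"se\": %.12f, \"tau2\": %.12f}',"
        " as.numeric(res$b), res$se, res$tau2))"
    )
    out = subprocess.run(
        ["Rscript", "-e", script], capture_output=True, text=True, check=True
    )
    oracle = json.loads(out.stdout)
    est = pool_effects(y, v, model="random_dl")
    assert est.mean == pytest.approx(oracle["b"], abs=1e-8)
    assert est.se == pytest.approx(oracle["se"], abs=1e-8)
    assert est.tau2 == pytest.approx(oracle["tau2"], abs=1e-8)


class TestFloorZeroVariances:
    def test_floors_to_smallest_positive(self):
        eff = effects_frame([1.0, 2.0, 3.0], [0.0, 0.2, 0.05])
        floored, n = floor_zero_variances(eff)
        assert n == 1
        assert floored["variance"].tolist() == [0.05, 0.2, 0.05]

    def test_all_zero_raises(self):
        with pytest.raises(ValueError):
            floor_zero_variances(effects_frame([1.0], [0.0]))


class TestYearlyWeightedMeans:
    def test_years_with_no_effects_omitted(self):
        eff = effects_frame([1.0, 2.0], [0.1, 0.1], years=[2009, 2012])
        yearly = yearly_weighted_means(eff, model="fixed")
        assert yearly["year"].tolist() == [2009, 2012]

    def test_signed_vs_magnitude_response(self):
        eff = effects_frame([-2.0, -2.0], [0.1, 0.1], years=[2009, 2009])
        signed = yearly_weighted_means(eff, model="fixed", response="signed")
        mag = yearly_weighted_means(eff, model="fixed", response="magnitude")
        assert signed["pooled_mean"].iloc[0] == pytest.approx(-2.0)
        assert mag["pooled_mean"].iloc[0] == pytest.approx(2.0)

    def test_ci_brackets_mean(self):
        eff = effects_frame([1.0, 1.5, 0.5], [0.1, 0.3, 0.2])
        yearly = yearly_weighted_means(eff)
        row = yearly.iloc[0]
        assert row["ci_low"] <= row["pooled_mean"] <= row["ci_high"]
        assert row["k"] == 3


def trend_effects(rng, n_per_year=6, years=range(2009, 2017), slope=0.0, intercept=1.7, noise=0.0):
    rows_y, rows_year = [], []
    for year in years:
        for _ in range(n_per_year):
            rows_year.append(year)
            rows_y.append(intercept + slope * year + noise * rng.standard_normal())
    return effects_frame(rows_y, np.full(len(rows_y), 1.0), years=rows_year)


class TestDeclineTrend:
    def test_constant_effects_give_flat_curve_and_unit_ratio(self):
        rng = np.random.default_rng(0)
        eff = trend_effects(rng)
        res = DeclineTrend(eff, response="signed").fit(boot_reps=0)
        assert np.allclose(res.curve["fitted"], 1.7, atol=1e-8)
        assert res.weighted_slope == pytest.approx(0.0, abs=1e-10)
        assert res.decline_ratio == pytest.approx(1.0)

    def test_noiseless_linear_slope_recovered(self):
        rng = np.random.default_rng(0)
        eff = trend_effects(rng, slope=-0.2, intercept=0.0)
        res = DeclineTrend(eff, response="signed").fit(boot_reps=0)
        assert res.weighted_slope == pytest.approx(-0.2, abs=1e-10)

    def test_same_seed_identical_results(self):
        rng = np.random.default_rng(1)
        eff = trend_effects(rng, noise=0.4)
        res1 = DeclineTrend(eff).fit(boot_reps=50, seed=99)
        res2 = DeclineTrend(eff.copy()).fit(boot_reps=50, seed=99)
        pd.testing.assert_frame_equal(res1.curve, res2.curve)
        pd.testing.assert_frame_equal(res1.yearly, res2.yearly)
        assert res1.weighted_slope == res2.weighted_slope

    def test_bootstrap_band_brackets_fit(self):
        rng = np.random.default_rng(2)
        eff = trend_effects(rng, noise=0.3)
        res = DeclineTrend(eff).fit(boot_reps=200, seed=5)
        inside = (
            (res.curve["ci_low"] <= res.curve["fitted"] + 1e-9)
            & (res.curve["fitted"] <= res.curve["ci_high"] + 1e-9)
        )
        assert inside.mean() >= 0.95

    def test_band_narrows_with_more_effects(self):
        rng = np.random.default_rng(3)
        small = trend_effects(rng, n_per_year=5, noise=0.5)
        big = trend_effects(rng, n_per_year=60, noise=0.5)
        w_small = (
            DeclineTrend(small).fit(boot_reps=120, seed=4).curve.eval("ci_high - ci_low").mean()
        )
        w_big = (
            DeclineTrend(big).fit(boot_reps=120, seed=4).curve.eval("ci_high - ci_low").mean()
        )
        assert w_big < w_small

    def test_too_few_points_or_years_raise(self):
        eff = effects_frame([1.0] * 5, [0.1] * 5, years=[2009, 2010, 2011, 2012, 2013])
        with pytest.raises(ValueError, match=">= 10 effects"):
            DeclineTrend(eff)
        eff = effects_frame([1.0] * 12, [0.1] * 12, years=[2009, 2010] * 6)
        with pytest.raises(ValueError, match="distinct years"):
            DeclineTrend(eff)

    def test_invalid_span_raises(self):
        rng = np.random.default_rng(0)
        eff = trend_effects(rng)
        with pytest.raises(ValueError, match="span"):
            DeclineTrend(eff, span=1.5)

    def test_summary_mentions_key_quantities(self):
        rng = np.random.default_rng(0)
        eff = trend_effects(rng, noise=0.2)
        text = DeclineTrend(eff).fit(boot_reps=0).summary()
        for fragment in ("decline ratio", "weighted slope", "yearly pooled means"):
            assert fragment in text


class TestCompareTrends:
    def make_result(self, seed=0, slope=0.0, years=range(2009, 2017)):
        rng = np.random.default_rng(seed)
        # keep values positive: intercept anchored one year past the range
        eff = trend_effects(
            rng, slope=slope, intercept=1.7 - slope * 2017, noise=0.2, years=years
        )
        return loess_trend(eff, boot_reps=0, response="signed")

    def test_identical_inputs_zero_deltas(self):
        res = self.make_result()
        cmp = compare_trends({"a": res, "b": res})
        assert cmp.metrics.loc["a", "decline_ratio"] == cmp.metrics.loc["b", "decline_ratio"]
        assert (cmp.yearly_means["a"] == cmp.yearly_means["b"]).all()

    def test_steeper_decline_flagged(self):
        flat = self.make_result(seed=1, slope=0.0)
        declining = self.make_result(seed=1, slope=-0.15)
        cmp = compare_trends({"flat": flat, "declining": declining})
        assert cmp.steepest_decline == "declining"
        assert bool(cmp.metrics.loc["declining", "steepest_decline"])

    def test_single_result_raises(self):
        with pytest.raises(ValueError, match=">= 2"):
            compare_trends({"only": self.make_result()})

    def test_disjoint_or_single_shared_year_raises(self):
        early = self.make_result(years=range(2009, 2013))
        late = self.make_result(years=range(2012, 2017))
        with pytest.raises(ValueError, match="fewer than two years"):
            compare_trends({"early": early, "late": late})
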