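"""Cyclic diel models, rank tests and the daily-walking covariate model."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_bins
from koalawalk import activity as act
from koalawalk.labels import MOTIONLESS, WALKING

M, W = MOTIONLESS, WALKING


def sinusoid_bins(peak_hour=17.0, n_individuals=2, n_days=2, noise=0.05,
                  seed=0):
    rng = np.random.default_rng(seed)
    frames = []
    for i in range(n_individuals):
        offset = rng.normal(0, 0.2)
        for d in range(n_days):
            n = 4320
            start_s = np.arange(n) * 20
            hours = (start_s % 86400) // 3600
            hour_f = (start_s % 86400) / 3600.0
            v = 1.0 + offset + 0.5 * np.cos(
                2 * np.pi * (hour_f - peak_hour) / 24.0)
            frame = make_bins([M] * n, individual=f"k{i+1:02d}",
                              date=str(np.datetime64("2023-05-15") + d),
                              vedba=v + rng.normal(0, noise, n), hours=hours)
            frames.append(frame)
    return pd.concat(frames, ignore_index=True)


class TestCyclicActivity:
    def test_periodicity_at_zero_and_24(self):
        res = act.fit_cyclic_activity(sinusoid_bins())
        assert res.predict(0.0) == pytest.approx(res.predict(24.0), abs=1e-10)

    def test_constant_response_gives_flat_curve(self):
        bins = sinusoid_bins(noise=0.0)
        bins["vedba_max_mean"] = 1.23
        res = act.fit_cyclic_activity(bins)
        curve = res.predict(np.linspace(0, 24, 97))
        assert np.max(curve) - np.min(curve) < 1e-6
        assert curve[0] == pytest.approx(1.23, abs=1e-8)

    def test_planted_peak_recovered_within_one_hour(self):
        res = act.fit_cyclic_activity(sinusoid_bins(peak_hour=17.0))
        assert abs(res.peak_hour - 17.0) <= 1.0

    def test_single_individual_flagged(self):
        bins = sinusoid_bins(n_individuals=1)
        with pytest.warns(UserWarning, match="single individual"):
            res = act.fit_cyclic_activity(bins)
        assert res.random_intercepts is False

    def test_hourly_table_ribbon(self):
        res = act.fit_cyclic_activity(sinusoid_bins())
        tab = res.hourly_table()
        assert (tab["lower"] <= tab["mean"]).all()
        assert (tab["mean"] <= tab["upper"]).all()
        assert res.summary()  # renders without error


class TestWalkingCurve:
    def _bins_with_walking(self, lo=2, hi=5, seed=1):
        rng = np.random.default_rng(seed)
        frames = []
        for i in range(3):
            for d in range(4):
                n = 4320
                start_s = np.arange(n) * 20
                hours = (start_s % 86400) // 3600
                p = np.where((hours >= lo) & (hours < hi), 0.02, 0.0005)
                labels = np.where(rng.random(n) < p, W, M).astype(object)
                frames.append(
                    make_bins(list(labels), individual=f"k{i+1:02d}",
                              date=str(np.datetime64("2023-05-15") + d),
                              hours=hours))
        return pd.concat(frames, ignore_index=True)

    def test_peak_inside_configured_window(self):
        res = act.fit_walking_curve(self._bins_with_walking())
        assert 2.0 <= res.peak_hour <= 5.0

    def test_predictions_are_proportions(self):
        res = act.fit_walking_curve(self._bins_with_walking())
        curve = res.predict(np.linspace(0, 24, 49))
        assert np.all(curve >= 0) and np.all(curve <= 1)

    def test_uniform_walking_is_flat_within_ribbon(self):
        rng = np.random.default_rng(2)
        frames = []
        for i in range(3):
            labels = np.where(rng.random(4320) < 0.01, W, M).astype(object)
            frames.append(make_bins(list(labels), individual=f"k{i+1:02d}"))
        res = act.fit_walking_curve(pd.concat(frames, ignore_index=True))
        tab = res.hourly_table()
        spread = tab["mean"].max() - tab["mean"].min()
        ribbon = (tab["upper"] - tab["lower"]).median()
        assert spread < 2 * ribbon

    def test_no_walking_rejected(self):
        with pytest.raises(ValueError, match="Walking"):
            act.fit_walking_curve(make_bins([M] * 4320))


class TestCompareVedba:
    def test_identical_distributions_null(self):
        rng = np.random.default_rng(3)
        frames = [
            make_bins([cat] * 300, vedba=rng.lognormal(0, 0.5, 300))
            for cat in (M, "General Movement in Tree")
        ]
        res = act.compare_vedba(pd.concat(frames, ignore_index=True))
        assert res.pvalue > 0.01
        assert (res.pairwise["p_adj"] > 0.05).all()

    def test_separated_groups_all_pairs_significant(self):
        rng = np.random.default_rng(4)
        frames = []
        for cat, mu in ((M, 0.05), ("Feeding & Grooming in Tree", 0.5), (W, 4.0)):
            frames.append(
                make_bins([cat] * 200, vedba=mu * rng.lognormal(0, 0.2, 200)))
        res = act.compare_vedba(pd.concat(frames, ignore_index=True))
        assert res.pvalue < 1e-6
        assert (res.pairwise["p_adj"] < 0.001).all()
        med = res.group_summary.set_index("category")["median"]
        assert med[W] > med["Feeding & Grooming in Tree"] > med[M]

    def test_bh_adjustment_monotone_and_above_raw(self):
        rng = np.random.default_rng(5)
        frames = [
            make_bins([cat] * 60,
                      vedba=rng.lognormal(mu, 0.4, 60))
            for cat, mu in ((M, 0.0), ("General Movement in Tree", 0.15),
                            ("Feeding & Grooming in Tree", 0.3), (W, 0.5))
        ]
        res = act.compare_vedba(pd.concat(frames, ignore_index=True))
        pw = res.pairwise.sort_values("p_raw")
        assert (pw["p_adj"].to_numpy() >= pw["p_raw"].to_numpy() - 1e-12).all()
        assert (np.diff(pw["p_adj"].to_numpy()) >= -1e-12).all()
        assert pw["p_adj"].between(0, 1).all()

    def test_single_category_rejected(self):
        with pytest.raises(ValueError, match="categories"):
            act.compare_vedba(make_bins([M] * 50))


class TestRankMachinery:
    def test_kruskal_k2_equals_squared_wilcoxon_z(self):
        # for two groups without ties, H equals the squared normal
        # approximation of the rank-sum statistic
        rng = np.random.default_rng(6)
        x, y = rng.normal(0, 1, 12), rng.normal(0.5, 1, 15)
        h, _ = stats.kruskal(x, y)
        n1, n2 = len(x), len(y)
        ranks = stats.rankdata(np.concatenate([x, y]))
        r1 = ranks[:n1].sum()
        mu = n1 * (n1 + n2 + 1) / 2
        sigma = np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12)
        z = (r1 - mu) / sigma
        assert h == pytest.approx(z**2, rel=1e-10)

    def test_bh_matches_exhaustive_definition(self):
        # brute-force BH: p_(i) * m / i, cumulative minimum from the largest
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(7)
        for _ in range(20):
            m = rng.integers(2, 9)
            p = np.sort(rng.random(m))
            expected = np.minimum.accumulate(
                (p * m / np.arange(1, m + 1))[::-1])[::-1]
            expected = np.minimum(expected, 1.0)
            got = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(got, expected, atol=1e-12)


class TestWalkingCovariates:
    def _budgets(self, rng, n_animals=20, n_days=10, habitat_effect=0.0):
        rows = []
        for a in range(n_animals):
            sex = "M" if a % 2 == 0 else "F"
            habitat = "patch" if a < n_animals // 2 else "linear"
            intercept = 3.0 + rng.normal(0, 0.8)
            for d in range(n_days):
                minutes = max(
                    0.0,
                    intercept
                    + (habitat_effect if habitat == "linear" else 0.0)
                    + rng.normal(0, 1.2),
                )
                rows.append(
                    {"individual_id": f"k{a:02d}", "date": d,
                     "category": W, "minutes": minutes, "percent": 0.0,
                     "raw_minutes": minutes, "recorded_minutes": 1440.0,
                     "sex": sex, "habitat": habitat})
        return pd.DataFrame(rows)

    def test_null_type_one_error_controlled(self):
        rng = np.random.default_rng(8)
        sig_sex = sig_hab = 0
        n_rep = 100
        for _ in range(n_rep):
            res = act.walking_covariate_test(self._budgets(rng))
            sig_sex += res.effects.loc["sex[M]", "p"] < 0.05
            sig_hab += res.effects.loc["habitat[linear]", "p"] < 0.05
        assert sig_sex <= 0.06 * n_rep
        assert sig_hab <= 0.06 * n_rep

    def test_injected_habitat_effect_detected_with_power(self):
        rng = np.random.default_rng(9)
        detected = sum(
            act.walking_covariate_test(
                self._budgets(rng, habitat_effect=2.0)
            ).effects.loc["habitat[linear]", "p"] < 0.05
            for _ in range(50)
        )
        assert detected / 50 > 0.8

    def test_constant_response_rejected(self):
        rng = np.random.default_rng(10)
        budgets = self._budgets(rng)
        budgets["minutes"] = 3.0
        with pytest.raises(ValueError, match="variance"):
            act.walking_covariate_test(budgets)

    def test_effect_table_shape(self):
        rng = np.random.default_rng(11)
        res = act.walking_covariate_test(self._budgets(rng))
        assert list(res.effects.columns) == ["coef", "se", "stat", "p"]
        assert res.n_groups == 20
        assert res.summary()
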