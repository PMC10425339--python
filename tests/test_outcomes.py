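"""Discrepancy, instability, correlation statistics, trends, attribution."""

import numpy as np
import pandas as pd
import pytest

import emervent as ev
from emervent.outcomes import kendall_tau_b, point_biserial


from tests_oracles import brute_force_tau_b as _brute_force_tau_b, pearson as _pearson


class TestDiscrepancy:
    def test_identical_sequences(self):
        a = np.array([1, 1, 0, 0])
        assert ev.policy_discrepancy(a, a) == 0

    def test_direct_count(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 2, 300)
        b = a.copy()
        idx = rng.choice(300, size=60, replace=False)
        b[idx] = 1 - b[idx]
        assert ev.policy_discrepancy(a, b) == 60

    def test_earlier_switch_off(self):
        clin = (np.arange(300) < 120).astype(int)
        model = (np.arange(300) < 60).astype(int)
        assert ev.policy_discrepancy(clin, model) == 60

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            ev.policy_discrepancy(np.ones(5), np.ones(4))

    def test_behavior_against_itself_zero(self, episodes):
        for ep in episodes["episodes"][:10]:
            assert ev.policy_discrepancy(ep.actions, ep.actions) == 0


class TestInstability:
    def _episode(self, hr=None, sbp=None, spo2=None, n=100):
        from emervent.preprocess import EmergenceEpisode

        frames = pd.DataFrame({
            "hr": hr if hr is not None else np.full(n, 75.0),
            "sbp": sbp if sbp is not None else np.full(n, 120.0),
            "spo2": spo2 if spo2 is not None else np.full(n, 99.0),
            "pip": np.full(n, 15.0),
            "etco2": np.full(n, 35.0),
            "action": np.ones(n, dtype=int),
        }, index=pd.RangeIndex(n))
        return EmergenceEpisode(start=0, end=n, frames=frames, sb_onset=None,
                                sb_flag=np.zeros(n, int), apnea_cum=np.zeros(n),
                                extubation=None)

    BASE = ev.Baselines(hr0=75.0, sbp0=120.0, pip0=15.0)

    def test_all_stable(self):
        out = ev.instability_duration(self._episode(), self.BASE)
        assert out["instability_s"] == 0

    def test_spo2_only(self):
        spo2 = np.full(100, 99.0)
        spo2[10:40] = 94.0
        out = ev.instability_duration(self._episode(spo2=spo2), self.BASE)
        assert out["instability_s"] == 30 and out["spo2_lt95_s"] == 30

    def test_union_of_intervals(self):
        hr = np.full(100, 75.0)
        hr[10:40] = 75.0 * 1.25
        sbp = np.full(100, 120.0)
        sbp[30:60] = 120.0 * 1.25
        out = ev.instability_duration(self._episode(hr=hr, sbp=sbp), self.BASE)
        assert out["instability_s"] == 50

    def test_two_sided_hr_one_sided_pip(self):
        hr = np.full(100, 75.0 * 0.7)  # bradycardia counts
        out = ev.instability_duration(self._episode(hr=hr), self.BASE)
        assert out["hr_gt20_s"] == 100
        ep = self._episode()
        ep.frames["pip"] = 15.0 * 0.5  # PIP drop does not count
        assert ev.instability_duration(ep, self.BASE)["pip_gt20_s"] == 0

    def test_composite_bounds(self, episodes):
        for ep in episodes["episodes"][:20]:
            base = ev.compute_baseline(ep)
            out = ev.instability_duration(ep, base)
            comp = out["instability_s"]
            parts = [out["spo2_lt95_s"], out["hr_gt20_s"], out["sbp_gt20_s"]]
            assert max(parts) <= comp <= sum(parts)


class TestRankStatistics:
    def test_perfect_concordance_and_reversal(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert kendall_tau_b(x, x)[0] == pytest.approx(1.0)
        assert kendall_tau_b(x, -x)[0] == pytest.approx(-1.0)

    def test_spec_example_two_thirds(self):
        tau, _ = kendall_tau_b([1, 2, 3, 4], [1, 3, 2, 4])
        assert tau == pytest.approx(2.0 / 3.0, abs=1e-12)

    def test_point_biserial_example(self):
        r, _ = point_biserial([0, 0, 1, 1], [1.0, 2.0, 3.0, 4.0])
        assert r == pytest.approx(0.8944271909999159, abs=1e-12)

    def test_equal_group_means_zero(self):
        r, _ = point_biserial([0, 1, 0, 1], [2.0, 1.0, 1.0, 2.0])
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_all_tied_rejected(self):
        with pytest.raises(ValueError):
            kendall_tau_b([1, 1, 1], [1, 2, 3])
        with pytest.raises(ValueError):
            point_biserial([1, 1, 1], [1.0, 2.0, 3.0])

    def test_oracle_agreement_on_random_tied_vectors(self):
        """tau-b against exhaustive pair enumeration and point-biserial
        against definitional Pearson, 1,000 random vectors with ties."""
        rng = np.random.default_rng(123)
        for _ in range(500):
            n = int(rng.integers(4, 25))
            x = rng.integers(0, 6, n).astype(float)
            y = rng.integers(0, 6, n).astype(float)
            if np.all(x == x[0]) or np.all(y == y[0]):
                continue
            tau, _ = kendall_tau_b(x, y)
            assert tau == pytest.approx(_brute_force_tau_b(x, y), abs=1e-12)
        for _ in range(500):
            n = int(rng.integers(4, 40))
            b = rng.integers(0, 2, n)
            if b.min() == b.max():
                continue
            y = rng.normal(size=n).round(1)
            if np.all(y == y[0]):
                continue
            r, _ = point_biserial(b, y)
            assert r == pytest.approx(_pearson(b, y), abs=1e-12)


class TestCorrelateOutcomes:
    def test_bonferroni_threshold(self):
        df = pd.DataFrame({"discrepancy_s": [1.0, 2, 3, 4, 5],
                           "los_days": [1.0, 2, 3, 4, 5]})
        rep = ev.correlate_outcomes(df, family_alpha=0.05, n_outcomes=25)
        assert rep.corrected_level == pytest.approx(0.002)

    def test_missing_outcome_reported_with_zero_n(self):
        df = pd.DataFrame({"discrepancy_s": np.arange(5, dtype=float),
                           "pao2": [np.nan] * 5})
        rep = ev.correlate_outcomes(df)
        row = rep.table.iloc[0]
        assert row["n"] == 0 and np.isnan(row["coefficient"])

    def test_subgroups(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({
            "discrepancy_s": rng.uniform(0, 100, 60),
            "instability_s": rng.uniform(0, 50, 60),
            "age_band": ["<=50", ">50"] * 30,
        })
        rep = ev.correlate_outcomes(df, by="age_band")
        assert set(rep.table["group"]) == {"<=50", ">50"}


class TestTrendCurve:
    def test_constant_outcome_flat_zero_width(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 100, 40)
        y = np.full(40, 7.0)
        curve = ev.bootstrap_trend_curve(x, y, n_boot=50)
        np.testing.assert_allclose(curve["mean"], 7.0, atol=1e-9)
        np.testing.assert_allclose(curve["ub95"] - curve["lb95"], 0.0, atol=1e-9)

    def test_band_contains_point_curve(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 100, 80)
        y = 0.5 * x + rng.normal(0, 5, 80)
        curve = ev.bootstrap_trend_curve(x, y, n_boot=300, seed=3)
        assert (curve["lb95"] <= curve["mean"] + 1e-9).all()
        assert (curve["ub95"] >= curve["mean"] - 1e-9).all()

    def test_planted_positive_slope(self):
        rng = np.random.default_rng(2)
        hits = 0
        for s in range(20):
            x = rng.uniform(0, 100, 60)
            y = 0.3 * x + rng.normal(0, 4, 60)
            curve = ev.bootstrap_trend_curve(x, y, n_boot=30, seed=s)
            hits += curve["mean"].iloc[-1] > curve["mean"].iloc[0]
        assert hits >= 19

    def test_too_few_cases(self):
        with pytest.raises(ValueError):
            ev.bootstrap_trend_curve(np.arange(5), np.arange(5), n_boot=10)


class TestAttribution:
    class ThresholdPolicy:
        feature_names = ["awp_ma6", "hr", "spo2"]

        def act(self, X):
            X = np.atleast_2d(X)
            return (X[:, 0] > 8.0).astype(int)

    def _states(self, rng, n=600):
        return pd.DataFrame({
            "awp_ma6": rng.uniform(4, 14, n),
            "hr": rng.normal(75, 8, n),
            "spo2": rng.normal(98, 1, n),
        })

    def test_threshold_feature_ranked_first(self):
        rng = np.random.default_rng(0)
        imp = ev.feature_attribution(self.ThresholdPolicy(), self._states(rng),
                                     n_learners=100)
        assert imp.index[0] == "awp_ma6"
        assert (imp >= 0).all() and np.isfinite(imp).all()

    def test_ranking_stable_across_surrogate_seeds(self):
        rng = np.random.default_rng(1)
        states = self._states(rng)
        a = ev.feature_attribution(self.ThresholdPolicy(), states, 100, seed=0)
        b = ev.feature_attribution(self.ThresholdPolicy(), states, 100, seed=99)
        assert list(a.index[:3]) == list(b.index[:3])

    def test_degenerate_policy_uniform(self):
        class AlwaysOn:
            def act(self, X):
                return np.ones(len(np.atleast_2d(X)), dtype=int)

        rng = np.random.default_rng(2)
        with pytest.warns(UserWarning):
            imp = ev.feature_attribution(AlwaysOn(), self._states(rng), 50)
        assert np.allclose(imp, imp.iloc[0])
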