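"""IPQ computation, pause-model fitting, bout detection and summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from patchdive import ipq
from patchdive.ipq import IPQConstants


class TestComputeIpq:
    def test_zero_bottom_time_gives_zero_both_forms(self):
        assert ipq.compute_ipq(40.0, 40.0, 20.0, 0.01, "consistent") == 0.0
        assert ipq.compute_ipq(40.0, 40.0, 20.0, 0.01, "as_printed") == 0.0

    def test_u_below_tau_absent(self):
        assert np.isnan(ipq.compute_ipq(30.0, 40.0, 20.0, 0.01))

    def test_no_overflow_for_long_dives(self):
        x = ipq.compute_ipq(3600.0, 100.0, 20.0, 0.03, "consistent")
        assert np.isfinite(x)
        # in the large-u limit the consistent form approaches c * (u - tau)
        assert x == pytest.approx(0.03 * 3500.0, rel=1e-3)

    @settings(deadline=None, max_examples=80, derandomize=True)
    @given(
        tau=st.floats(10.0, 120.0),
        b=st.floats(5.0, 60.0),
        c=st.floats(0.003, 0.03),
    )
    def test_strictly_increasing_in_duration(self, tau, b, c):
        u = np.linspace(tau + 0.5, tau + 500.0, 400)
        for form in ("consistent", "as_printed"):
            x = ipq.compute_ipq(u, tau, b, c, form)
            assert np.all(np.diff(x) > 0)

    def test_bad_form_rejected(self):
        with pytest.raises(ValueError):
            ipq.compute_ipq(50.0, 40.0, 20.0, 0.01, form="nope")


class TestAddIpq:
    def _dives(self, rows):
        df = pd.DataFrame(rows)
        df["start_time"] = pd.Timestamp("2015-12-20")
        return df

    def test_exclusion_bookkeeping(self):
        const = IPQConstants(b=20.0, c=0.01)
        dives = self._dives(
            [
                {"dive_type": "forage", "u": 120.0, "tau": 95.0, "s_post": 60.0},
                {"dive_type": "forage", "u": 120.0, "tau": 95.0, "s_post": 400.0},  # long pause
                {"dive_type": "forage", "u": 120.0, "tau": 95.0, "s_post": np.nan},  # last dive
                {"dive_type": "travel", "u": 24.0, "tau": 20.0, "s_post": 20.0},
                {"dive_type": "forage", "u": 900.0, "tau": 95.0, "s_post": 60.0},  # x > 5
            ]
        )
        out = ipq.add_ipq(dives, const)
        assert np.isfinite(out.loc[0, "ipq"])
        assert out.loc[1, "ipq_excluded"] == "long_pause"
        assert out.loc[2, "ipq_excluded"] == "no_pause"
        assert np.isnan(out.loc[3, "ipq"]) and out.loc[3, "ipq_excluded"] == ""
        assert out.loc[4, "ipq_excluded"] == "ipq_gt_cap" and np.isnan(out.loc[4, "ipq"])

    def test_constructed_overcap_value_is_excluded(self):
        const = IPQConstants(b=20.0, c=0.01)
        # pick u so the consistent-form x lands near 7
        u = 900.0
        x = ipq.compute_ipq(u, 95.0, 20.0, 0.01)
        assert x > 5
        out = ipq.add_ipq(
            self._dives([{"dive_type": "forage", "u": u, "tau": 95.0, "s_post": 60.0}]), const
        )
        assert (out["ipq_excluded"] == "ipq_gt_cap").sum() == 1


class TestFitConstants:
    def test_noiseless_exponential_exact(self):
        u = np.arange(60.0, 201.0, 10.0)
        s = 20.0 * np.exp(0.01 * u)
        const = ipq.fit_constants(u, s)
        assert const.b == pytest.approx(20.0, rel=1e-9)
        assert const.c == pytest.approx(0.01, rel=1e-9)

    def test_recovery_under_lognormal_noise(self):
        rng = np.random.default_rng(0)
        u = rng.uniform(60.0, 200.0, 2000)
        s = 20.0 * np.exp(0.01 * u) * np.exp(rng.normal(0.0, 0.2, 2000))
        const = ipq.fit_constants(u, s)
        assert const.b == pytest.approx(20.0, rel=0.05)
        assert const.c == pytest.approx(0.01, rel=0.05)

    def test_constant_duration_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            ipq.fit_constants(np.full(50, 100.0), np.full(50, 50.0))

    def test_decreasing_pauses_rejected(self):
        u = np.linspace(60, 200, 50)
        s = 100.0 * np.exp(-0.01 * u)
        with pytest.raises(ValueError, match="violated"):
            ipq.fit_constants(u, s)

    def test_ols_alternative_close_to_theil_sen(self):
        rng = np.random.default_rng(1)
        u = rng.uniform(60.0, 200.0, 500)
        s = 15.0 * np.exp(0.012 * u) * np.exp(rng.normal(0.0, 0.1, 500))
        a = ipq.fit_constants(u, s, method="theil-sen")
        b = ipq.fit_constants(u, s, method="ols")
        assert a.c == pytest.approx(b.c, rel=0.1)


class TestPauseThreshold:
    def test_recovers_constructed_changepoint(self):
        # piecewise-exponential pauses: within-bout mean 60 s, between-bout
        # mean 900 s (325 + exp(575)), with densities matched at the 325 s
        # break so the log-frequency curve has a clean slope change there
        rng = np.random.default_rng(2)
        n_short = 30000
        short = rng.exponential(60.0, n_short)
        short = short[short < 325]
        n_long = int(575.0 * (n_short / 60.0) * np.exp(-325.0 / 60.0))
        long = 325.0 + rng.exponential(575.0, n_long)
        est = ipq.estimate_pause_threshold(np.concatenate([short, long]))
        assert est == pytest.approx(325.0, abs=75.0)

    def test_degenerate_distribution_rejected(self):
        with pytest.raises(ValueError):
            ipq.estimate_pause_threshold(np.full(500, 100.0))

    def test_too_few_pauses_rejected(self):
        with pytest.raises(ValueError):
            ipq.estimate_pause_threshold(np.arange(50.0))


def dive_row(t0_s, u, dive_type="forage", **kw):
    row = {
        "start_time": pd.Timestamp("2015-12-20") + pd.Timedelta(seconds=t0_s),
        "u": float(u),
        "dive_type": dive_type,
        "bird_id": "B1",
        "trip_id": "B1_T01",
    }
    row.update(kw)
    return row


class TestDetectBouts:
    def test_gap_rule_splits_run(self):
        dives = pd.DataFrame(
            [
                dive_row(0, 100),
                dive_row(200, 100),  # gap 100 s -> same bout
                dive_row(700, 100),  # gap 400 s -> single
            ]
        )
        out = ipq.detect_bouts(dives, 325.0)
        assert out["in_bout"].tolist() == [True, True, False]
        assert out.loc[0, "bout_id"] == out.loc[1, "bout_id"]
        assert pd.isna(out.loc[2, "bout_id"])

    def test_lone_dive_is_single(self):
        out = ipq.detect_bouts(pd.DataFrame([dive_row(0, 100)]), 325.0)
        assert not out["in_bout"].iloc[0]

    def test_non_foraging_dives_do_not_participate(self):
        dives = pd.DataFrame(
            [
                dive_row(0, 100),
                dive_row(150, 50, dive_type="explore"),
                dive_row(250, 100),  # forage-to-forage gap 150 s despite explore between
            ]
        )
        out = ipq.detect_bouts(dives, 325.0)
        forage = out[out["dive_type"] == "forage"]
        assert forage["in_bout"].all()
        assert pd.isna(out.loc[1, "bout_id"])

    def test_partition_matches_brute_force_gap_scan(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            n = 25
            t, rows = 0.0, []
            for _ in range(n):
                u = rng.uniform(60, 150)
                rows.append(dive_row(t, u))
                t += u + rng.uniform(10, 700)
            dives = pd.DataFrame(rows)
            out = ipq.detect_bouts(dives, 325.0)
            # oracle: quadratic scan over consecutive pairs
            starts = dives["start_time"].astype("int64").to_numpy() / 1e9
            ends = starts + dives["u"].to_numpy()
            groups, cur = [], [0]
            for i in range(1, n):
                if starts[i] - ends[i - 1] < 325.0:
                    cur.append(i)
                else:
                    groups.append(cur)
                    cur = [i]
            groups.append(cur)
            expect_in_bout = np.zeros(n, dtype=bool)
            for g in groups:
                if len(g) >= 2:
                    expect_in_bout[g] = True
            np.testing.assert_array_equal(out["in_bout"].to_numpy(), expect_in_bout)

    def test_recovers_generator_bout_membership(self, small_dataset):
        from patchdive.synthetic import truth_dive_table

        d = truth_dive_table(small_dataset)
        d = ipq.detect_bouts(d, 325.0)
        truth = small_dataset["truth_dives"]
        got = d[d["dive_type"] == "forage"]["in_bout"].to_numpy()
        want = truth[truth["dive_type"] == "forage"]["in_bout_true"].to_numpy()
        assert (got == want).mean() > 0.97  # clipped pauses can merge adjacent patches


class TestSummarizeBouts:
    def test_arithmetic_means(self):
        dives = pd.DataFrame(
            [
                dive_row(0, 100, dist_to_colony=10.0, ipq=0.4),
                dive_row(150, 100, dist_to_colony=20.0, ipq=0.6),
            ]
        )
        out = ipq.summarize_bouts(ipq.detect_bouts(dives, 325.0))
        assert len(out) == 1
        assert out.loc[0, "n_dives"] == 2
        assert out.loc[0, "mean_dist"] == pytest.approx(15.0)
        assert out.loc[0, "mean_ipq"] == pytest.approx(0.5)

    def test_excluded_dive_dropped_from_mean(self):
        dives = pd.DataFrame(
            [
                dive_row(0, 100, dist_to_colony=10.0, ipq=0.4),
                dive_row(150, 100, dist_to_colony=20.0, ipq=np.nan),
            ]
        )
        out = ipq.summarize_bouts(ipq.detect_bouts(dives, 325.0))
        assert out.loc[0, "mean_ipq"] == pytest.approx(0.4)

    def test_bout_quality_signals(self, pipeline_out):
        """Better patches hold more dives, and in-bout dives beat singles."""
        dives = pipeline_out["dives"]
        bouts = pipeline_out["bouts"]
        f = dives[(dives["dive_type"] == "forage") & dives["ipq"].notna()]
        assert f[f["in_bout"]]["ipq"].mean() > f[~f["in_bout"]]["ipq"].mean()
        big = bouts[bouts["n_dives"] >= bouts["n_dives"].median()]
        small = bouts[bouts["n_dives"] < bouts["n_dives"].median()]
        assert big["mean_ipq"].mean() > small["mean_ipq"].mean()
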