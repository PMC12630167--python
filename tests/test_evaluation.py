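"""Season rule, the three metrics, sweeps and envelopes — with
independent brute-force oracles for the season mask and tau-b."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import holopollen as hp
from holopollen.errors import DataError, InvalidParameterError, is_defined


# ------------------------------------------------------------- oracles
def season_mask_oracle(values, T=20.0, W=7, k=4):
    """Enumerate every length-W window; a day is off-season iff it lies
    in at least one window with >= k sub-threshold days."""
    n = len(values)
    off = [False] * n
    for start in range(n - W + 1):
        window = values[start:start + W]
        if sum(v < T for v in window) >= k:
            for d in range(start, start + W):
                off[d] = True
    return np.array(off)


def tau_b_oracle(x, y):
    """O(n^2) pair enumeration with tie corrections."""
    n = len(x)
    conc = disc = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            a, b = x[i] - x[j], y[i] - y[j]
            if a == 0 and b == 0:
                continue
            if a == 0:
                tx += 1
            elif b == 0:
                ty += 1
            elif (a > 0) == (b > 0):
                conc += 1
            else:
                disc += 1
    n0 = n * (n - 1) // 2
    # count tied pairs per vector (including pairs tied in both)
    tied_x = sum(1 for i in range(n) for j in range(i + 1, n) if x[i] == x[j])
    tied_y = sum(1 for i in range(n) for j in range(i + 1, n) if y[i] == y[j])
    denom = math.sqrt((n0 - tied_x) * (n0 - tied_y))
    if denom == 0:
        return float("nan")
    return (conc - disc) / denom


def daily(values, site="site", taxon="Poaceae", source="manual",
          start="2024-04-01"):
    idx = pd.date_range(start, periods=len(values), freq="D", tz="UTC")
    return hp.ConcentrationSeries(site, taxon, "daily",
                                  pd.Series(np.asarray(values, float), index=idx),
                                  source)


# --------------------------------------------------------- season rule
class TestOffSeason:
    def test_all_zero_entirely_off_season(self):
        mask = hp.detect_off_season(daily([0.0] * 14))
        assert mask.off_season.all()

    def test_all_high_entirely_in_season(self):
        mask = hp.detect_off_season(daily([100.0] * 14))
        assert not mask.off_season.any()

    def test_transition_window_semantics(self):
        # Only the first window (days 1-7) holds >= 4 sub-threshold days:
        # its members are off-season, the remaining days in-season.
        vals = [0, 0, 0, 0, 30, 30, 30, 30, 30, 30]
        mask = hp.detect_off_season(daily(vals))
        np.testing.assert_array_equal(
            mask.off_season, [1, 1, 1, 1, 1, 1, 1, 0, 0, 0])

    def test_short_series_rejected(self):
        with pytest.raises(DataError):
            hp.detect_off_season(daily([0.0] * 5))

    def test_non_daily_rejected(self):
        idx = pd.date_range("2024-04-01", periods=30, freq="h", tz="UTC")
        hourly = hp.ConcentrationSeries(
            "s", "t", "hourly", pd.Series(np.ones(30), index=idx), "manual")
        with pytest.raises(DataError):
            hp.detect_off_season(hourly)

    def test_matches_bruteforce_on_random_series(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            n = rng.integers(7, 31)
            vals = np.where(rng.uniform(size=n) < 0.4, 0.0,
                            rng.uniform(0, 200, n))
            got = hp.detect_off_season(daily(vals)).off_season
            np.testing.assert_array_equal(got, season_mask_oracle(vals))

    @given(st.lists(st.floats(0, 200, allow_nan=False), min_size=7,
                    max_size=30))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_bruteforce_property(self, vals):
        got = hp.detect_off_season(daily(vals)).off_season
        np.testing.assert_array_equal(got, season_mask_oracle(vals))


# --------------------------------------------------------------- tau-b
class TestKendallTau:
    def test_perfect_concordance(self):
        assert hp.kendall_tau_b([1, 2, 3], [10, 20, 30]) == pytest.approx(1.0)

    def test_perfect_discordance(self):
        assert hp.kendall_tau_b([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_tied_example_closed_form(self):
        # C=5, D=0, one tie in x: tau-b = 5 / sqrt(30)
        got = hp.kendall_tau_b([1, 2, 2, 3], [1, 3, 2, 4])
        assert got == pytest.approx(5 / math.sqrt(30), abs=1e-12)

    def test_all_tied_is_undefined(self):
        assert not is_defined(hp.kendall_tau_b([5, 5, 5], [1, 2, 3]))

    def test_length_mismatch_rejected(self):
        with pytest.raises(DataError):
            hp.kendall_tau_b([1, 2], [1, 2, 3])

    def test_matches_pair_enumeration_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            n = rng.integers(2, 51)
            # integers force ties
            x = rng.integers(0, 6, n).astype(float)
            y = rng.integers(0, 6, n).astype(float)
            got = hp.kendall_tau_b(x, y)
            want = tau_b_oracle(x, y)
            if math.isnan(want):
                assert not is_defined(got)
            else:
                assert got == pytest.approx(want, abs=1e-12)


# ------------------------------------------------- aggregation & units
class TestAggregation:
    def test_zero_events_all_zero_bins(self):
        table = pd.DataFrame({"timestamp": [], "label": []})
        span = (pd.Timestamp("2024-04-01", tz="UTC"),
                pd.Timestamp("2024-04-03", tz="UTC"))
        counts = hp.aggregate_counts(table, "daily", "Poaceae", span=span)
        assert len(counts) == 2 and (counts == 0).all()

    def test_hourly_bin_counts(self):
        ts = pd.date_range("2024-06-01T06:00", "2024-06-01T06:59",
                           periods=120, tz="UTC")
        table = pd.DataFrame({"timestamp": ts, "label": ["Poaceae"] * 120})
        counts = hp.aggregate_counts(table, "hourly", "Poaceae")
        assert counts[pd.Timestamp("2024-06-01T06:00", tz="UTC")] == 120

    def test_daily_equals_sum_of_hourly(self):
        rng = np.random.default_rng(2)
        ts = pd.to_datetime("2024-06-01", utc=True) + pd.to_timedelta(
            rng.uniform(0, 72, 500), unit="h")
        labels = rng.choice(["Poaceae", "droplet"], 500)
        table = pd.DataFrame({"timestamp": ts, "label": labels})
        span = (ts.min().floor("D"), ts.min().floor("D") + pd.Timedelta(days=3))
        for taxon in ("Poaceae", "droplet"):
            d = hp.aggregate_counts(table, "daily", taxon, span=span)
            h = hp.aggregate_counts(table, "hourly", taxon, span=span)
            assert d.sum() == h.sum() == (labels == taxon).sum()
            np.testing.assert_array_equal(
                d.to_numpy(), h.resample("D").sum().to_numpy())

    def test_unresolved_labels_rejected(self):
        table = pd.DataFrame({
            "timestamp": [pd.Timestamp("2024-06-01", tz="UTC")],
            "label": [None],
        })
        with pytest.raises(DataError):
            hp.aggregate_counts(table, "daily", "Poaceae")

    def test_counts_to_concentration_arithmetic(self):
        idx = pd.date_range("2024-06-01", periods=2, freq="h", tz="UTC")
        counts = pd.Series([120, 0], index=idx)
        conc = hp.counts_to_concentration(counts, 2.4, resolution="hourly")
        assert conc.values[0] == pytest.approx(50.0)
        assert conc.values[1] == 0.0
        assert conc.source == "automatic"
        doubled = hp.counts_to_concentration(counts, 4.8, resolution="hourly")
        np.testing.assert_allclose(doubled.values, conc.values / 2)

    def test_non_positive_flow_rejected(self):
        idx = pd.date_range("2024-06-01", periods=2, freq="D", tz="UTC")
        with pytest.raises(InvalidParameterError):
            hp.counts_to_concentration(pd.Series([1, 2], index=idx), 0.0)


# ------------------------------------------------------ scalar metrics
class TestScalingFactor:
    def test_ratio_of_totals(self):
        s = hp.scaling_factor(daily([100, 100, 100]),
                              daily([50, 30, 20], source="automatic"))
        assert s == pytest.approx(3.0)

    def test_identical_series_unity(self):
        a = daily([5, 10, 20])
        b = daily([5, 10, 20], source="automatic")
        assert hp.scaling_factor(a, b) == pytest.approx(1.0)

    def test_zero_automatic_total_undefined(self):
        assert not is_defined(hp.scaling_factor(
            daily([1, 2, 3]), daily([0, 0, 0], source="automatic")))

    def test_emulated_efficiency_recovered(self):
        true_vals = np.random.default_rng(3).uniform(5, 80, 5000)
        true_s = daily(true_vals, source="true")
        manual = hp.emulate_manual_series(true_s, 2.0, 0.2, 7)
        auto = daily(true_vals, source="automatic")
        assert hp.scaling_factor(manual, auto) == pytest.approx(2.0, rel=0.05)


class TestNoiseRatio:
    def _mask(self, flags, start="2024-04-01"):
        idx = pd.date_range(start, periods=len(flags), freq="D", tz="UTC")
        return hp.SeasonMask(index=idx, off_season=np.asarray(flags, bool))

    def test_simple_ratio(self):
        auto = daily([2, 2, 20, 20], source="automatic")
        mask = self._mask([1, 1, 0, 0])
        assert hp.off_season_noise_ratio(auto, mask) == pytest.approx(0.1)

    def test_zero_off_season_signal_gives_zero(self):
        auto = daily([0, 0, 20, 20], source="automatic")
        assert hp.off_season_noise_ratio(auto, self._mask([1, 1, 0, 0])) == 0.0

    def test_no_off_season_days_undefined(self):
        auto = daily([5, 5, 5, 5], source="automatic")
        assert not is_defined(
            hp.off_season_noise_ratio(auto, self._mask([0, 0, 0, 0])))


# ------------------------------------------------- sweeps & envelopes
class _Ev:
    def __init__(self, ts):
        t = pd.Timestamp(ts)
        self.timestamp = t.tz_localize("UTC") if t.tzinfo is None else t


class TestSweep:
    def _setup(self):
        rng = np.random.default_rng(5)
        classes = ["Poaceae", "droplet"]
        events, labels = [], []
        manual_vals = []
        start = pd.Timestamp("2024-04-01", tz="UTC")
        for day in range(10):
            n = int(rng.integers(5, 40))
            manual_vals.append(float(rng.integers(30, 100)))
            for j in range(n):
                events.append(_Ev(start + pd.Timedelta(days=day, hours=int(rng.integers(0, 24)))))
                labels.append("Poaceae")
        # varying confidences so abstention actually bites
        confs = rng.uniform(0.55, 0.95, len(events))
        preds = []
        for i, (lab, cf) in enumerate(zip(labels, confs)):
            probs = np.array([cf, 1 - cf])
            preds.append(hp.Prediction(f"e{i}", probs, tuple(classes)))
        manual = daily(manual_vals)
        return preds, events, manual

    def test_curve_lengths_and_monotonicity(self):
        preds, events, manual = self._setup()
        thr = np.array([0.0, 0.6, 0.7, 0.8, 0.9])
        curve = hp.threshold_sweep(preds, events, manual, thr)
        assert len(curve.tau) == len(thr)
        assert np.all(np.diff(curve.counts_retained) <= 0)
        defined = [s for s in curve.scaling if is_defined(s)]
        assert np.all(np.diff(defined) >= 0)  # S non-decreasing in c

    def test_all_abstain_gives_sentinels(self):
        preds, events, manual = self._setup()
        m = hp.evaluate_at_threshold(preds, events, manual, 1.0)
        assert m.n_classified == 0
        assert not is_defined(m.scaling)

    def test_descending_thresholds_rejected(self):
        preds, events, manual = self._setup()
        with pytest.raises(InvalidParameterError):
            hp.threshold_sweep(preds, events, manual, [0.5, 0.1])

    def test_off_season_false_positives_increase_noise_ratio(self):
        preds, events, manual = self._setup()
        # an all-zero prefix makes the leading week off-season
        manual2 = daily([0.0] * 7 + list(manual.values), start="2024-03-25")
        base = hp.evaluate_at_threshold(preds, events, manual2, 0.0)
        assert is_defined(base.noise_ratio)
        # droplet-driven grass false positives in the off-season
        extra_events = [_Ev("2024-03-26T08:00") for _ in range(50)]
        extra_preds = [
            hp.Prediction(f"fp{i}", np.array([0.9, 0.1]),
                          ("Poaceae", "droplet"))
            for i in range(50)
        ]
        noisy = hp.evaluate_at_threshold(
            preds + extra_preds, events + extra_events, manual2, 0.0)
        assert noisy.noise_ratio > base.noise_ratio


class TestEnvelope:
    def _curve(self, tau, site):
        n = len(tau)
        return hp.MetricCurve(
            thresholds=np.linspace(0, 0.9, n), tau=tau,
            scaling=np.ones(n), noise_ratio=np.zeros(n),
            counts_retained=np.arange(n, 0, -1), site=site, taxon="Poaceae")

    def test_single_site_degenerate(self):
        env = hp.cross_site_envelope([self._curve([0.5, 0.4], "a")])
        np.testing.assert_array_equal(env.min["tau"], env.max["tau"])
        np.testing.assert_array_equal(env.mean["tau"], [0.5, 0.4])

    def test_two_site_mean_min_max(self):
        env = hp.cross_site_envelope([
            self._curve([0.4, 0.4], "a"), self._curve([0.6, 0.6], "b")])
        np.testing.assert_allclose(env.mean["tau"], [0.5, 0.5])
        np.testing.assert_allclose(env.min["tau"], [0.4, 0.4])
        np.testing.assert_allclose(env.max["tau"], [0.6, 0.6])
        assert (env.n_sites["tau"] == 2).all()

    def test_order_invariance(self):
        a, b = self._curve([0.4, 0.7], "a"), self._curve([0.6, 0.2], "b")
        e1 = hp.cross_site_envelope([a, b])
        e2 = hp.cross_site_envelope([b, a])
        np.testing.assert_array_equal(e1.mean["tau"], e2.mean["tau"])

    def test_sentinels_excluded_with_counts(self):
        a = self._curve([0.4, np.nan], "a")
        b = self._curve([0.6, 0.8], "b")
        env = hp.cross_site_envelope([a, b])
        assert env.mean["tau"][1] == pytest.approx(0.8)
        np.testing.assert_array_equal(env.n_sites["tau"], [2, 1])

    def test_mismatched_grids_rejected(self):
        a = self._curve([0.4, 0.5], "a")
        bad = hp.MetricCurve(
            thresholds=[0.0, 0.5, 0.9], tau=[0.1] * 3, scaling=[1] * 3,
            noise_ratio=[0] * 3, counts_retained=[3, 2, 1])
        with pytest.raises(DataError):
            hp.cross_site_envelope([a, bad])

    def test_plot_writes_file(self, tmp_path):
        env = hp.cross_site_envelope([
            self._curve([0.4, 0.5], "a"), self._curve([0.6, 0.7], "b")])
        out = tmp_path / "curve.png"
        hp.plot_metric_curves(env, out)
        assert out.exists() and out.stat().st_size > 0
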