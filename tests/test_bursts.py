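"""Burst search against a brute-force oracle, background estimation,
metric algebra and dual-label selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from alexfret import simkit
from alexfret.bursts import (
    CorrectionSet,
    compute_metrics,
    estimate_background,
    histogram_E,
    search_bursts,
    search_bursts_bruteforce,
    select_bursts,
)
from conftest import poisson_stream


class TestBackground:
    def test_poisson_rate_within_five_percent(self):
        stream = poisson_stream(1000.0, 30.0, seed=0)
        bg = estimate_background(stream, window_s=60.0)
        assert len(bg) == 1
        assert bg["bg_all"].iloc[0] == pytest.approx(1000.0, rel=0.05)

    def test_two_segment_windowed_estimates(self):
        s1 = poisson_stream(1000.0, 10.0, seed=1)
        s2 = poisson_stream(2000.0, 10.0, seed=2)
        ticks2 = s2.timestamps + int(10.0 / s1.clock_period_s)
        stream = simkit.PhotonStream(
            np.concatenate([s1.timestamps, ticks2]),
            np.concatenate([s1.channels, s2.channels]),
            s1.clock_period_s,
            20.0,
        )
        bg = estimate_background(stream, window_s=10.0)
        assert bg["bg_all"].iloc[0] == pytest.approx(1000.0, rel=0.10)
        assert bg["bg_all"].iloc[1] == pytest.approx(2000.0, rel=0.10)

    def test_empty_stream_rejected(self):
        empty = simkit.PhotonStream(
            np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int8), 12.5e-9, 1.0
        )
        with pytest.raises(ValueError):
            estimate_background(empty)


def _cluster_stream(seed=0, n_cluster=40, bg_rate=100.0, duration=1.0):
    """Sparse background with one dense photon cluster at t = 0.5 s."""
    rng = np.random.default_rng(seed)
    clock = 12.5e-9
    t_bg = np.sort(rng.uniform(0, duration, rng.poisson(bg_rate * duration)))
    t_cl = 0.5 + np.arange(n_cluster) * 20e-6
    t = np.sort(np.concatenate([t_bg, t_cl]))
    ticks = np.unique(np.round(t / clock).astype(np.int64))
    ch = rng.choice(3, size=ticks.size).astype(np.int8)
    return simkit.PhotonStream(ticks, ch, clock, duration)


def _flat_background(rate, duration):
    return pd.DataFrame(
        [{"t_start": 0.0, "t_stop": duration, "bg_all": rate,
          "bg_DexDem": rate / 3, "bg_DexAem": rate / 3, "bg_AexAem": rate / 3}]
    )


class TestSearch:
    def test_background_only_yields_no_bursts(self):
        stream = poisson_stream(450.0, 10.0, seed=3)
        table = search_bursts(stream, m=10, F=6.0, min_size=30)
        assert len(table) == 0

    def test_dense_cluster_found_as_single_burst(self):
        stream = _cluster_stream()
        bg = _flat_background(100.0, 1.0)
        table = search_bursts(stream, m=10, F=6.0, min_size=30, background=bg)
        assert len(table) == 1
        b = table.iloc[0]
        t = stream.times_s
        # burst covers the cluster plus at most a couple of nearby
        # background photons
        assert 0.5 - 2e-3 <= t[int(b.istart)] <= 0.5 + 1e-9
        assert t[int(b.istop) - 1] <= 0.5 + 40 * 20e-6 + 2e-3
        assert 39 <= b.n_photons <= 45

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_bruteforce_criterion(self, seed):
        rng = np.random.default_rng(seed)
        clock = 12.5e-9
        # background plus a few clusters, <= 500 photons
        t = list(rng.uniform(0, 2.0, rng.integers(100, 300)))
        for _ in range(rng.integers(0, 4)):
            t0 = rng.uniform(0.1, 1.9)
            t.extend(t0 + np.arange(rng.integers(10, 60)) * rng.uniform(1e-5, 1e-4))
        t = np.sort(np.asarray(t))[:500]
        ticks = np.unique(np.round(t / clock).astype(np.int64))
        ch = rng.choice(3, size=ticks.size).astype(np.int8)
        stream = simkit.PhotonStream(ticks, ch, clock, 2.0)
        bg = _flat_background(150.0, 2.0)
        fast = search_bursts(stream, m=10, F=6.0, min_size=10, background=bg)
        slow = search_bursts_bruteforce(stream, m=10, F=6.0, min_size=10, background=bg)
        pd.testing.assert_frame_equal(fast, slow)

    def test_parameter_validation(self):
        stream = poisson_stream(500.0, 1.0, seed=4)
        with pytest.raises(ValueError):
            search_bursts(stream, m=1)
        with pytest.raises(ValueError):
            search_bursts(stream, F=0.5)


class TestMetrics:
    @pytest.mark.parametrize(
        "dd,da,aa,E,S",
        [
            (50, 50, 100, 0.5, 0.5),
            (30, 10, 40, 0.25, 0.5),
            (70, 0, 30, 0.0, 0.7),
        ],
    )
    def test_arithmetic_identities(self, dd, da, aa, E, S):
        df = pd.DataFrame([{"F_DD": dd, "F_DA": da, "F_AA": aa}])
        out = compute_metrics(df)
        assert out["E"].iloc[0] == pytest.approx(E)
        assert out["S"].iloc[0] == pytest.approx(S)

    def test_e_equals_pr_without_corrections(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(
            {"F_DD": rng.integers(1, 100, 50), "F_DA": rng.integers(1, 100, 50),
             "F_AA": rng.integers(1, 100, 50)}
        )
        out = compute_metrics(df, CorrectionSet())
        assert np.array_equal(out["E"].to_numpy(), out["PR"].to_numpy())

    def test_corrections_change_e(self):
        df = pd.DataFrame([{"F_DD": 100, "F_DA": 30, "F_AA": 100}])
        out = compute_metrics(df, CorrectionSet(leakage=0.1, direct_excitation=0.05))
        # F_DA' = 30 - 10 - 5 = 15 -> E = 15/115
        assert out["E"].iloc[0] == pytest.approx(15 / 115)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        dd=st.integers(0, 500), da=st.integers(0, 500), aa=st.integers(0, 500)
    )
    def test_metric_ranges_for_any_counts(self, dd, da, aa):
        out = compute_metrics(pd.DataFrame([{"F_DD": dd, "F_DA": da, "F_AA": aa}]))
        row = out.iloc[0]
        if not row["flag_undefined"]:
            assert 0.0 <= row["PR"] <= 1.0
            assert 0.0 <= row["S_raw"] <= 1.0
            assert row["E"] == row["PR"]  # neutral corrections

    def test_zero_denominator_flagged(self):
        df = pd.DataFrame([{"F_DD": 0, "F_DA": 0, "F_AA": 10}])
        out = compute_metrics(df)
        assert out["flag_undefined"].iloc[0]
        assert np.isnan(out["E"].iloc[0])


class TestSelection:
    def test_retained_fraction_matches_population(self):
        # bright scenario so the size filter passes every species
        sc = simkit.SimScenario(
            state_efficiencies=(0.5,), rate_matrix=((0.0,),),
            frac_dual=0.6, frac_donly=0.2, frac_aonly=0.2,
            burst_rate=100_000.0, n_bursts=600, seed=13,
        )
        stream = simkit.simulate_experiment(sc)
        table = search_bursts(stream, min_size=20)
        metrics = compute_metrics(table)
        selected, rep = select_bursts(metrics, size_range=(20, np.inf))
        frac = rep["n_selected"] / rep["n_total"]
        sigma = np.sqrt(0.6 * 0.4 / rep["n_total"])
        assert abs(frac - 0.6) < 4 * sigma

    def test_full_range_is_identity_and_idempotent(self, apo_small):
        metrics = apo_small["metrics"]
        all_sel, _ = select_bursts(metrics, s_range=(0, 1), size_range=(0, np.inf))
        assert len(all_sel) == len(metrics.dropna(subset=["S"]))
        once, _ = select_bursts(metrics)
        twice, _ = select_bursts(once)
        pd.testing.assert_frame_equal(once, twice)
        # order independence
        shuffled = metrics.sample(frac=1.0, random_state=0)
        again, _ = select_bursts(shuffled)
        assert set(again["istart"]) == set(once["istart"])

    def test_all_donor_only_selects_nothing(self):
        sc = simkit.SimScenario(
            frac_dual=0.0, frac_donly=1.0, frac_aonly=0.0, n_bursts=100, seed=14
        )
        stream = simkit.simulate_experiment(sc)
        metrics = compute_metrics(search_bursts(stream))
        with pytest.warns(UserWarning):
            selected, rep = select_bursts(metrics)
        assert rep["n_selected"] == 0 and len(selected) == 0


class TestHistogram:
    def test_static_single_state_unimodal_at_truth(self, static_small):
        hist = histogram_E(static_small["selected"], bins=20)
        mode = hist.loc[hist["frequency"].idxmax()]
        assert 0.35 <= mode["bin_left"] and mode["bin_right"] <= 0.45
        assert hist["frequency"].sum() == pytest.approx(1.0)

    def test_apo_dominant_low_fret_mode(self, apo_small):
        hist = histogram_E(apo_small["selected"], bins=20)
        mode = hist.loc[hist["frequency"].idxmax()]
        assert mode["bin_right"] <= 0.3

    def test_empty_input_all_zero(self):
        hist = histogram_E(pd.DataFrame(columns=["E"]), bins=10)
        assert hist["count"].sum() == 0
        assert np.all(hist["frequency"] == 0)

    def test_too_few_bins_rejected(self, apo_small):
        with pytest.raises(ValueError):
            histogram_E(apo_small["selected"], bins=1)
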