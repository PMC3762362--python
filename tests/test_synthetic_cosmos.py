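"""Simulator: scheme probabilities, dwell laws, and the observation model."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cosmoskin import (
    KineticParams,
    ObservationConfig,
    apply_observation_model,
    simulate_filament_sites,
    simulate_tethered_arp,
)


def _nascent_pairs(events: pd.DataFrame) -> pd.DataFrame:
    """diVCA-channel rows of +diVCA arrivals (one per nascent branch)."""
    return events[events["channel"] == "vca"]


@pytest.fixture(scope="module")
def big_run():
    """A large wild-type run used by several distributional checks."""
    params = KineticParams.from_construct("wt", conc_arp=5e-8)
    obs = ObservationConfig(seed=42, duration=600.0)
    events = simulate_filament_sites(params, 400, obs)
    return params, events


def test_zero_release_rate_gives_only_corelease():
    params = KineticParams(k_v_minus_star=0.0, f_av_truth=1.0, p_nuc_bare=0.0)
    obs = ObservationConfig(seed=1, duration=300.0)
    events = simulate_filament_sites(params, 50, obs)
    fates = set(events["fate"])
    assert fates <= {"corelease"}


def test_release_fraction_matches_competing_clock_formula(big_run):
    params, events = big_run
    pairs = _nascent_pairs(events)
    n = len(pairs)
    assert n > 20000
    released = pairs["fate"].str.startswith("vca_release")
    f_hat = released.mean()
    f_true = params.f_v_minus_truth
    se = np.sqrt(f_true * (1 - f_true) / n)
    assert abs(f_hat - f_true) < 3 * se


def test_mean_nascent_dwell_matches_reference_lifetime(big_run):
    params, events = big_run
    pairs = _nascent_pairs(events)
    dwell = (pairs["t_off_s"] - pairs["t_on_s"]).to_numpy()
    # censoring at record end is negligible at these scales
    mean = dwell.mean()
    expect = params.tau_v_star_truth
    assert expect == pytest.approx(0.6993, abs=1e-3)  # the 0.7 s reference
    assert abs(mean - expect) < 3 * expect / np.sqrt(len(dwell))


def test_nascent_dwells_are_exponential_ks(big_run):
    params, events = big_run
    dwell = (
        _nascent_pairs(events)["t_off_s"] - _nascent_pairs(events)["t_on_s"]
    ).to_numpy()[:10000]
    ktot = params.k_a_minus + params.k_v_minus_star
    res = stats.kstest(dwell, "expon", args=(0, 1.0 / ktot))
    assert res.pvalue > 0.01


def test_same_seed_byte_identical_different_seed_not():
    params = KineticParams.from_construct("wt")
    obs = ObservationConfig(seed=7)
    a = simulate_filament_sites(params, 30, obs)
    b = simulate_filament_sites(params, 30, obs)
    pd.testing.assert_frame_equal(a, b)
    c = simulate_filament_sites(params, 30, obs, seed=8)
    assert not a.equals(c)


def test_invalid_rates_rejected():
    with pytest.raises(ValueError):
        KineticParams(k_a_minus=-1.0)
    with pytest.raises(ValueError):
        KineticParams(k_a_minus=np.inf)
    with pytest.raises(ValueError):
        KineticParams(f_av_truth=1.5)


class TestTetheredArp:
    def test_unoccupied_interval_mean(self):
        params = KineticParams(k_v_plus=1e8, conc_divca=5e-9)
        obs = ObservationConfig(seed=3, duration=2000.0)
        ev = simulate_tethered_arp(params, 30, obs)
        gaps = []
        for _, g in ev.groupby("site_id"):
            t = g.sort_values("t_on_s")
            gaps.append(t["t_on_s"].iloc[0])
            gaps.extend(
                (t["t_on_s"].values[1:] - t["t_off_s"].values[:-1]).tolist()
            )
        gaps = np.asarray(gaps)
        gaps = gaps[gaps > 0]
        assert len(gaps) > 1000
        assert abs(gaps.mean() - 2.0) < 3 * 2.0 / np.sqrt(len(gaps))

    def test_pure_fast_component_single_exponential(self):
        params = KineticParams(a_v1=1.0, tau_v1=5.0)
        obs = ObservationConfig(seed=4, duration=3000.0)
        ev = simulate_tethered_arp(params, 50, obs)
        dwell = (ev["t_off_s"] - ev["t_on_s"]).to_numpy()
        dwell = dwell[ev["t_off_s"] < obs.duration]  # drop censored
        assert abs(dwell.mean() - 5.0) < 3 * 5.0 / np.sqrt(len(dwell))

    def test_mixture_mean_dwell(self):
        # reference off-filament mixture: 0.24*8 + 0.76*61 = 48.3 s
        params = KineticParams.from_construct("wt")
        obs = ObservationConfig(seed=5, duration=100000.0)
        ev = simulate_tethered_arp(params, 10, obs)
        dwell = (ev["t_off_s"] - ev["t_on_s"]).to_numpy()
        dwell = dwell[ev["t_off_s"] < obs.duration]
        expect = 0.24 * 8 + 0.76 * 61
        assert expect == pytest.approx(48.28, abs=0.01)
        sd = np.std(dwell)
        assert abs(dwell.mean() - expect) < 3 * sd / np.sqrt(len(dwell))

    def test_zero_molecules_empty_table(self):
        ev = simulate_tethered_arp(KineticParams(), 0, ObservationConfig(seed=1))
        assert len(ev) == 0


class TestObservationModel:
    def test_identity_limit(self, obs_clean):
        params = KineticParams.from_construct("wt")
        true = simulate_filament_sites(params, 20, obs_clean)
        seen = apply_observation_model(true, obs_clean)
        merged = seen.sort_values(["site_id", "channel", "t_on_s"]).reset_index(drop=True)
        orig = true.sort_values(["site_id", "channel", "t_on_s"]).reset_index(drop=True)
        assert len(merged) == len(orig)
        np.testing.assert_allclose(
            merged["t_on_s"].to_numpy(), orig["t_on_s"].to_numpy(), atol=2e-6
        )
        np.testing.assert_allclose(merged["x_um"], orig["x_um"])

    def test_minimum_dwell_survival_fraction(self):
        # exponential dwells with tau = 0.1443 s: S(0.1) = 0.500
        tau, t_min = 0.1443, 0.1
        rng = np.random.default_rng(11)
        n = 10000
        t_on = rng.uniform(0, 500, n)
        dwell = rng.exponential(tau, n)
        true = pd.DataFrame(
            {
                "site_id": np.arange(n), "channel": "vca",
                "x_um": rng.uniform(0, 50, n), "y_um": rng.uniform(0, 50, n),
                "t_on_s": t_on, "t_off_s": t_on + dwell, "fate": "x",
            }
        )
        obs = ObservationConfig(
            t_min=t_min, bleach_rate_per_power=0.0, loc_sigma=0.0,
            nonspecific_rate=0.0, frame_interval=1e-6, duration=600.0, seed=2,
        )
        seen = apply_observation_model(true, obs)
        frac = len(seen) / n
        p = np.exp(-t_min / tau)
        assert p == pytest.approx(0.5, abs=1e-3)
        assert abs(frac - p) < 3 * np.sqrt(p * (1 - p) / n)

    def test_bleaching_adds_to_observed_rate(self):
        k_true, b = 1.0, 0.5
        rng = np.random.default_rng(21)
        n = 10000
        t_on = rng.uniform(0, 500, n)
        dwell = rng.exponential(1.0 / k_true, n)
        true = pd.DataFrame(
            {
                "site_id": np.arange(n), "channel": "vca",
                "x_um": rng.uniform(0, 50, n), "y_um": rng.uniform(0, 50, n),
                "t_on_s": t_on, "t_off_s": t_on + dwell, "fate": "x",
            }
        )
        obs = ObservationConfig(
            t_min=0.0, bleach_rate_per_power=b, laser_power=1.0,
            loc_sigma=0.0, nonspecific_rate=0.0, frame_interval=1e-6,
            duration=600.0, seed=3,
        )
        seen = apply_observation_model(true, obs)
        observed_rate = 1.0 / (seen["t_off_s"] - seen["t_on_s"]).mean()
        se = (k_true + b) / np.sqrt(len(seen))
        assert abs(observed_rate - (k_true + b)) < 3 * se

    def test_negative_power_rejected(self):
        with pytest.raises(ValueError):
            ObservationConfig(laser_power=-1.0)
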