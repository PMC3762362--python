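"""Coincidence/departure classification, corrections, initiation times."""

import numpy as np
import pandas as pd
import pytest

from cosmoskin import KineticParams, ObservationConfig, simulate_filament_sites
from cosmoskin.dwell_inference import ExpMixtureFit
from cosmoskin.event_classification import (
    classify_arrivals,
    classify_departures,
    detection_efficiency,
    estimate_initiation_time,
    match_arrivals,
    nonspecific_correction,
    summarize_fates,
)


def _table(rows):
    return pd.DataFrame(
        rows, columns=["site_id", "channel", "x_um", "y_um", "t_on_s", "t_off_s", "fate"]
    )


class TestArrivalMatching:
    def test_inside_both_windows_is_coincident(self):
        arp = _table([(0, "arp", 0.0, 0.0, 10.00, 11.0, "")])
        vca = _table([(0, "vca", 0.10, 0.0, 10.10, 11.0, "")])
        m = match_arrivals(arp, vca, 0.27, 0.15)
        assert m[0] == 0

    def test_outside_time_window_not_coincident(self):
        arp = _table([(0, "arp", 0.0, 0.0, 10.00, 11.0, "")])
        vca = _table([(0, "vca", 0.0, 0.0, 10.20, 11.0, "")])
        assert match_arrivals(arp, vca, 0.27, 0.15)[0] == -1

    def test_outside_distance_window_not_coincident(self):
        arp = _table([(0, "arp", 0.0, 0.0, 10.0, 11.0, "")])
        vca = _table([(0, "vca", 0.30, 0.0, 10.0, 11.0, "")])
        assert match_arrivals(arp, vca, 0.27, 0.15)[0] == -1

    def test_ambiguity_resolved_nearest_in_time_then_space(self):
        arp = _table([(0, "arp", 0.0, 0.0, 10.0, 11.0, "")])
        vca = _table(
            [
                (0, "vca", 0.05, 0.0, 10.10, 11.0, ""),
                (1, "vca", 0.20, 0.0, 10.05, 11.0, ""),
            ]
        )
        # second candidate is nearer in time despite being farther away
        assert match_arrivals(arp, vca, 0.27, 0.15)[0] == 1

    def test_each_vca_consumed_once(self):
        arp = _table(
            [
                (0, "arp", 0.0, 0.0, 10.00, 11.0, ""),
                (1, "arp", 0.0, 0.0, 10.05, 11.0, ""),
            ]
        )
        vca = _table([(0, "vca", 0.0, 0.0, 10.02, 11.0, "")])
        m = match_arrivals(arp, vca, 0.27, 0.15)
        assert sorted(m.tolist()) == [-1, 0]


class TestDepartures:
    def _pair(self, arp_off, vca_off):
        arp = _table([(0, "arp", 0.0, 0.0, 10.0, arp_off, "")])
        vca = _table([(0, "vca", 0.0, 0.0, 10.0, vca_off, "")])
        return arp, vca, np.array([0])

    def test_same_frame_disappearance_is_corelease(self):
        arp, vca, m = self._pair(12.0, 12.0)
        s = classify_departures(arp, vca, m, 0.15)
        assert s.n_corelease == 1 and s.n_release == 0

    def test_window_boundary(self):
        s = classify_departures(*self._pair(12.10, 12.0), 0.15)
        assert s.n_corelease == 1
        s = classify_departures(*self._pair(12.20, 12.0), 0.15)
        assert s.n_release == 1

    def test_vca_outlasting_arp_is_anomalous(self):
        s = classify_departures(*self._pair(12.0, 12.5), 0.15)
        assert s.n_anomalous == 1
        assert s.f_v_minus == 0.0


class TestDetectionEfficiency:
    def test_tmin_zero_gives_unity(self):
        fit = ExpMixtureFit(np.array([1.0]), np.array([0.5]), 0.0, 100, 0.0)
        assert detection_efficiency(fit, 0.0) == 1.0

    def test_single_component_half(self):
        fit = ExpMixtureFit(np.array([1.0]), np.array([0.1443]), 0.0, 100, 0.0)
        assert detection_efficiency(fit, 0.1) == pytest.approx(0.500, abs=1e-3)

    def test_negative_tmin_rejected(self):
        fit = ExpMixtureFit(np.array([1.0]), np.array([1.0]), 0.0, 100, 0.0)
        with pytest.raises(ValueError):
            detection_efficiency(fit, -0.1)

    def test_correction_unbiased_on_truncated_data(self, rng):
        # truncating an exponential sample and rescaling by 1/p0 recovers
        # the original count on average
        tau, t_min, n = 0.5, 0.1, 2000
        errs = []
        for _ in range(100):
            d = rng.exponential(tau, n)
            kept = d[d >= t_min]
            p0 = np.exp(-t_min / tau)
            errs.append(len(kept) / p0 - n)
        se = np.sqrt(n * (1 - p0) / p0)  # binomial, scaled
        assert abs(np.mean(errs)) < 3 * se / np.sqrt(100)


class TestNonspecificCorrection:
    def test_zero_control(self):
        assert nonspecific_correction(100, 0) == 100

    def test_arithmetic(self):
        assert nonspecific_correction(100, 20, 1.0) == 80

    def test_floor_with_warning(self):
        with pytest.warns(UserWarning):
            assert nonspecific_correction(10, 20, 1.0) == 0.0

    def test_poisson_background_removed_in_expectation(self, rng):
        lam_sig, lam_bg = 80, 30
        resid = [
            nonspecific_correction(
                rng.poisson(lam_sig + lam_bg), rng.poisson(lam_bg), 1.0
            )
            - lam_sig
            for _ in range(100)
        ]
        se = np.sqrt(lam_sig + 2 * lam_bg)
        assert abs(np.mean(resid)) < 3 * se / np.sqrt(100)


class TestInitiationTime:
    def test_exact_line(self):
        est = estimate_initiation_time([10, 20, 30], [0.25, 0.75, 1.25], 0.0)
        assert est.t_init == pytest.approx(5.0, abs=1e-9)
        assert est.slope == pytest.approx(0.05)
        assert est.included

    def test_noisy_recovery(self, rng):
        hits = attempts = 0
        for _ in range(100):
            t = np.linspace(10, 50, 10)
            L = 0.05 * (t - 5) + rng.normal(0, 0.1, 10)
            if np.any(L <= 0):
                continue
            attempts += 1
            est = estimate_initiation_time(t, L, 0.0)
            if abs(est.t_init - 5.0) < 2 * est.t_init_se:
                hits += 1
        assert attempts >= 90 and hits / attempts >= 0.85

    def test_initiation_after_arrival_included(self):
        est = estimate_initiation_time([10, 20, 30], [0.25, 0.75, 1.25], 4.5)
        assert est.included  # 5.0 > 4.5 + 0.1

    def test_initiation_too_close_to_arrival_excluded(self):
        est = estimate_initiation_time([10, 20, 30], [0.25, 0.75, 1.25], 4.99)
        assert not est.included

    def test_nonpositive_slope_excluded(self):
        est = estimate_initiation_time([10, 20, 30], [1.0, 0.6, 0.3], 0.0)
        assert not est.included


class TestGroundTruthAgreement:
    def test_classification_matches_simulator_labels(self):
        """Wide windows relative to jitter: >=99% fate agreement."""
        params = KineticParams.from_construct("wt")
        obs = ObservationConfig(
            seed=9, duration=600.0, loc_sigma=0.02,
            bleach_rate_per_power=0.0, nonspecific_rate=0.0,
        )
        from cosmoskin.synthetic_cosmos import apply_observation_model

        true = simulate_filament_sites(params, 150, obs)
        seen = apply_observation_model(true, obs)
        arp = seen[seen.channel == "arp"].reset_index(drop=True)
        vca = seen[seen.channel == "vca"].reset_index(drop=True)
        m = match_arrivals(arp, vca, 0.27, 0.15)
        s = classify_departures(arp, vca, m, 0.15)
        # arrival agreement: matched iff fate involves diVCA
        has_vca = arp["fate"].isin(
            ["corelease", "vca_release_detach", "vca_release_branch"]
        ).to_numpy()
        agree = ((m >= 0) == has_vca).mean()
        assert agree >= 0.99
        # departure agreement on the matched pairs
        idx = np.flatnonzero(m >= 0)
        truth_release = arp["fate"].to_numpy()[idx] != "corelease"
        ta = arp["t_off_s"].to_numpy()[idx]
        tv = vca["t_off_s"].to_numpy()[m[idx]]
        called_release = ta - tv > 0.15
        assert (called_release == truth_release).mean() >= 0.99

    def test_fraction_sum_invariant(self):
        params = KineticParams.from_construct("wt")
        obs = ObservationConfig(seed=10, duration=600.0)
        from cosmoskin.synthetic_cosmos import apply_observation_model

        true = simulate_filament_sites(params, 80, obs)
        seen = apply_observation_model(true, obs)
        arp = seen[seen.channel == "arp"].reset_index(drop=True)
        vca = seen[seen.channel == "vca"].reset_index(drop=True)
        s = summarize_fates(
            arp, vca, record_end=obs.duration, correct_detection=False
        )
        assert s.f_v_minus + s.f_corelease <= 1.0 + 1e-12
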