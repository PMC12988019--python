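"""Synthetic experiment generator: determinism, distributions, bookkeeping."""

import numpy as np
import pytest
from dataclasses import replace

from routemem.errors import ConfigError
from routemem.geo import geodesic_distance_m
from routemem.metrics import BaselineSet, homing_efficiency, mean_nnd
from routemem.preprocess import PreprocessParams, filter_stationary, trim_homing_segment
from routemem.simulate import (
    HOME_LOFT,
    STANTON_HARCOURT,
    SimConfig,
    forget_route,
    generate_experiment,
    make_baseline_corridor,
    pool_pair_memory,
    realize_flight,
)
from routemem.trackio import validate_records


CFG = SimConfig(seed=42)


def beeline_offsets(wp):
    """Perpendicular distances of interior waypoints from the beeline (m)."""
    from routemem.simulate import _enu

    home = HOME_LOFT
    xy = _enu(wp[:, 0], wp[:, 1], home)
    r, h = xy[0], xy[-1]
    u = (h - r) / np.linalg.norm(h - r)
    nperp = np.array([-u[1], u[0]])
    rel = xy - (r[None, :] + np.outer((xy - r) @ u, u))
    return rel[1:-1] @ nperp


class TestCorridors:
    def test_zero_sd_lies_on_beeline_and_is_straight(self):
        cfg = replace(CFG, corridor_sd_m=0.0, flight_wobble_m=0.0, gps_noise_m=0.0)
        wp = make_baseline_corridor(STANTON_HARCOURT, HOME_LOFT, cfg, np.random.default_rng(0))
        assert np.abs(beeline_offsets(wp)).max() < 1e-6
        flight = realize_flight(wp, cfg, np.random.default_rng(1))
        trimmed = trim_homing_segment(
            filter_stationary(flight, PreprocessParams()),
            STANTON_HARCOURT, HOME_LOFT, PreprocessParams(),
        )
        assert homing_efficiency(trimmed) > 0.99

    def test_same_stream_reproduces_distinct_pairs_differ(self):
        wp1 = make_baseline_corridor(STANTON_HARCOURT, HOME_LOFT, CFG, np.random.default_rng(5))
        wp1b = make_baseline_corridor(STANTON_HARCOURT, HOME_LOFT, CFG, np.random.default_rng(5))
        wp2 = make_baseline_corridor(STANTON_HARCOURT, HOME_LOFT, CFG, np.random.default_rng(6))
        np.testing.assert_array_equal(wp1, wp1b)
        assert np.abs(wp1 - wp2).max() > 0

    def test_mean_perpendicular_offset_is_half_normal(self):
        rng = np.random.default_rng(0)
        offs = []
        for _ in range(200):
            wp = make_baseline_corridor(STANTON_HARCOURT, HOME_LOFT, CFG, rng)
            offs.append(np.abs(beeline_offsets(wp)))
        mean_abs = np.mean(offs)
        expected = CFG.corridor_sd_m * np.sqrt(2 / np.pi)
        assert mean_abs == pytest.approx(expected, rel=0.05)


class TestRealizeFlight:
    def test_duration_matches_kinematics(self):
        cfg = replace(CFG, flight_wobble_m=0.0, gps_noise_m=0.0)
        wp = make_baseline_corridor(STANTON_HARCOURT, HOME_LOFT, cfg, np.random.default_rng(2))
        t = realize_flight(wp, cfg, np.random.default_rng(3))
        seg = sum(
            geodesic_distance_m(
                type(STANTON_HARCOURT)(wp[i, 0], wp[i, 1]),
                type(STANTON_HARCOURT)(wp[i + 1, 0], wp[i + 1, 1]),
            )
            for i in range(len(wp) - 1)
        )
        expected = seg / (cfg.step_speed_kmh / 3.6)
        flight_duration = t.duration_s - cfg.dawdle_s - 10  # minus dawdle+approach
        assert flight_duration == pytest.approx(expected, abs=2.0)

    def test_same_corridor_flights_nnd_matches_monte_carlo(self):
        """Mean NND between two flights of one corridor is set by the wobble,
        drift-free GPS process; cross-check a planar Monte-Carlo mock."""
        cfg = replace(CFG, corridor_sd_m=0.0, route_drift_step_m=0.0)
        params = PreprocessParams()
        rng = np.random.default_rng(9)
        vals = []
        for _ in range(8):
            wp = make_baseline_corridor(STANTON_HARCOURT, HOME_LOFT, cfg, rng)
            a = realize_flight(wp, cfg, rng)
            b = realize_flight(wp, cfg, rng)
            a = trim_homing_segment(filter_stationary(a, params), STANTON_HARCOURT, HOME_LOFT, params)
            b = trim_homing_segment(filter_stationary(b, params), STANTON_HARCOURT, HOME_LOFT, params)
            vals.append(mean_nnd(a, BaselineSet([b])))
        observed = np.mean(vals)

        # independent planar Monte Carlo of the same generative process
        from scipy.signal import lfilter

        mc_rng = np.random.default_rng(123)
        mc_vals = []
        n, spacing = 430, cfg.step_speed_kmh / 3.6
        s = np.arange(n) * spacing
        L = s[-1]
        for _ in range(8):
            tracks = []
            for _ in range(2):
                w = np.zeros(n)
                z = mc_rng.normal(size=3)
                ph = mc_rng.uniform(0, 2 * np.pi, 3)
                for h in range(3):
                    w += z[h] * np.sin(2 * np.pi * (h + 1) * s / L + ph[h])
                w *= cfg.flight_wobble_m * np.sqrt(2 / 3)
                innov = cfg.gps_noise_m * np.sqrt(1 - cfg.gps_noise_ar**2)
                e = np.empty((n, 2))
                for ax in range(2):
                    eta = mc_rng.normal(0, innov, n)
                    e0 = mc_rng.normal(0, cfg.gps_noise_m)
                    e[:, ax] = lfilter([1.0], [1.0, -cfg.gps_noise_ar], eta,
                                       zi=[cfg.gps_noise_ar * e0])[0]
                tracks.append(np.column_stack((s + e[:, 0], w + e[:, 1])))
            d2 = (
                (tracks[0][:, None, 0] - tracks[1][None, :, 0]) ** 2
                + (tracks[0][:, None, 1] - tracks[1][None, :, 1]) ** 2
            )
            mc_vals.append(np.sqrt(d2.min(axis=1)).mean())
        assert observed == pytest.approx(np.mean(mc_vals), rel=0.15)


class TestForgetting:
    def wp(self):
        return make_baseline_corridor(STANTON_HARCOURT, HOME_LOFT, CFG, np.random.default_rng(1))

    def test_full_retention_is_identity(self):
        out, mask = forget_route(self.wp(), 1.0, CFG, np.random.default_rng(0))
        np.testing.assert_array_equal(out, self.wp())
        assert mask.all()

    def test_zero_retention_perturbs_all_interior(self):
        wp = self.wp()
        out, mask = forget_route(wp, 0.0, CFG, np.random.default_rng(0))
        assert not mask[1:-1].any()
        assert mask[0] and mask[-1]
        np.testing.assert_array_equal(out[[0, -1]], wp[[0, -1]])
        assert np.abs(out[1:-1] - wp[1:-1]).max() > 0

    def test_retained_fraction_matches_binomial(self):
        rng = np.random.default_rng(0)
        wp = self.wp()
        total = kept = 0
        for _ in range(10_000 // CFG.corridor_waypoints + 1):
            _, mask = forget_route(wp, 0.6, CFG, rng)
            kept += mask[1:-1].sum()
            total += CFG.corridor_waypoints
        assert kept / total == pytest.approx(0.6, abs=0.01)

    def test_shared_latent_gives_identical_masks(self):
        wp = self.wp()
        lat = np.random.default_rng(7).normal(size=CFG.corridor_waypoints)
        _, m1 = forget_route(wp, 0.5, CFG, np.random.default_rng(1), latent=lat)
        _, m2 = forget_route(wp, 0.5, CFG, np.random.default_rng(2), latent=lat)
        np.testing.assert_array_equal(m1, m2)


class TestPooling:
    def test_both_retain_everything_returns_originals(self):
        wp = make_baseline_corridor(STANTON_HARCOURT, HOME_LOFT, CFG, np.random.default_rng(1))
        mask = np.ones(len(wp), dtype=bool)
        pooled, pmask = pool_pair_memory(wp, wp, mask, mask, CFG, np.random.default_rng(0))
        np.testing.assert_allclose(pooled, wp)
        assert pmask.all()

    def test_complementary_masks_retain_all_under_distributed(self):
        wp = make_baseline_corridor(STANTON_HARCOURT, HOME_LOFT, CFG, np.random.default_rng(1))
        rng = np.random.default_rng(2)
        memA, maskA = forget_route(wp, 0.5, CFG, rng)
        maskB = ~maskA
        maskB[0] = maskB[-1] = True
        memB = wp.copy()
        pooled, pmask = pool_pair_memory(memA, memB, maskA, maskB, CFG, rng)
        assert pmask.all()

    def test_pooled_retention_is_one_minus_squared_loss(self):
        rng = np.random.default_rng(0)
        wp = make_baseline_corridor(STANTON_HARCOURT, HOME_LOFT, CFG, rng)
        p = 0.6
        kept = total = 0
        for _ in range(900):
            memA, mA = forget_route(wp, p, CFG, rng)
            memB, mB = forget_route(wp, p, CFG, rng)
            _, pm = pool_pair_memory(memA, memB, mA, mB, CFG, rng)
            kept += pm[1:-1].sum()
            total += CFG.corridor_waypoints
        assert kept / total == pytest.approx(1 - (1 - p) ** 2, abs=0.01)

    def test_leader_rule_uses_better_member(self):
        cfg = replace(CFG, pooling_rule="leader")
        wp = make_baseline_corridor(STANTON_HARCOURT, HOME_LOFT, cfg, np.random.default_rng(1))
        rng = np.random.default_rng(3)
        memA, mA = forget_route(wp, 0.9, cfg, rng)
        memB, mB = forget_route(wp, 0.2, cfg, rng)
        assert mA.sum() > mB.sum()
        pooled, pmask = pool_pair_memory(memA, memB, mA, mB, cfg, rng)
        np.testing.assert_array_equal(pooled, memA)


class TestGenerateExperiment:
    def test_bit_reproducible(self, small_config):
        e1 = generate_experiment(small_config)
        e2 = generate_experiment(small_config)
        assert len(e1.tracks) == len(e2.tracks)
        for a, b in zip(e1.tracks, e2.tracks):
            np.testing.assert_array_equal(a.lats, b.lats)
            np.testing.assert_array_equal(a.times, b.times)

    def test_records_pass_all_metadata_validations(self, small_experiment):
        validate_records(small_experiment.records)

    def test_counts_match_ledger_and_design(self, small_experiment, small_config):
        exp, cfg = small_experiment, small_config
        assert len(exp.tracks) == exp.ledger.n_tracks
        per_pair_site_tracks = (
            2 * cfg.n_tracked_baseline_paired + 2 * cfg.n_tracked_baseline_solo
        )
        # every pair and site has the tracked training block
        from collections import Counter

        c = Counter(
            (r.pair_id, r.site)
            for r in exp.records
            if r.testing_time == "baseline" and "train" in r.release_id
        )
        assert all(v == per_pair_site_tracks for v in c.values())
        # memory testing: one paired release (2 records) or two solo records
        mem = Counter(
            (r.pair_id, r.site) for r in exp.records if r.testing_time == "memory_testing"
        )
        assert all(v == 2 for v in mem.values())

    def test_ledger_truth_masks_cover_memory_releases(self, small_experiment):
        mem_rids = {
            r.release_id
            for r in small_experiment.records
            if r.testing_time == "memory_testing"
        }
        assert mem_rids == set(small_experiment.ledger.truth)
        for rid, t in small_experiment.ledger.truth.items():
            assert t["nnd_true_m"] >= 1.0
            for mask in t["masks"].values():
                assert mask[0] and mask[-1]

    def test_generating_effects_recorded_per_treatment(self, small_experiment):
        eff = small_experiment.ledger.generating_effects
        assert set(eff) == {"forgetting", "extra_training"}

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(segment_retention_solo={"forgetting": 1.5, "extra_training": 0.9}).validate()
        with pytest.raises(ConfigError):
            SimConfig(pooling_rule="telepathy").validate()
        with pytest.raises(ConfigError):
            SimConfig(n_tracked_baseline_paired=20).validate()
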