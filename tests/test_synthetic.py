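"""Trace and cohort generators: determinism, ground truth, recovery."""

import numpy as np
import pytest

from fixstab import (
    CohortSimConfig,
    ExclusionPolicy,
    TraceSimConfig,
    apply_exclusions,
    compare_conditions,
    detect_blinks,
    estimate_dispersion,
    pearson_r,
    pixels_to_degrees,
    simulate_cohort,
    simulate_trace,
)
from fixstab.synthetic import TABLE_COHORT_PARAMS


class TestSimulateTrace:
    def test_same_seed_is_deterministic(self):
        cfg = TraceSimConfig(seed=5, duration_s=30.0)
        t1, g1 = simulate_trace(cfg)
        t2, g2 = simulate_trace(cfg)
        assert np.array_equal(t1.x, t2.x, equal_nan=True)
        assert np.array_equal(t1.valid, t2.valid)
        assert g1.blink_intervals == g2.blink_intervals

    def test_degenerate_config_pins_gaze_to_target(self):
        cfg = TraceSimConfig(
            duration_s=5.0, sigma_h=0.0, sigma_v=0.0, rho=0.0,
            microsaccade_rate_hz=0.0, blink_rate_per_min=0.0,
            noise_sd_deg=0.0, setup_s=0.0, seed=0,
        )
        trace, _ = simulate_trace(cfg)
        assert np.allclose(trace.x, cfg.geometry.target_px[0])
        assert np.allclose(trace.y, cfg.geometry.target_px[1])

    def test_sample_count_and_units(self):
        cfg = TraceSimConfig(duration_s=60.0, setup_s=10.0, seed=1)
        trace, truth = simulate_trace(cfg)
        assert len(trace) == 70 * 50 == truth.n_samples
        assert trace.units == "pixels"
        assert truth.setup_window == (0.0, 10.0)

    def test_invalid_rho_rejected(self):
        with pytest.raises(ValueError):
            TraceSimConfig(rho=1.5)

    def test_excessive_microsaccade_variance_rejected(self):
        with pytest.raises(ValueError, match="microsaccade"):
            simulate_trace(TraceSimConfig(
                sigma_h=0.05, sigma_v=0.05, microsaccade_rate_hz=20.0,
                microsaccade_amp_mean_deg=1.0,
            ))

    def test_blink_gaps_are_invalid_runs(self, sim_trace):
        cfg, trace, truth = sim_trace
        for s, e in truth.blink_intervals:
            assert not trace.valid[s:e].any()
            assert np.isnan(trace.x[s:e]).all()

    def test_stationary_dispersion_recovered_artifact_free(self):
        # isotropic 300 s trace; tolerance from the autocorrelation-corrected
        # effective sample size ESS = duration / (2 * drift timescale)
        cfg = TraceSimConfig(
            duration_s=300.0, sigma_h=1.0, sigma_v=1.0, rho=0.0,
            microsaccade_rate_hz=0.0, blink_rate_per_min=0.0,
            noise_sd_deg=0.0, setup_s=0.0, seed=21,
        )
        trace, _ = simulate_trace(cfg)
        deg = pixels_to_degrees(trace, cfg.geometry)
        d = estimate_dispersion(np.column_stack([deg.x, deg.y]))
        ess = cfg.duration_s / (2.0 * cfg.drift_timescale_s)
        tol = 3.0 / np.sqrt(2.0 * ess)
        assert abs(d.sigma_h - 1.0) < tol
        assert abs(d.sigma_v - 1.0) < tol

    def test_end_to_end_recovery_with_default_artifacts(self):
        # full pipeline over a handful of seeds: < 5% bias on sigma and rho
        sh, sv, rho = [], [], []
        for seed in range(12):
            cfg = TraceSimConfig(seed=seed)
            trace, truth = simulate_trace(cfg)
            deg = pixels_to_degrees(trace, cfg.geometry)
            policy = ExclusionPolicy(setup_window=(truth.setup_window,))
            clean = apply_exclusions(deg, detect_blinks(deg, policy), policy)
            d = estimate_dispersion(clean)
            sh.append(d.sigma_h)
            sv.append(d.sigma_v)
            rho.append(d.rho)
        assert abs(np.mean(sh) / 1.5 - 1.0) < 0.05
        assert abs(np.mean(sv) / 1.0 - 1.0) < 0.05
        assert abs(np.mean(rho) / 0.4 - 1.0) < 0.15  # rho is noisier per seed


class TestSimulateCohort:
    def test_zero_sd_reproduces_condition_means(self):
        params = {
            "visual_field": {"bcea_1sd": {
                "DEF": (4.62, 0.0), "N-DEF": (5.24, 0.0), "BF": (2.85, 0.0)}}
        }
        table, _ = simulate_cohort(CohortSimConfig(metric_params=params, seed=0))
        for cond, mu in (("DEF", 4.62), ("N-DEF", 5.24), ("BF", 2.85)):
            vals = table[table.condition == cond]["bcea_1sd"]
            assert np.allclose(vals, mu)

    def test_table_layout_complete(self):
        table, truth = simulate_cohort(CohortSimConfig(n_participants=6, seed=2))
        assert len(table) == 6 * 3 * 2  # participants x conditions x phases
        assert set(table.condition) == {"DEF", "N-DEF", "BF"}
        assert set(table.phase) == {"foveal_threshold", "visual_field"}
        assert truth["n_participants"] == 6
        assert {"ocular_position_pd", "fusional_amplitude_pd"} <= set(table.columns)

    def test_mean_recovery_of_configured_values(self):
        # grand mean over many simulated cohorts approaches the input mean
        n_seeds, n_part = 120, 35
        mu, sd = TABLE_COHORT_PARAMS["visual_field"]["bcea_1sd"]["BF"]
        means = []
        for seed in range(n_seeds):
            cfg = CohortSimConfig(
                metric_params={"visual_field":
                               {"bcea_1sd": TABLE_COHORT_PARAMS["visual_field"]["bcea_1sd"]}},
                seed=seed,
            )
            table, _ = simulate_cohort(cfg)
            means.append(table[table.condition == "BF"]["bcea_1sd"].mean())
        se = sd / np.sqrt(n_part * n_seeds)
        assert abs(np.mean(means) - mu) < 3 * se

    def test_within_subject_correlation_structure(self):
        table, _ = simulate_cohort(CohortSimConfig(n_participants=2000, seed=3))
        wide = table[table.phase == "visual_field"].pivot(
            index="participant", columns="condition", values="bcea_1sd"
        )
        r, _, _ = pearson_r(np.log(wide["DEF"]), np.log(wide["BF"]))
        assert r == pytest.approx(0.5, abs=0.06)  # copula corr on the log scale

    def test_high_covariate_correlation_is_detectable(self):
        detections = 0
        n_seeds = 40
        for seed in range(n_seeds):
            cfg = CohortSimConfig(covariate_corr=0.9, seed=seed)
            table, _ = simulate_cohort(cfg)
            sub = table[(table.condition == "BF") & (table.phase == "visual_field")]
            _, p, _ = pearson_r(sub["bcea_1sd"], sub["ocular_position_pd"])
            detections += p < 0.05
        assert detections / n_seeds >= 0.95

    def test_null_cohorts_stay_null_under_comparison(self):
        # equal condition means: Bonferroni-significant pairs at <= nominal rate
        params = {"visual_field": {"bcea_1sd": {
            "DEF": (2.85, 2.0), "N-DEF": (2.85, 2.0), "BF": (2.85, 2.0)}}}
        fw_errors = 0
        n_seeds = 200
        for seed in range(n_seeds):
            table, _ = simulate_cohort(
                CohortSimConfig(metric_params=params, seed=seed))
            rep = compare_conditions(table, ["bcea_1sd"])
            fw_errors += (rep["p_adjusted"] < 0.05).any()
        rate = fw_errors / n_seeds
        assert rate <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_seeds)
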