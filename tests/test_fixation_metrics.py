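"""BCEA, coverage relation, ellipse geometry and deviation statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fixstab import (
    CoverageSpec,
    DispersionEstimate,
    bcea,
    deviation_summary,
    ellipse_contour,
    estimate_dispersion,
    k_from_p,
    p_from_k,
    point_in_ellipse_fraction,
)
from fixstab.fixation_metrics import metrics_record
from fixstab.preprocessing import CleanTrace


def _random_dispersion(rng):
    return DispersionEstimate(
        mean_h=float(rng.normal(0, 2)), mean_v=float(rng.normal(0, 2)),
        sigma_h=float(rng.uniform(0.1, 3.0)), sigma_v=float(rng.uniform(0.1, 3.0)),
        rho=float(rng.uniform(-0.95, 0.95)), n=100,
    )


class TestCoverageRelation:
    @pytest.mark.parametrize(
        "p, k",
        [
            (0.63212, 1.0000),     # 1 - 1/e, the k = 1 coverage
            (0.6827, 1.1479076),   # 1-SD mass
            (0.9545, 3.0900430),   # 2-SD mass
            (0.9973, 5.9145035),   # 3-SD mass
        ],
    )
    def test_k_from_p_reference_values(self, p, k):
        assert k_from_p(p) == pytest.approx(k, abs=1e-4)

    @given(st.floats(1e-9, 1 - 1e-9))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_round_trip_p_k(self, p):
        assert p_from_k(k_from_p(p)) == pytest.approx(p, abs=1e-12)

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.2, 1.3])
    def test_domain_errors(self, p):
        with pytest.raises(ValueError):
            k_from_p(p)

    def test_coverage_spec_enforces_relation(self):
        CoverageSpec.from_p(0.6827)
        CoverageSpec.from_k(1.147)  # printed-k override route
        with pytest.raises(ValueError):
            CoverageSpec(p=0.6827, k=1.147)  # inconsistent pair


class TestEstimateDispersion:
    def test_four_point_hand_computation(self):
        xy = np.array([[0, 0], [2, 0], [0, 2], [2, 2]], dtype=float)
        d = estimate_dispersion(xy)
        assert (d.mean_h, d.mean_v) == (1.0, 1.0)
        assert d.sigma_h == pytest.approx(1.1547005, abs=1e-6)
        assert d.sigma_v == pytest.approx(1.1547005, abs=1e-6)
        assert d.rho == 0.0
        assert d.n == 4 and not d.degenerate

    def test_identical_samples_flagged_degenerate(self):
        d = estimate_dispersion(np.ones((10, 2)))
        assert d.sigma_h == d.sigma_v == 0.0
        assert d.rho == 0.0 and d.degenerate

    def test_insufficient_data(self):
        with pytest.raises(ValueError):
            estimate_dispersion(np.array([[1.0, 2.0]]))

    def test_monte_carlo_recovery(self):
        rng = np.random.default_rng(42)
        sh, sv, rho, n = 1.5, 1.0, 0.4, 50_000
        cov = [[sh**2, rho * sh * sv], [rho * sh * sv, sv**2]]
        d = estimate_dispersion(rng.multivariate_normal([0, 0], cov, n))
        # 3 MC standard errors: SE(sigma) ~ sigma/sqrt(2n), SE(rho) ~ (1-rho^2)/sqrt(n)
        assert abs(d.sigma_h - sh) < 3 * sh / math.sqrt(2 * n)
        assert abs(d.sigma_v - sv) < 3 * sv / math.sqrt(2 * n)
        assert abs(d.rho - rho) < 3 * (1 - rho**2) / math.sqrt(n)


class TestBcea:
    def test_unit_circle_case(self):
        d = DispersionEstimate(0, 0, 1.0, 1.0, 0.0, 10)
        cov = CoverageSpec.from_k(1.0)
        assert bcea(d, cov).area_deg2 == pytest.approx(2 * math.pi, rel=1e-12)

    def test_perfect_correlation_collapses_area(self):
        d = DispersionEstimate(0, 0, 1.0, 2.0, 1.0, 10)
        assert bcea(d, CoverageSpec.from_p(0.6827)).area_deg2 == 0.0

    def test_direct_formula_value(self):
        d = DispersionEstimate(0, 0, 1.2, 0.8, 0.5, 10)
        area = bcea(d, CoverageSpec.from_p(0.6827)).area_deg2
        assert area == pytest.approx(5.997, abs=2e-3)

    def test_equals_determinant_form_on_random_dispersions(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            d = _random_dispersion(rng)
            cov = CoverageSpec.from_p(float(rng.uniform(0.05, 0.999)))
            expected = 2 * cov.k * math.pi * math.sqrt(np.linalg.det(d.covariance))
            assert bcea(d, cov).area_deg2 == pytest.approx(expected, rel=1e-12)

    def test_strictly_increasing_in_k(self):
        d = DispersionEstimate(0, 0, 1.2, 0.9, 0.3, 10)
        areas = [bcea(d, CoverageSpec.from_k(k)).area_deg2 for k in (0.5, 1.147, 3.0, 5.9)]
        assert all(a < b for a, b in zip(areas, areas[1:]))

    def test_scale_equivariance(self):
        rng = np.random.default_rng(5)
        xy = rng.multivariate_normal([0.3, -0.2], [[1.4, 0.3], [0.3, 0.8]], 400)
        cov = CoverageSpec.from_p(0.6827)
        for c in (0.5, 2.0, 7.3):
            a1 = bcea(estimate_dispersion(xy), cov).area_deg2
            a2 = bcea(estimate_dispersion(c * xy), cov).area_deg2
            assert a2 == pytest.approx(c**2 * a1, rel=1e-9)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(6)
        xy = rng.multivariate_normal([0, 0], [[2.0, 0.7], [0.7, 0.9]], 500)
        cov = CoverageSpec.from_p(0.9545)
        base = bcea(estimate_dispersion(xy), cov).area_deg2
        for th in (0.3, 1.2, 2.5):
            r = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
            rotated = (xy - xy.mean(0)) @ r.T + xy.mean(0)
            assert bcea(estimate_dispersion(rotated), cov).area_deg2 == pytest.approx(
                base, rel=1e-9
            )


class TestEllipseContour:
    def test_isotropic_circle_radius(self):
        d = DispersionEstimate(0.5, -0.5, 1.0, 1.0, 0.0, 10)
        e = ellipse_contour(d, CoverageSpec.from_k(1.0))
        assert e.semi_major == pytest.approx(math.sqrt(2.0))
        assert e.semi_minor == pytest.approx(math.sqrt(2.0))
        assert e.center == (0.5, -0.5)

    def test_axis_aligned_when_uncorrelated(self):
        d = DispersionEstimate(0, 0, 2.0, 1.0, 0.0, 10)
        e = ellipse_contour(d, CoverageSpec.from_p(0.6827))
        assert e.angle_rad == pytest.approx(0.0, abs=1e-12)
        assert e.semi_major > e.semi_minor

    def test_area_matches_bcea(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            d = _random_dispersion(rng)
            cov = CoverageSpec.from_p(0.9545)
            e = ellipse_contour(d, cov)
            assert e.area == pytest.approx(bcea(d, cov).area_deg2, rel=1e-9)

    def test_polygon_area_oracle(self):
        # shoelace area of the sampled contour vs the analytic BCEA
        rng = np.random.default_rng(2)
        d = _random_dispersion(rng)
        cov = CoverageSpec.from_p(0.6827)
        poly = ellipse_contour(d, cov).contour(n_points=20000)
        x, y = poly[:, 0], poly[:, 1]
        shoelace = 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
        assert shoelace == pytest.approx(bcea(d, cov).area_deg2, rel=1e-6)

    def test_degenerate_dispersion_rejected(self):
        d = DispersionEstimate(0, 0, 0.0, 1.0, 0.0, 10, degenerate=True)
        with pytest.raises(ValueError):
            ellipse_contour(d, CoverageSpec.from_p(0.6827))


class TestPointInEllipseFraction:
    def test_all_points_at_mean(self):
        xy = np.tile([[1.0, 2.0]], (50, 1))
        d = DispersionEstimate(1.0, 2.0, 1.0, 1.0, 0.0, 50)
        e = ellipse_contour(d, CoverageSpec.from_k(1.0))
        assert point_in_ellipse_fraction(xy, e) == 1.0

    @pytest.mark.parametrize("p", [0.6827, 0.9545])
    def test_bivariate_normal_coverage(self, p):
        rng = np.random.default_rng(9)
        n = 50_000
        xy = rng.multivariate_normal([0, 0], [[1.8, -0.5], [-0.5, 1.1]], n)
        e = ellipse_contour(estimate_dispersion(xy), CoverageSpec.from_p(p))
        frac = point_in_ellipse_fraction(xy, e)
        assert abs(frac - p) < 3 * math.sqrt(p * (1 - p) / n)

    def test_empty_trace_rejected(self):
        d = DispersionEstimate(0, 0, 1.0, 1.0, 0.0, 10)
        e = ellipse_contour(d, CoverageSpec.from_k(1.0))
        with pytest.raises(ValueError):
            point_in_ellipse_fraction(np.empty((0, 2)), e)


class TestDeviationSummary:
    def test_all_samples_at_origin(self):
        s = deviation_summary(np.zeros((20, 2)))
        assert s.mean_dev_deg == 0.0
        assert all(v == 1.0 for v in s.frac_within.values())

    def test_two_sample_arithmetic(self):
        xy = np.array([[1.0, 0.0], [0.0, 3.0]])
        s = deviation_summary(xy)
        assert s.mean_dev_deg == pytest.approx(2.0)
        assert s.frac_within[2.0] == 0.5
        assert s.frac_within[4.0] == 1.0

    def test_rayleigh_mean_closed_form(self):
        rng = np.random.default_rng(3)
        sigma, n = 1.3, 100_000
        xy = rng.normal(0.0, sigma, size=(n, 2))
        s = deviation_summary(xy)
        expect = sigma * math.sqrt(math.pi / 2.0)
        se = sigma * math.sqrt((2.0 - math.pi / 2.0) / n)
        assert abs(s.mean_dev_deg - expect) < 3 * se

    def test_frac_within_monotone_and_histogram_sums_to_one(self):
        rng = np.random.default_rng(4)
        xy = rng.normal(0, 1.5, size=(5000, 2))
        s = deviation_summary(xy, thresholds=(0.5, 1, 2, 4, 8))
        fracs = [s.frac_within[t] for t in sorted(s.frac_within)]
        assert all(a <= b for a, b in zip(fracs, fracs[1:]))
        assert s.bin_proportions.sum() == pytest.approx(1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            deviation_summary(np.empty((0, 2)))


def test_metrics_record_shape():
    rng = np.random.default_rng(8)
    xy = rng.normal(0, 1, size=(500, 2))
    clean = CleanTrace(
        t=np.arange(500) / 50.0, x=xy[:, 0], y=xy[:, 1],
        n_total=500, n_removed_blink=0, n_removed_setup=0,
        condition="BF", phase="visual_field",
    )
    rec = metrics_record(clean)
    for key in ("bcea_1sd", "bcea_2sd", "bcea_3sd", "mean_dev_deg",
                "frac_within_2deg", "frac_within_4deg", "sigma_h", "rho"):
        assert key in rec
    assert rec["condition"] == "BF"
    assert rec["bcea_1sd"] < rec["bcea_2sd"] < rec["bcea_3sd"]
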