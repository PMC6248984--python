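"""Bivariate contour ellipse area (BCEA) and gaze-deviation statistics.

Fixation stability is summarised by the area of the ellipse that contains
a chosen proportion *p* of the gaze positions.  For bivariate-normal
scatter with per-axis standard deviations σH, σV and product–moment
correlation ρ, the iso-density ellipse at squared Mahalanobis radius 2k
contains the proportion

    p = 1 − exp(−k),

and its area is

    BCEA = 2·k·π·σH·σV·√(1 − ρ²) = 2·k·π·√(det Σ)   [deg²],

where Σ is the 2×2 positional covariance.  The three conventional coverage
levels correspond to the 1-, 2- and 3-SD probability masses of a univariate
normal: p = 0.6827, 0.9545, 0.9973.

Two different centres are used deliberately: the dispersion (and hence
BCEA) is centred on the mean gaze position, while gaze *deviation* metrics
measure distance from the fixation target at the origin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .preprocessing import CleanTrace

__all__ = [
    "DEFAULT_COVERAGES",
    "DEFAULT_THRESHOLDS_DEG",
    "CoverageSpec",
    "DispersionEstimate",
    "BceaResult",
    "Ellipse",
    "DeviationSummary",
    "k_from_p",
    "p_from_k",
    "estimate_dispersion",
    "bcea",
    "ellipse_contour",
    "point_in_ellipse_fraction",
    "deviation_summary",
    "metrics_record",
]

#: The 1-, 2- and 3-SD coverage proportions used throughout the analysis.
DEFAULT_COVERAGES = (0.6827, 0.9545, 0.9973)

#: Gaze-deviation thresholds (degrees) for the within-2°/4° frequencies.
DEFAULT_THRESHOLDS_DEG = (2.0, 4.0)

#: Column label suffix per default coverage level (Table-style "1SD" names).
COVERAGE_LABELS = {0.6827: "1sd", 0.9545: "2sd", 0.9973: "3sd"}


def k_from_p(p: float) -> float:
    """Ellipse scale k for coverage proportion p: k = −ln(1 − p).

    Raises ``ValueError`` unless 0 < p < 1.
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"coverage proportion must be in (0, 1), got {p}")
    return -math.log1p(-p)


def p_from_k(k: float) -> float:
    """Coverage proportion for ellipse scale k: p = 1 − e^(−k)."""
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    return -math.expm1(-k)


@dataclass(frozen=True)
class CoverageSpec:
    """A coverage proportion p and its ellipse scale k, p = 1 − e^(−k).

    Construct via :meth:`from_p` (the normal route) or :meth:`from_k`
    (replication of published k values that deviate from the relation is
    possible by constructing from k).
    """

    p: float
    k: float

    def __post_init__(self) -> None:
        if not 0.0 < self.p < 1.0:
            raise ValueError("p must be in (0, 1)")
        if self.k <= 0:
            raise ValueError("k must be positive")
        if abs(self.p - p_from_k(self.k)) > 1e-12:
            raise ValueError(
                f"p={self.p} and k={self.k} violate p = 1 - exp(-k); "
                "use from_p or from_k"
            )

    @classmethod
    def from_p(cls, p: float) -> "CoverageSpec":
        return cls(p=p, k=k_from_p(p))

    @classmethod
    def from_k(cls, k: float) -> "CoverageSpec":
        return cls(p=p_from_k(k), k=k)


@dataclass(frozen=True)
class DispersionEstimate:
    """Mean position and bivariate dispersion of retained gaze samples.

    σH and σV are the sample standard deviations (n−1 denominator) over
    the horizontal and vertical meridians; ρ is the product–moment
    correlation of the two positional components.  ``degenerate`` is set
    when an axis has zero variance, in which case ρ is reported as 0.
    """

    mean_h: float
    mean_v: float
    sigma_h: float
    sigma_v: float
    rho: float
    n: int
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("dispersion requires n >= 2 samples")
        if self.sigma_h < 0 or self.sigma_v < 0:
            raise ValueError("standard deviations must be non-negative")
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [-1, 1]")

    @property
    def covariance(self) -> np.ndarray:
        """The implied 2×2 positional covariance matrix Σ."""
        c = self.rho * self.sigma_h * self.sigma_v
        return np.array(
            [[self.sigma_h**2, c], [c, self.sigma_v**2]], dtype=float
        )


@dataclass(frozen=True)
class BceaResult:
    """Ellipse area (deg²) at one coverage level, with its inputs."""

    coverage: CoverageSpec
    area_deg2: float
    dispersion: DispersionEstimate


@dataclass(frozen=True)
class Ellipse:
    """An iso-density ellipse: centre, semi-axes and orientation.

    ``angle_rad`` is the counter-clockwise angle of the semi-major axis
    from +x, in (−π/2, π/2].
    """

    center: tuple[float, float]
    semi_major: float
    semi_minor: float
    angle_rad: float

    @property
    def area(self) -> float:
        return math.pi * self.semi_major * self.semi_minor

    def contour(self, n_points: int = 256) -> np.ndarray:
        """Polygon approximation of the contour, (n_points, 2)."""
        th = np.linspace(0.0, 2.0 * math.pi, n_points, endpoint=False)
        u = np.column_stack([self.semi_major * np.cos(th), self.semi_minor * np.sin(th)])
        c, s = math.cos(self.angle_rad), math.sin(self.angle_rad)
        rot = np.array([[c, -s], [s, c]])
        return u @ rot.T + np.asarray(self.center)


@dataclass(frozen=True)
class DeviationSummary:
    """Distance-from-target statistics of a cleaned trace.

    ``frac_within`` maps each threshold (deg) to the proportion of samples
    within that distance of the target; the histogram covers [0, max
    distance) in equal-width bins with proportions summing to 1.
    """

    mean_dev_deg: float
    frac_within: dict[float, float]
    bin_edges_deg: np.ndarray
    bin_proportions: np.ndarray


def _as_xy(trace) -> np.ndarray:
    if isinstance(trace, CleanTrace):
        return trace.xy
    return np.column_stack(
        [np.asarray(trace[0], float), np.asarray(trace[1], float)]
    ) if isinstance(trace, tuple) else np.asarray(trace, dtype=float)


def estimate_dispersion(trace) -> DispersionEstimate:
    """Estimate (mean, σH, σV, ρ) from retained samples.

    Accepts a :class:`~fixstab.preprocessing.CleanTrace` or an (n, 2)
    array.  Uses the n−1 denominator for the SDs.  Raises ``ValueError``
    for fewer than two samples; a zero-variance axis yields ρ = 0 with the
    degenerate flag set instead of an error.
    """
    xy = _as_xy(trace)
    if xy.ndim != 2 or xy.shape[1] != 2:
        raise ValueError("expected an (n, 2) array of positions")
    n = xy.shape[0]
    if n < 2:
        raise ValueError(f"need at least 2 samples to estimate dispersion, got {n}")
    mean = xy.mean(axis=0)
    sd = xy.std(axis=0, ddof=1)
    degenerate = bool(sd[0] == 0.0 or sd[1] == 0.0)
    if degenerate:
        rho = 0.0
    else:
        c = np.cov(xy[:, 0], xy[:, 1], ddof=1)[0, 1]
        rho = float(np.clip(c / (sd[0] * sd[1]), -1.0, 1.0))
    return DispersionEstimate(
        mean_h=float(mean[0]),
        mean_v=float(mean[1]),
        sigma_h=float(sd[0]),
        sigma_v=float(sd[1]),
        rho=rho,
        n=n,
        degenerate=degenerate,
    )


def bcea(disp: DispersionEstimate, coverage: CoverageSpec) -> BceaResult:
    """BCEA = 2kπ·σH·σV·√(1 − ρ²), equivalently 2kπ·√(det Σ)."""
    area = (
        2.0 * coverage.k * math.pi
        * disp.sigma_h * disp.sigma_v
        * math.sqrt(max(0.0, 1.0 - disp.rho**2))
    )
    return BceaResult(coverage=coverage, area_deg2=float(area), dispersion=disp)


def ellipse_contour(disp: DispersionEstimate, coverage: CoverageSpec) -> Ellipse:
    """The iso-density ellipse at squared Mahalanobis radius 2k.

    Its semi-axes are √(2k·λᵢ) along the eigenvectors of Σ, so its area
    equals the BCEA.  Raises ``ValueError`` for degenerate dispersion.
    """
    if disp.degenerate or disp.sigma_h == 0 or disp.sigma_v == 0 or abs(disp.rho) == 1:
        raise ValueError("ellipse is undefined for degenerate dispersion")
    evals, evecs = np.linalg.eigh(disp.covariance)
    # eigh returns ascending order: evals[1] is the major-axis variance
    major = math.sqrt(2.0 * coverage.k * evals[1])
    minor = math.sqrt(2.0 * coverage.k * evals[0])
    vx, vy = evecs[:, 1]
    angle = math.atan2(vy, vx)
    if angle <= -math.pi / 2:
        angle += math.pi
    elif angle > math.pi / 2:
        angle -= math.pi
    return Ellipse(
        center=(disp.mean_h, disp.mean_v),
        semi_major=major,
        semi_minor=minor,
        angle_rad=angle,
    )


def point_in_ellipse_fraction(trace, ellipse: Ellipse) -> float:
    """Fraction of samples lying inside (or on) the given ellipse."""
    xy = _as_xy(trace)
    if xy.shape[0] == 0:
        raise ValueError("cannot compute point fraction of an empty trace")
    d = xy - np.asarray(ellipse.center)
    c, s = math.cos(ellipse.angle_rad), math.sin(ellipse.angle_rad)
    # rotate into the ellipse frame, then scale axes to the unit circle
    u = d[:, 0] * c + d[:, 1] * s
    v = -d[:, 0] * s + d[:, 1] * c
    r2 = (u / ellipse.semi_major) ** 2 + (v / ellipse.semi_minor) ** 2
    return float(np.mean(r2 <= 1.0))


def deviation_summary(
    trace,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS_DEG,
    bin_width: float = 1.0,
) -> DeviationSummary:
    """Distance-from-target summary of a degree-unit cleaned trace.

    The target is at the origin by construction of the degree frame.
    Raises ``ValueError`` on an empty trace or non-positive bin width.
    """
    xy = _as_xy(trace)
    if xy.shape[0] == 0:
        raise ValueError("cannot summarise an empty trace")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    dist = np.hypot(xy[:, 0], xy[:, 1])
    frac = {float(th): float(np.mean(dist <= th)) for th in thresholds}
    upper = max(bin_width, float(np.ceil(dist.max() / bin_width)) * bin_width)
    edges = np.arange(0.0, upper + bin_width / 2, bin_width)
    counts, edges = np.histogram(dist, bins=edges)
    return DeviationSummary(
        mean_dev_deg=float(dist.mean()),
        frac_within=frac,
        bin_edges_deg=edges,
        bin_proportions=counts / dist.size,
    )


def metrics_record(
    clean: CleanTrace,
    coverages: tuple[float, ...] = DEFAULT_COVERAGES,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS_DEG,
) -> dict:
    """One flat per-trace record: dispersion, BCEA per coverage, deviations.

    This is the row format aggregated into the cohort table.  Degenerate
    traces yield BCEA 0 (flagged) so cohort pipelines can proceed.
    """
    if clean.is_empty or clean.n_retained < 2:
        raise ValueError("cleaned trace has fewer than 2 retained samples")
    disp = estimate_dispersion(clean)
    rec: dict = {
        "condition": clean.condition,
        "phase": clean.phase,
        "n": disp.n,
        "sigma_h": disp.sigma_h,
        "sigma_v": disp.sigma_v,
        "rho": disp.rho,
        "degenerate": disp.degenerate,
    }
    for p in coverages:
        cov = CoverageSpec.from_p(p)
        label = COVERAGE_LABELS.get(p, f"p{p:.4f}".replace("0.", ""))
        rec[f"bcea_{label}"] = bcea(disp, cov).area_deg2
    dev = deviation_summary(clean, thresholds=thresholds)
    rec["mean_dev_deg"] = dev.mean_dev_deg
    for th, fr in dev.frac_within.items():
        rec[f"frac_within_{th:g}deg"] = fr
    return rec
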