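"""Synthetic oculomotor traces and cohorts with analytic ground truth.

Trace model
-----------
Fixational gaze is simulated as a discrete-time mean-reverting (AR(1) /
Ornstein–Uhlenbeck) bivariate process — slow drift pulled back toward the
fixation point — superposed with Poisson-timed instantaneous jumps
(microsaccades, exponentially distributed amplitudes in uniformly random
directions) and white sensor noise.  The AR innovation covariance is
solved so that the *total* stationary covariance of the drift+jump process
equals the requested (σH, σV, ρ) exactly; ground truth is therefore
analytic, not empirical.  Blink gaps are inserted as runs of invalid
samples, and a leading setup segment with off-target gaze precedes the
measurement.  The trace is finally mapped to scene-camera pixels through
the calibration geometry, mirroring what the tracker exports.

Cohort model
------------
Per-participant summary metrics (BCEA and mean gaze deviation per
condition and phase) are drawn log-normally — these metrics are positive
with SDs comparable to their means — with moments matched in arithmetic
space and a Gaussian-copula correlation across conditions within each
participant.  Clinical covariates (near ocular position and fusional
amplitude, prism dioptres) are normal with a configurable latent
correlation to the visual-field BCEA.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .gaze_io import CalibrationGeometry, GazeTrace

__all__ = [
    "TraceSimConfig",
    "TraceGroundTruth",
    "CohortSimConfig",
    "TABLE_COHORT_PARAMS",
    "simulate_trace",
    "simulate_cohort",
]


@dataclass(frozen=True)
class TraceSimConfig:
    """Generator settings for one raw gaze trace.

    Defaults emulate the study's acquisition: 50 Hz sampling over a
    ~250–300 s visual-field test on a 1920×1080 scene camera, with
    fixational dispersion of order 1–1.5° per axis.

    Parameters
    ----------
    duration_s : float
        Measurement duration after the setup segment.
    sigma_h, sigma_v, rho : float
        Target stationary dispersion of the gaze process (degrees).
    drift_timescale_s : float
        Mean-reversion timescale of the drift component.
    microsaccade_rate_hz, microsaccade_amp_mean_deg : float
        Poisson rate and mean (exponential) amplitude of jump events.
    blink_rate_per_min, blink_dur_mean_ms, blink_dur_shape : float
        Poisson blink rate and gamma blink-duration parameters; durations
        are clipped to at least ``blink_dur_min_ms``.
    noise_sd_deg : float
        White sensor noise SD added to every valid sample.
    setup_s : float
        Leading setup segment length (off-target gaze, removed by
        preprocessing before analysis).
    fixation_offset_deg : (float, float)
        Mean gaze position relative to the target.
    """

    duration_s: float = 300.0
    rate_hz: float = 50.0
    sigma_h: float = 1.5
    sigma_v: float = 1.0
    rho: float = 0.4
    drift_timescale_s: float = 0.5
    microsaccade_rate_hz: float = 1.0
    microsaccade_amp_mean_deg: float = 0.3
    blink_rate_per_min: float = 12.0
    blink_dur_mean_ms: float = 250.0
    blink_dur_shape: float = 4.0
    blink_dur_min_ms: float = 120.0
    noise_sd_deg: float = 0.05
    setup_s: float = 10.0
    setup_offset_deg: tuple[float, float] = (6.0, 4.0)
    fixation_offset_deg: tuple[float, float] = (0.0, 0.0)
    geometry: CalibrationGeometry = field(default_factory=CalibrationGeometry)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "duration_s", "rate_hz", "sigma_h", "sigma_v", "drift_timescale_s",
            "microsaccade_rate_hz", "microsaccade_amp_mean_deg",
            "blink_rate_per_min", "blink_dur_mean_ms", "noise_sd_deg", "setup_s",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.rate_hz == 0 or self.duration_s == 0:
            raise ValueError("rate_hz and duration_s must be positive")
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [-1, 1]")


@dataclass(frozen=True)
class TraceGroundTruth:
    """What the generator actually programmed into a trace."""

    sigma_h: float
    sigma_v: float
    rho: float
    fixation_offset_deg: tuple[float, float]
    setup_window: tuple[float, float]
    blink_intervals: tuple[tuple[int, int], ...]  # half-open sample indices
    n_samples: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "sigma_h": self.sigma_h,
            "sigma_v": self.sigma_v,
            "rho": self.rho,
            "fixation_offset_deg": list(self.fixation_offset_deg),
            "setup_window": list(self.setup_window),
            "blink_intervals": [list(iv) for iv in self.blink_intervals],
            "n_samples": self.n_samples,
            "seed": self.seed,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def _target_covariance(cfg: TraceSimConfig) -> np.ndarray:
    c = cfg.rho * cfg.sigma_h * cfg.sigma_v
    return np.array([[cfg.sigma_h**2, c], [c, cfg.sigma_v**2]])


def simulate_trace(cfg: TraceSimConfig) -> tuple[GazeTrace, TraceGroundTruth]:
    """Generate one pixel-unit gaze trace plus its ground-truth record.

    The stationary covariance of the simulated drift+microsaccade process
    equals (σH, σV, ρ) by construction: the per-step jump covariance is
    subtracted from the AR(1) innovation covariance.  Raises
    ``ValueError`` when |ρ| > 1 or when the requested microsaccade
    activity alone exceeds the requested dispersion (innovation covariance
    not positive semi-definite).
    """
    rng = np.random.default_rng(cfg.seed)
    dt = 1.0 / cfg.rate_hz
    n_setup = int(round(cfg.setup_s * cfg.rate_hz))
    n_meas = int(round(cfg.duration_s * cfg.rate_hz))
    n = n_setup + n_meas
    t = np.arange(n) * dt

    sigma = _target_covariance(cfg)
    if cfg.drift_timescale_s > 0:
        a = float(np.exp(-dt / cfg.drift_timescale_s))
    else:
        a = 0.0

    # Per-step microsaccade covariance: rate·dt·E[A²]/2 per axis for
    # exponential amplitudes (E[A²] = 2·mean²) in uniform directions.
    jump_var = cfg.microsaccade_rate_hz * dt * cfg.microsaccade_amp_mean_deg**2
    q = (1.0 - a**2) * sigma - jump_var * np.eye(2)
    evals, evecs = np.linalg.eigh(q)
    if evals[0] < -1e-12:
        if cfg.sigma_h > 0 and cfg.sigma_v > 0:
            raise ValueError(
                "microsaccade variance exceeds the requested dispersion; "
                "reduce microsaccade_rate_hz or amplitude"
            )
        evals = np.clip(evals, 0.0, None)  # degenerate request: clamp to PSD
    evals = np.clip(evals, 0.0, None)

    # innovations: Gaussian drift noise + Poisson-timed jumps
    if evals[1] > 0:
        chol = evecs @ np.diag(np.sqrt(evals))
        w = rng.standard_normal((n_meas, 2)) @ chol.T
    else:
        w = np.zeros((n_meas, 2))
    n_jumps = rng.poisson(cfg.microsaccade_rate_hz * cfg.duration_s)
    if n_jumps and n_meas:
        steps = rng.integers(0, n_meas, size=n_jumps)
        amps = rng.exponential(cfg.microsaccade_amp_mean_deg, size=n_jumps)
        dirs = rng.uniform(0.0, 2.0 * np.pi, size=n_jumps)
        np.add.at(w[:, 0], steps, amps * np.cos(dirs))
        np.add.at(w[:, 1], steps, amps * np.sin(dirs))

    # AR(1) recursion x[k] = a·x[k-1] + w[k], stationary initial state
    if np.any(sigma):
        x0 = rng.multivariate_normal([0.0, 0.0], sigma)
    else:
        x0 = np.zeros(2)
    drift = np.empty((n_meas, 2))
    for axis in range(2):
        drift[:, axis], _ = lfilter([1.0], [1.0, -a], w[:, axis], zi=[a * x0[axis]])

    gaze = drift + np.asarray(cfg.fixation_offset_deg)
    if cfg.noise_sd_deg > 0:
        gaze = gaze + rng.normal(0.0, cfg.noise_sd_deg, size=(n_meas, 2))

    # setup segment: gaze parked off-target with mild wander
    off = np.asarray(cfg.setup_offset_deg)
    setup = off + rng.normal(0.0, 0.5 + cfg.noise_sd_deg, size=(n_setup, 2))

    x_deg = np.concatenate([setup[:, 0], gaze[:, 0]])
    y_deg = np.concatenate([setup[:, 1], gaze[:, 1]])
    valid = np.ones(n, dtype=bool)

    # blink gaps: Poisson starts within the measurement, non-overlapping
    blink_intervals: list[tuple[int, int]] = []
    n_blinks = rng.poisson(cfg.blink_rate_per_min * cfg.duration_s / 60.0)
    if n_blinks and n_meas:
        starts = np.sort(rng.uniform(0.0, cfg.duration_s, size=n_blinks))
        durs = rng.gamma(
            cfg.blink_dur_shape,
            cfg.blink_dur_mean_ms / cfg.blink_dur_shape,
            size=n_blinks,
        )
        durs = np.maximum(durs, cfg.blink_dur_min_ms) / 1000.0
        # keep gaps >= 10 samples apart so margin dilation cannot merge them
        min_sep = 10
        last_end = -np.inf
        for s_t, d_t in zip(starts, durs):
            i0 = n_setup + int(np.floor(s_t * cfg.rate_hz))
            i1 = i0 + max(1, int(round(d_t * cfg.rate_hz)))
            if i0 < last_end + min_sep or i1 > n:
                continue
            blink_intervals.append((i0, i1))
            valid[i0:i1] = False
            last_end = i1
    x_deg[~valid] = np.nan
    y_deg[~valid] = np.nan

    # degree → pixel mapping (inverse of pixels_to_degrees)
    g = cfg.geometry
    x_px = g.target_px[0] + x_deg / g.deg_per_px_h
    y_px = g.target_px[1] - y_deg / g.deg_per_px_v

    trace = GazeTrace(t=t, x=x_px, y=y_px, valid=valid, rate_hz=cfg.rate_hz,
                      units="pixels")
    truth = TraceGroundTruth(
        sigma_h=cfg.sigma_h,
        sigma_v=cfg.sigma_v,
        rho=cfg.rho,
        fixation_offset_deg=tuple(cfg.fixation_offset_deg),
        setup_window=(0.0, n_setup * dt),
        blink_intervals=tuple(blink_intervals),
        n_samples=n,
        seed=cfg.seed,
    )
    return trace, truth


# Per-condition (mean, SD) of the cohort metrics the analysis reports,
# keyed phase → metric → condition.  These are the study-scale defaults
# the generator reproduces: BCEA in deg² at the three coverage levels and
# mean gaze deviation in degrees.
TABLE_COHORT_PARAMS: dict[str, dict[str, dict[str, tuple[float, float]]]] = {
    "foveal_threshold": {
        "bcea_1sd": {"DEF": (1.75, 2.73), "N-DEF": (1.45, 1.51), "BF": (1.67, 2.62)},
        "bcea_2sd": {"DEF": (10.29, 13.37), "N-DEF": (8.80, 8.89), "BF": (9.52, 14.89)},
        "bcea_3sd": {"DEF": (18.44, 23.98), "N-DEF": (15.77, 15.95), "BF": (17.07, 26.69)},
        "mean_dev_deg": {"DEF": (0.92, 0.48), "N-DEF": (0.85, 0.38), "BF": (0.91, 0.69)},
    },
    "visual_field": {
        "bcea_1sd": {"DEF": (4.62, 3.38), "N-DEF": (5.24, 3.67), "BF": (2.85, 2.00)},
        "bcea_2sd": {"DEF": (27.73, 19.84), "N-DEF": (29.92, 19.79), "BF": (16.78, 11.09)},
        "bcea_3sd": {"DEF": (49.72, 35.58), "N-DEF": (53.66, 35.48), "BF": (30.10, 19.88)},
        "mean_dev_deg": {"DEF": (1.62, 0.64), "N-DEF": (1.69, 0.55), "BF": (1.22, 0.46)},
    },
}

#: Cohort covariate distributions (mean, SD): near ocular position and
#: fusional amplitude, both in prism dioptres.
COVARIATE_PARAMS = {"ocular_position_pd": (-7.5, 6.5), "fusional_amplitude_pd": (38.6, 15.1)}


@dataclass(frozen=True)
class CohortSimConfig:
    """Generator settings for a per-participant summary cohort.

    ``metric_params`` maps phase → metric → condition → (mean, SD) in
    arithmetic space; metrics are drawn log-normally with these moments.
    ``within_corr`` is the Gaussian-copula correlation of a metric across
    conditions within a participant; ``covariate_corr`` correlates the
    covariates' latent normals with the visual-field BCEA latent (0 = the
    no-association study finding).
    """

    n_participants: int = 35
    metric_params: dict = field(default_factory=lambda: TABLE_COHORT_PARAMS)
    within_corr: float = 0.5
    covariate_params: dict = field(default_factory=lambda: dict(COVARIATE_PARAMS))
    covariate_corr: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("need at least 2 participants")
        if not -1.0 <= self.within_corr <= 1.0:
            raise ValueError("within_corr must lie in [-1, 1]")
        if not -1.0 <= self.covariate_corr <= 1.0:
            raise ValueError("covariate_corr must lie in [-1, 1]")
        for phase, metrics in self.metric_params.items():
            for metric, conds in metrics.items():
                for cond, (mu, sd) in conds.items():
                    if mu <= 0 or sd < 0:
                        raise ValueError(
                            f"invalid (mean, SD) for {phase}/{metric}/{cond}"
                        )


def _lognormal_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """(μ, σ) of ln X for a log-normal with arithmetic mean and SD."""
    s2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - s2 / 2.0, np.sqrt(s2)


def simulate_cohort(cfg: CohortSimConfig) -> tuple[pd.DataFrame, dict]:
    """Draw a per-participant cohort table plus its ground-truth record.

    Returns a long-format frame with one row per (participant, condition,
    phase), metric columns per ``metric_params``, and per-participant
    covariate columns repeated on every row.  Raises ``ValueError`` if the
    implied latent correlation matrix is not positive semi-definite.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_participants
    conditions = sorted(
        {c for ms in cfg.metric_params.values() for cs in ms.values() for c in cs}
    )
    k = len(conditions)
    corr = np.full((k, k), cfg.within_corr)
    np.fill_diagonal(corr, 1.0)
    if np.linalg.eigvalsh(corr)[0] < -1e-12:
        raise ValueError("within-condition correlation matrix not positive semi-definite")
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(k))

    # latent normals per metric×phase, correlated across conditions
    latents: dict[tuple[str, str], np.ndarray] = {}
    for phase, metrics in cfg.metric_params.items():
        for metric in metrics:
            z = rng.standard_normal((n, k)) @ chol.T
            latents[(phase, metric)] = z

    # covariates share a latent with the visual-field BCEA when requested
    cov_vals: dict[str, np.ndarray] = {}
    anchor = latents.get(("visual_field", "bcea_1sd"))
    for name, (mu, sd) in cfg.covariate_params.items():
        zc = rng.standard_normal(n)
        if cfg.covariate_corr != 0.0 and anchor is not None:
            r = cfg.covariate_corr
            zc = r * anchor[:, conditions.index("BF") if "BF" in conditions else 0] \
                + np.sqrt(1 - r**2) * zc
        cov_vals[name] = mu + sd * zc

    rows = []
    for i in range(n):
        pid = f"P{i + 1:02d}"
        for ci, cond in enumerate(conditions):
            for phase, metrics in cfg.metric_params.items():
                row = {"participant": pid, "condition": cond, "phase": phase}
                for metric, conds in metrics.items():
                    mu, sd = conds[cond]
                    if sd == 0.0:
                        row[metric] = mu
                    else:
                        lmu, lsd = _lognormal_from_moments(mu, sd)
                        row[metric] = float(
                            np.exp(lmu + lsd * latents[(phase, metric)][i, ci])
                        )
                for name in cfg.covariate_params:
                    row[name] = float(cov_vals[name][i])
                rows.append(row)
    table = pd.DataFrame(rows)
    truth = {
        "metric_params": cfg.metric_params,
        "within_corr": cfg.within_corr,
        "covariate_params": dict(cfg.covariate_params),
        "covariate_corr": cfg.covariate_corr,
        "n_participants": n,
        "seed": cfg.seed,
    }
    return table, truth
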