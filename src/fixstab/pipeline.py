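"""End-to-end study analysis: traces in, cohort tables and reports out.

``run_study`` drives the full chain — read each gaze export, convert to
degrees, remove setup/blink data, compute per-trace fixation metrics,
aggregate to the cohort table, and emit the condition-comparison table,
gaze-deviation histograms and covariate correlations, plus a
machine-readable JSON report with provenance (config hash, package
versions, seed).

``replicate_from_supplementary`` recomputes the cohort summary from a
deposited per-participant spreadsheet instead of raw traces.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .fixation_metrics import (
    DEFAULT_COVERAGES,
    DEFAULT_THRESHOLDS_DEG,
    metrics_record,
)
from .gaze_io import CalibrationGeometry, GazeTrace, pixels_to_degrees, read_gaze_export
from .group_stats import CONDITION_PAIRS, compare_conditions, pearson_r
from .preprocessing import ExclusionPolicy, apply_exclusions, detect_blinks

__all__ = [
    "RunConfig",
    "StudyReport",
    "analyze_trace",
    "run_study",
    "write_cohort_xlsx",
    "DEFAULT_SUPPLEMENTARY_MAPPING",
    "replicate_from_supplementary",
]

_COVARIATE_COLS = ("ocular_position_pd", "fusional_amplitude_pd")


@dataclass
class RunConfig:
    """Configuration of one full study analysis run.

    ``manifest`` maps participant → condition → phase → trace file path.
    """

    manifest: dict
    geometry: CalibrationGeometry = field(default_factory=CalibrationGeometry)
    exclusion: ExclusionPolicy = field(default_factory=ExclusionPolicy)
    coverages: tuple[float, ...] = DEFAULT_COVERAGES
    thresholds_deg: tuple[float, ...] = DEFAULT_THRESHOLDS_DEG
    hist_bin_width_deg: float = 1.0
    hist_max_deg: float = 10.0
    covariate_file: str | None = None
    output_dir: str | None = None
    make_figures: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.manifest:
            raise ValueError("manifest is empty")
        for p in self.coverages:
            if not 0.0 < p < 1.0:
                raise ValueError(f"coverage level {p} outside (0, 1)")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        d = json.loads(Path(path).read_text())
        kwargs = dict(d)
        if "geometry" in d:
            kwargs["geometry"] = CalibrationGeometry.from_dict(d["geometry"])
        if "exclusion" in d:
            e = d["exclusion"]
            kwargs["exclusion"] = ExclusionPolicy(
                blink_margin_samples=int(e.get("blink_margin_samples", 2)),
                min_gap_ms=float(e.get("min_gap_ms", 100.0)),
                setup_window=tuple(tuple(w) for w in e.get("setup_window", ())),
            )
        for key in ("coverages", "thresholds_deg"):
            if key in d:
                kwargs[key] = tuple(d[key])
        return cls(**kwargs)

    def to_canonical_dict(self) -> dict:
        return {
            "manifest": self.manifest,
            "geometry": self.geometry.to_dict(),
            "exclusion": {
                "blink_margin_samples": self.exclusion.blink_margin_samples,
                "min_gap_ms": self.exclusion.min_gap_ms,
                "setup_window": [list(w) for w in self.exclusion.setup_window],
            },
            "coverages": list(self.coverages),
            "thresholds_deg": list(self.thresholds_deg),
            "hist_bin_width_deg": self.hist_bin_width_deg,
            "hist_max_deg": self.hist_max_deg,
            "covariate_file": self.covariate_file,
            "seed": self.seed,
        }


@dataclass
class StudyReport:
    """Everything ``run_study`` produces, in memory."""

    cohort: pd.DataFrame
    comparisons: pd.DataFrame
    histograms: pd.DataFrame
    correlations: pd.DataFrame
    cleaning: pd.DataFrame
    errors: list[dict]
    provenance: dict

    @property
    def ok(self) -> bool:
        return not self.errors

    def to_json_dict(self) -> dict:
        return {
            "provenance": self.provenance,
            "cohort": self.cohort.to_dict(orient="records"),
            "comparisons": self.comparisons.to_dict(orient="records"),
            "histograms": self.histograms.to_dict(orient="records"),
            "correlations": self.correlations.to_dict(orient="records"),
            "cleaning": self.cleaning.to_dict(orient="records"),
            "errors": self.errors,
        }


def analyze_trace(
    path: str | Path,
    geometry: CalibrationGeometry,
    policy: ExclusionPolicy,
    *,
    condition: str | None = None,
    phase: str | None = None,
    coverages: tuple[float, ...] = DEFAULT_COVERAGES,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS_DEG,
) -> tuple[dict, dict]:
    """Read, clean and summarise one trace file.

    Returns the flat metrics record and the cleaning report.
    """
    trace = read_gaze_export(path, condition=condition, phase=phase)
    deg = pixels_to_degrees(trace, geometry)
    blinks = detect_blinks(deg, policy)
    clean = apply_exclusions(deg, blinks, policy)
    rec = metrics_record(clean, coverages=coverages, thresholds=thresholds)
    return rec, clean.report()


def _deviation_histogram(clean_xy: np.ndarray, edges: np.ndarray) -> np.ndarray:
    dist = np.hypot(clean_xy[:, 0], clean_xy[:, 1])
    dist = np.clip(dist, None, edges[-1] - 1e-9)  # overflow into the last bin
    counts, _ = np.histogram(dist, bins=edges)
    return counts / max(1, dist.size)


def run_study(config: RunConfig) -> StudyReport:
    """Run the full analysis over the manifest.

    Unreadable or degenerate traces are collected as per-file errors and
    the run continues; callers decide what an acceptable error count is
    (the CLI exits 2 when any trace failed).
    """
    rows, cleaning_rows, errors, hist_rows = [], [], [], []
    edges = np.arange(
        0.0, config.hist_max_deg + config.hist_bin_width_deg / 2,
        config.hist_bin_width_deg,
    )
    for participant, by_cond in sorted(config.manifest.items()):
        for condition, by_phase in sorted(by_cond.items()):
            for phase, path in sorted(by_phase.items()):
                try:
                    trace = read_gaze_export(path, condition=condition, phase=phase)
                    deg = pixels_to_degrees(trace, config.geometry)
                    blinks = detect_blinks(deg, config.exclusion)
                    clean = apply_exclusions(deg, blinks, config.exclusion)
                    rec = metrics_record(
                        clean, coverages=config.coverages,
                        thresholds=config.thresholds_deg,
                    )
                except Exception as exc:  # collect and continue
                    errors.append(
                        {"participant": participant, "condition": condition,
                         "phase": phase, "file": str(path), "error": str(exc)}
                    )
                    continue
                rec["participant"] = participant
                rows.append(rec)
                cr = clean.report()
                cr.update(participant=participant, condition=condition, phase=phase)
                cleaning_rows.append(cr)
                props = _deviation_histogram(clean.xy, edges)
                hist_rows.append(
                    {"participant": participant, "condition": condition,
                     "phase": phase,
                     **{f"bin_{edges[i]:g}_{edges[i+1]:g}": props[i]
                        for i in range(len(props))}}
                )
    cohort = pd.DataFrame(rows)
    cleaning = pd.DataFrame(cleaning_rows)

    metric_cols = [
        c for c in cohort.columns
        if c.startswith(("bcea_", "mean_dev", "frac_within"))
    ] if len(cohort) else []

    if len(cohort):
        if config.covariate_file:
            cov = pd.read_csv(config.covariate_file)
            cohort = cohort.merge(cov, on="participant", how="left")
        comparisons = compare_conditions(
            cohort, metric_cols, CONDITION_PAIRS, allow_missing=True
        )
    else:
        comparisons = pd.DataFrame()

    # per condition × phase mean ± SD of the per-participant histograms
    hist_df = pd.DataFrame(hist_rows)
    hist_summary_rows = []
    if len(hist_df):
        bin_cols = [c for c in hist_df.columns if c.startswith("bin_")]
        for (condition, phase), sub in hist_df.groupby(["condition", "phase"]):
            row = {"condition": condition, "phase": phase, "n": len(sub)}
            for c in bin_cols:
                row[f"{c}_mean"] = float(sub[c].mean())
                row[f"{c}_sd"] = float(sub[c].std(ddof=1)) if len(sub) > 1 else 0.0
            hist_summary_rows.append(row)
    histograms = pd.DataFrame(hist_summary_rows)

    # covariate correlations during binocular fixation, per phase
    corr_rows = []
    if len(cohort):
        bf = cohort[cohort["condition"] == "BF"]
        covariates = [c for c in _COVARIATE_COLS if c in bf.columns]
        for phase, sub in bf.groupby("phase"):
            for metric in metric_cols:
                for covariate in covariates:
                    ok = sub[[metric, covariate]].dropna()
                    if len(ok) < 3:
                        continue
                    r, p, n = pearson_r(ok[metric], ok[covariate])
                    corr_rows.append(
                        {"phase": phase, "metric": metric,
                         "covariate": covariate, "r": r, "p": p, "n": n}
                    )
    correlations = pd.DataFrame(corr_rows)

    canon = json.dumps(config.to_canonical_dict(), sort_keys=True)
    provenance = {
        "package": "fixstab",
        "version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "config_sha256": hashlib.sha256(canon.encode()).hexdigest(),
        "seed": config.seed,
        "n_traces_ok": len(rows),
        "n_traces_failed": len(errors),
    }
    report = StudyReport(
        cohort=cohort, comparisons=comparisons, histograms=histograms,
        correlations=correlations, cleaning=cleaning, errors=errors,
        provenance=provenance,
    )
    if config.output_dir:
        _write_bundle(report, config)
    return report


def _write_bundle(report: StudyReport, config: RunConfig) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.cohort.to_csv(out / "cohort.csv", index=False)
    report.comparisons.to_csv(out / "comparisons.csv", index=False)
    report.histograms.to_csv(out / "deviation_histograms.csv", index=False)
    report.correlations.to_csv(out / "covariate_correlations.csv", index=False)
    report.cleaning.to_csv(out / "cleaning_report.csv", index=False)
    (out / "report.json").write_text(
        json.dumps(report.to_json_dict(), sort_keys=True, indent=1, default=float)
    )
    if config.make_figures and len(report.histograms):
        _plot_histograms(report.histograms, out / "deviation_histograms.png",
                         config.hist_bin_width_deg)


def _plot_histograms(histograms: pd.DataFrame, path: Path, bin_width: float) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    phases = sorted(histograms["phase"].unique())
    conditions = sorted(histograms["condition"].unique())
    bin_cols = [c for c in histograms.columns if c.endswith("_mean")]
    lefts = [float(c.split("_")[1]) for c in bin_cols]
    fig, axes = plt.subplots(
        len(phases), len(conditions),
        figsize=(3.2 * len(conditions), 2.6 * len(phases)),
        squeeze=False, sharey=True,
    )
    for i, phase in enumerate(phases):
        for j, cond in enumerate(conditions):
            ax = axes[i][j]
            sub = histograms[
                (histograms["phase"] == phase) & (histograms["condition"] == cond)
            ]
            if len(sub):
                ax.bar(lefts, sub.iloc[0][bin_cols].to_numpy(float),
                       width=bin_width, align="edge")
            ax.set_title(f"{cond} / {phase}", fontsize=8)
            if i == len(phases) - 1:
                ax.set_xlabel("gaze deviation (deg)")
            if j == 0:
                ax.set_ylabel("proportion")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# Layout written by write_cohort_xlsx: long format, one row per
# participant × condition × phase, metric columns by their cohort names.
DEFAULT_SUPPLEMENTARY_MAPPING = {
    "participant": "participant",
    "condition": "condition",
    "phase": "phase",
    "metrics": {
        "bcea_1sd": "bcea_1sd",
        "bcea_2sd": "bcea_2sd",
        "bcea_3sd": "bcea_3sd",
        "mean_dev_deg": "mean_dev_deg",
    },
}


def write_cohort_xlsx(table: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort table as a single-sheet spreadsheet."""
    pd.DataFrame(table).to_excel(path, index=False)


def replicate_from_supplementary(
    xlsx_path: str | Path,
    mapping: Mapping = DEFAULT_SUPPLEMENTARY_MAPPING,
    *,
    pairs: Sequence[tuple[str, str]] = CONDITION_PAIRS,
) -> dict:
    """Recompute the cohort summary from a deposited per-participant file.

    ``mapping`` names the participant/condition/phase columns and maps
    spreadsheet metric columns to cohort metric names; optional
    ``condition_labels``/``phase_labels`` dictionaries translate the
    spreadsheet's labels.  Returns ``{"means": DataFrame, "comparisons":
    DataFrame, "n_participants": int}`` where ``means`` holds the
    per-condition × phase mean ± SD of every mapped metric.

    Raises ``ValueError`` naming any mapped column absent from the file.
    """
    df = pd.read_excel(xlsx_path)
    required = [mapping["participant"], mapping["condition"], mapping["phase"]]
    required += list(mapping["metrics"])
    for col in required:
        if col not in df.columns:
            raise ValueError(f"supplementary file is missing mapped column {col!r}")
    table = pd.DataFrame(
        {
            "participant": df[mapping["participant"]],
            "condition": df[mapping["condition"]],
            "phase": df[mapping["phase"]],
        }
    )
    for src, dst in mapping["metrics"].items():
        table[dst] = pd.to_numeric(df[src], errors="coerce")
    for key, col in (("condition_labels", "condition"), ("phase_labels", "phase")):
        if key in mapping:
            table[col] = table[col].map(lambda v: mapping[key].get(v, v))
    metrics = list(mapping["metrics"].values())
    comparisons = compare_conditions(table, metrics, pairs, allow_missing=True)
    means = (
        table.groupby(["phase", "condition"])[metrics]
        .agg(["mean", "std"])
        .reset_index()
    )
    means.columns = [
        "_".join(c for c in col if c) if isinstance(col, tuple) else col
        for col in means.columns
    ]
    return {
        "means": means,
        "comparisons": comparisons,
        "n_participants": int(table["participant"].nunique()),
    }
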