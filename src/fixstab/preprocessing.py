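"""Blink and setup exclusion, and phase segmentation.

The analysis uses every retained gaze sample as fixation data; the only
cleaning steps are (a) removing sensor-loss runs long enough to be blinks,
with a small safety margin on each side to catch the partially-closed-lid
samples flanking a blink, and (b) removing explicitly declared setup
intervals (the tracker records before the test starts).  No interpolation
is performed — excluded samples are simply removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .gaze_io import GazeTrace

__all__ = [
    "ExclusionPolicy",
    "CleanTrace",
    "detect_blinks",
    "apply_exclusions",
    "segment_phases",
]


@dataclass(frozen=True)
class ExclusionPolicy:
    """Rules deciding which samples are removed before metric computation.

    Parameters
    ----------
    blink_margin_samples : int
        Samples removed on each side of every detected blink run
        (default 2, i.e. 40 ms at 50 Hz).
    min_gap_ms : float
        Minimum invalid-run duration treated as a blink (default 100 ms);
        shorter dropouts are still removed as invalid but are not dilated.
    setup_window : sequence of (t0, t1)
        Time intervals (seconds, half-open) flagged as setup and removed.
    """

    blink_margin_samples: int = 2
    min_gap_ms: float = 100.0
    setup_window: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if self.blink_margin_samples < 0:
            raise ValueError("blink_margin_samples must be >= 0")
        if self.min_gap_ms < 0:
            raise ValueError("min_gap_ms must be >= 0")
        object.__setattr__(
            self, "setup_window", tuple(tuple(map(float, w)) for w in self.setup_window)
        )


@dataclass
class CleanTrace:
    """Retained degree-unit samples plus exclusion bookkeeping.

    Invariant: ``n_total == n_retained + n_removed_blink + n_removed_setup``
    and every retained sample is valid.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    n_total: int
    n_removed_blink: int
    n_removed_setup: int
    units: str = "degrees"
    condition: str | None = None
    phase: str | None = None

    @property
    def n_retained(self) -> int:
        return int(self.t.size)

    @property
    def is_empty(self) -> bool:
        """True when no samples survived cleaning (downstream must check)."""
        return self.n_retained == 0

    @property
    def xy(self) -> np.ndarray:
        """Retained positions as an (n, 2) array."""
        return np.column_stack([self.x, self.y])

    def report(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_retained": self.n_retained,
            "n_removed_blink": self.n_removed_blink,
            "n_removed_setup": self.n_removed_setup,
        }


def _invalid_runs(valid: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of False in ``valid`` as half-open index intervals."""
    inv = ~np.asarray(valid, dtype=bool)
    if not inv.any():
        return []
    padded = np.concatenate([[False], inv, [False]]).astype(int)
    d = np.diff(padded)
    starts = np.nonzero(d == 1)[0]
    ends = np.nonzero(d == -1)[0]
    return list(zip(starts.tolist(), ends.tolist()))


def merge_intervals(intervals: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping/touching half-open intervals into a disjoint list."""
    if not intervals:
        return []
    ivs = sorted(intervals)
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(iv) for iv in out]


def detect_blinks(
    trace: GazeTrace, policy: ExclusionPolicy = ExclusionPolicy()
) -> list[tuple[int, int]]:
    """Locate blink intervals as dilated runs of invalid samples.

    A run of consecutive invalid samples whose duration (run length ×
    nominal sample period) is at least ``policy.min_gap_ms`` is a blink;
    each is widened by ``policy.blink_margin_samples`` on both sides,
    clipped to the trace bounds, and overlapping results are merged.
    Returns half-open ``[start, stop)`` sample-index intervals; an empty
    list when there are no blinks.
    """
    n = len(trace)
    period_ms = 1000.0 / trace.rate_hz
    m = policy.blink_margin_samples
    blinks = []
    for s, e in _invalid_runs(trace.valid):
        if (e - s) * period_ms >= policy.min_gap_ms:
            blinks.append((max(0, s - m), min(n, e + m)))
    return merge_intervals(blinks)


def apply_exclusions(
    trace: GazeTrace,
    blinks: Sequence[tuple[int, int]],
    policy: ExclusionPolicy = ExclusionPolicy(),
) -> CleanTrace:
    """Remove setup windows, blink intervals and stray invalid samples.

    Each sample is counted in exactly one category; when a sample falls in
    both a setup window and a blink interval it counts as setup.  Invalid
    samples outside any blink interval (dropouts shorter than the blink
    threshold) are removed too — retained samples are always valid — and
    are counted in the blink category as sensor loss.
    """
    n = len(trace)
    for s, e in blinks:
        if not (0 <= s <= e <= n):
            raise ValueError(f"blink interval ({s}, {e}) out of bounds for n={n}")
    in_setup = np.zeros(n, dtype=bool)
    for t0, t1 in policy.setup_window:
        in_setup |= (trace.t >= t0) & (trace.t < t1)
    in_blink = np.zeros(n, dtype=bool)
    for s, e in blinks:
        in_blink[s:e] = True
    in_blink |= ~trace.valid  # stray dropouts below the blink threshold
    in_blink &= ~in_setup  # setup takes precedence; count each sample once
    keep = ~(in_setup | in_blink)
    return CleanTrace(
        t=trace.t[keep],
        x=trace.x[keep],
        y=trace.y[keep],
        n_total=n,
        n_removed_blink=int(in_blink.sum()),
        n_removed_setup=int(in_setup.sum()),
        units=trace.units,
        condition=trace.condition,
        phase=trace.phase,
    )


def segment_phases(
    trace: GazeTrace, events: Sequence[tuple[float, str]]
) -> dict[str, GazeTrace]:
    """Partition a trace into phases at the given (time, phase) markers.

    Each marker opens a half-open interval that runs to the next marker
    (the last runs to the end of the trace).  Samples before the first
    marker are not assigned to any phase.  A marker beyond the trace span
    yields an empty segment for its phase.
    """
    times = [t for t, _ in events]
    if any(b < a for a, b in zip(times, times[1:])):
        raise ValueError("phase markers must be time-ordered")
    out: dict[str, GazeTrace] = {}
    bounds = times + [np.inf]
    for i, (t0, phase) in enumerate(events):
        t1 = bounds[i + 1]
        sel = np.nonzero((trace.t >= t0) & (trace.t < t1))[0]
        if sel.size:
            seg = trace.slice(int(sel[0]), int(sel[-1]) + 1)
        else:
            seg = trace.slice(0, 0)
        out[phase] = seg.with_labels(phase=phase)
    return out
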