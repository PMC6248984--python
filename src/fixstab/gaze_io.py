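"""Reading, writing and calibrating raw gaze traces.

Wearable eye trackers export gaze as one sample per row — a timestamp, an
(x, y) position in scene-camera pixels and a sensor-validity flag.  This
module parses such exports into :class:`GazeTrace` objects and converts
pixel coordinates into degrees of visual angle centred on the fixation
target, which is the coordinate frame every downstream fixation metric
expects.

Conventions
-----------
* Degree space puts the fixation target at the origin with +x rightward and
  +y upward.  Screen pixel y grows downward, so the vertical axis flips
  sign during conversion.
* The default export dialect is tab-separated with a header row and columns
  ``timestamp_s, gaze_x_px, gaze_y_px, validity`` (validity 1 = tracked,
  0 = lost).  Other vendor layouts are handled by remapping
  :class:`GazeDialect`.
* Timestamps are taken from the file; ``rate_hz`` is carried as metadata
  and used only where a nominal sample period is needed.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CONDITIONS",
    "PHASES",
    "GazeDialect",
    "GazeTrace",
    "CalibrationGeometry",
    "GazeFormatError",
    "GazeIntegrityError",
    "UnitError",
    "read_gaze_export",
    "write_gaze_export",
    "pixels_to_degrees",
]

#: Viewing conditions of the study design: dominant-eye, non-dominant-eye
#: and binocular fixation.
CONDITIONS = ("DEF", "N-DEF", "BF")

#: Measurement phases a perimetry session is segmented into.
PHASES = ("setup", "foveal_threshold", "visual_field")


class GazeFormatError(ValueError):
    """A gaze export file does not match the declared dialect."""


class GazeIntegrityError(ValueError):
    """A gaze export violates a structural invariant (e.g. time order)."""


class UnitError(ValueError):
    """An operation received a trace in the wrong unit system."""


@dataclass(frozen=True)
class GazeDialect:
    """Column mapping and delimiter of a delimited gaze export."""

    delimiter: str = "\t"
    time_col: str = "timestamp_s"
    x_col: str = "gaze_x_px"
    y_col: str = "gaze_y_px"
    valid_col: str = "validity"

    @property
    def columns(self) -> tuple[str, str, str, str]:
        return (self.time_col, self.x_col, self.y_col, self.valid_col)


DEFAULT_DIALECT = GazeDialect()


@dataclass
class GazeTrace:
    """A time-ordered stream of gaze samples in one unit system.

    Parameters
    ----------
    t : array of float
        Seconds from recording start, strictly increasing, non-negative.
    x, y : array of float
        Gaze position per sample.  NaN is allowed where ``valid`` is False.
    valid : array of bool
        Sensor validity flag per sample.
    rate_hz : float
        Nominal sampling rate (metadata; 50 Hz for the study hardware).
    units : {"pixels", "degrees"}
    condition : str or None
        Viewing condition label, one of :data:`CONDITIONS` when set.
    phase : str or None
        Measurement phase label, one of :data:`PHASES` when set.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray
    rate_hz: float = 50.0
    units: str = "pixels"
    condition: str | None = None
    phase: str | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = self.t.size
        if not (self.x.size == self.y.size == self.valid.size == n):
            raise ValueError("t, x, y and valid must have equal length")
        if n and (not np.all(np.isfinite(self.t)) or self.t[0] < 0):
            raise GazeIntegrityError("timestamps must be finite and non-negative")
        if n > 1:
            bad = np.nonzero(np.diff(self.t) <= 0)[0]
            if bad.size:
                raise GazeIntegrityError(
                    f"timestamps not strictly increasing at sample {bad[0] + 1}"
                )
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        if self.units not in ("pixels", "degrees"):
            raise ValueError(f"unknown units {self.units!r}")
        if self.condition is not None and self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.phase is not None and self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r}")

    def __len__(self) -> int:
        return int(self.t.size)

    @property
    def n(self) -> int:
        return len(self)

    @property
    def duration_s(self) -> float:
        """Elapsed time plus one nominal sample period (span of coverage)."""
        if not len(self):
            return 0.0
        return float(self.t[-1] - self.t[0]) + 1.0 / self.rate_hz

    def slice(self, start: int, stop: int) -> "GazeTrace":
        """Sub-trace over sample indices [start, stop)."""
        return replace(
            self,
            t=self.t[start:stop],
            x=self.x[start:stop],
            y=self.y[start:stop],
            valid=self.valid[start:stop],
        )

    def with_labels(
        self, condition: str | None = None, phase: str | None = None
    ) -> "GazeTrace":
        out = replace(self)
        if condition is not None:
            out.condition = condition
        if phase is not None:
            out.phase = phase
        return out


@dataclass(frozen=True)
class CalibrationGeometry:
    """Scene-camera pixel grid and the pixel→degree mapping.

    The mapping is a homogeneous linear scale per axis (``deg_per_px_h``,
    ``deg_per_px_v``): fixational excursions span only a few degrees, so a
    tangent mapping is deliberately out of scope.
    """

    width_px: int = 1920
    height_px: int = 1080
    target_px: tuple[float, float] = (960.0, 540.0)
    deg_per_px_h: float = 0.02
    deg_per_px_v: float = 0.02

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("pixel grid dimensions must be positive")
        if self.deg_per_px_h <= 0 or self.deg_per_px_v <= 0:
            raise ValueError("degree-per-pixel scale factors must be positive")
        tx, ty = self.target_px
        if not (0 <= tx <= self.width_px and 0 <= ty <= self.height_px):
            raise ValueError("target_px must lie within the pixel grid")

    def to_dict(self) -> dict:
        return {
            "width_px": self.width_px,
            "height_px": self.height_px,
            "target_px": list(self.target_px),
            "deg_per_px_h": self.deg_per_px_h,
            "deg_per_px_v": self.deg_per_px_v,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CalibrationGeometry":
        return cls(
            width_px=int(d["width_px"]),
            height_px=int(d["height_px"]),
            target_px=tuple(float(v) for v in d["target_px"]),
            deg_per_px_h=float(d["deg_per_px_h"]),
            deg_per_px_v=float(d["deg_per_px_v"]),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationGeometry":
        return cls.from_dict(json.loads(Path(path).read_text()))


def read_gaze_export(
    path: str | Path | io.IOBase,
    dialect: GazeDialect = DEFAULT_DIALECT,
    *,
    rate_hz: float = 50.0,
    condition: str | None = None,
    phase: str | None = None,
) -> GazeTrace:
    """Parse a delimited gaze export into a pixel-unit :class:`GazeTrace`.

    Rows whose coordinates fail to parse become invalid samples (NaN
    position, validity False) rather than being dropped, so sample counts
    and timing are preserved.

    Raises
    ------
    GazeFormatError
        If a required column is missing (the message names it).
    GazeIntegrityError
        If timestamps are not strictly increasing (the message gives the
        first offending sample index).
    """
    df = pd.read_csv(path, sep=dialect.delimiter)
    for col in dialect.columns:
        if col not in df.columns:
            raise GazeFormatError(f"missing required column {col!r}")
    t = pd.to_numeric(df[dialect.time_col], errors="raise").to_numpy(float)
    x = pd.to_numeric(df[dialect.x_col], errors="coerce").to_numpy(float)
    y = pd.to_numeric(df[dialect.y_col], errors="coerce").to_numpy(float)
    flag = pd.to_numeric(df[dialect.valid_col], errors="coerce").fillna(0)
    valid = (flag.to_numpy(float) != 0) & np.isfinite(x) & np.isfinite(y)
    x = np.where(valid, x, np.nan)
    y = np.where(valid, y, np.nan)
    return GazeTrace(
        t=t, x=x, y=y, valid=valid,
        rate_hz=rate_hz, units="pixels", condition=condition, phase=phase,
    )


def write_gaze_export(
    trace: GazeTrace,
    path: str | Path | io.IOBase,
    dialect: GazeDialect = DEFAULT_DIALECT,
) -> None:
    """Serialize a trace in the delimited dialect ``read_gaze_export`` accepts.

    Invalid samples are written with validity 0 and empty coordinate
    fields.  Raises ``ValueError`` on an empty trace.
    """
    if not len(trace):
        raise ValueError("refusing to write an empty trace")
    df = pd.DataFrame(
        {
            dialect.time_col: trace.t,
            dialect.x_col: trace.x,
            dialect.y_col: trace.y,
            dialect.valid_col: trace.valid.astype(int),
        }
    )
    df.to_csv(path, sep=dialect.delimiter, index=False, float_format="%.9g")


def pixels_to_degrees(trace: GazeTrace, geom: CalibrationGeometry) -> GazeTrace:
    """Convert a pixel-unit trace to degrees centred on the fixation target.

    ``x_deg = (x_px − target_x)·deg_per_px_h`` and
    ``y_deg = (target_y − y_px)·deg_per_px_v`` — the vertical sign flip
    turns screen coordinates (y down) into the vision-science convention
    (y up).  Validity flags and sample count are preserved.

    Raises :class:`UnitError` if the trace is already in degrees.
    """
    if trace.units == "degrees":
        raise UnitError("trace is already in degrees")
    tx, ty = geom.target_px
    return replace(
        trace,
        x=(trace.x - tx) * geom.deg_per_px_h,
        y=(ty - trace.y) * geom.deg_per_px_v,
        units="degrees",
    )
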