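"""Track data model, CSV I/O, and step geometry.

A *track* is the ordered sequence of landing positions recorded for one
tagged fly.  Internally all coordinates are local planar meters (x east,
y north) and all angles are math-convention radians, counter-clockwise
from the +x axis, wrapped to (-pi, pi].  Compass bearings (degrees
clockwise from north) appear only at the I/O boundary, in the ``polar``
CSV dialect that mirrors how steps are recorded in the field with a tape
and compass.

CSV dialects
------------
``xy``     columns: fly_id, obs_index, time_h, x_m, y_m, confirmed
``polar``  columns: fly_id, obs_index, time_h, step_m, bearing_deg, confirmed

In the polar dialect each row is one flight arriving at a new landing;
the row with ``obs_index == 0`` must carry ``step_m == 0`` and anchors
the fly at the origin (0, 0).  Subsequent rows displace the fly by
``step_m`` meters along ``bearing_deg``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ObservedFix",
    "MovementPath",
    "StepSeries",
    "wrap_angle",
    "read_tracks",
    "write_tracks",
    "derive_steps",
    "movement_rate",
]

XY_COLUMNS = ["fly_id", "obs_index", "time_h", "x_m", "y_m", "confirmed"]
POLAR_COLUMNS = ["fly_id", "obs_index", "time_h", "step_m", "bearing_deg", "confirmed"]

#: fixes closer than this (meters) are treated as no movement
DEFAULT_MIN_STEP = 0.05


def wrap_angle(a):
    """Wrap angle(s) to (-pi, pi]; a reversal maps to +pi."""
    a = np.asarray(a, dtype=float)
    w = np.mod(a, 2.0 * np.pi)
    w = np.where(w > np.pi, w - 2.0 * np.pi, w)
    # exact -pi (mod gives pi already) cannot occur; 0 stays 0
    if w.ndim == 0:
        return float(w)
    return w


@dataclass(frozen=True)
class ObservedFix:
    """One recorded landing position.

    ``confirmed`` distinguishes visually sighted landings from
    signal-only detections; every analysis treats the two alike, the
    flag is carried through for bookkeeping.
    """

    fly_id: str
    obs_index: int
    time_h: float
    x: float
    y: float
    confirmed: bool = True


@dataclass
class MovementPath:
    """Ordered fixes for one fly."""

    fly_id: str
    fixes: list[ObservedFix]
    experiment: str = "continuous"  # "continuous" or "periodic"

    @property
    def n_steps(self) -> int:
        return max(len(self.fixes) - 1, 0)

    def xy(self) -> np.ndarray:
        """(n_fixes, 2) array of positions."""
        return np.array([[f.x, f.y] for f in self.fixes], dtype=float)

    def times(self) -> np.ndarray:
        return np.array([f.time_h for f in self.fixes], dtype=float)

    def gross_length(self) -> float:
        p = self.xy()
        return float(np.sum(np.hypot(*np.diff(p, axis=0).T))) if len(p) > 1 else 0.0


@dataclass
class StepSeries:
    """Per-flight lengths, absolute headings, and wrapped turning angles.

    ``turning_angles[i]`` is ``headings[i+1] - headings[i]`` wrapped to
    (-pi, pi]; the first step has no turning angle, so
    ``len(turning_angles) == len(lengths) - 1``.  The missing first
    turning angle is *absent*, not zero.
    """

    lengths: np.ndarray
    headings: np.ndarray
    turning_angles: np.ndarray
    fly_id: str = ""
    empty: bool = False

    def __post_init__(self):
        self.lengths = np.asarray(self.lengths, dtype=float)
        self.headings = np.asarray(self.headings, dtype=float)
        self.turning_angles = np.asarray(self.turning_angles, dtype=float)

    @property
    def n_steps(self) -> int:
        return len(self.lengths)

    def positions(self, origin=(0.0, 0.0)) -> np.ndarray:
        """Reconstruct fix positions from lengths and headings."""
        dx = self.lengths * np.cos(self.headings)
        dy = self.lengths * np.sin(self.headings)
        xs = np.concatenate([[origin[0]], origin[0] + np.cumsum(dx)])
        ys = np.concatenate([[origin[1]], origin[1] + np.cumsum(dy)])
        return np.column_stack([xs, ys])


def _bearing_to_heading_rad(bearing_deg):
    """Compass bearing (deg CW from north) -> math heading (rad CCW from east)."""
    return wrap_angle(np.deg2rad(90.0 - np.asarray(bearing_deg, dtype=float)))


def _heading_to_bearing_deg(heading_rad):
    b = np.mod(90.0 - np.rad2deg(np.asarray(heading_rad, dtype=float)), 360.0)
    return b


def read_tracks(source: str | IO[str], dialect: str = "xy",
                experiment: str = "continuous") -> list[MovementPath]:
    """Read tracks from CSV in the ``xy`` or ``polar`` dialect.

    Raises ``ValueError`` on duplicate (fly_id, obs_index) pairs or
    non-monotone time within a fly, naming the offending row.
    """
    if dialect not in ("xy", "polar"):
        raise ValueError(f"unknown dialect {dialect!r}")
    cols = XY_COLUMNS if dialect == "xy" else POLAR_COLUMNS
    df = pd.read_csv(source, dtype={"fly_id": str})
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns for dialect {dialect!r}: {missing}")

    dup = df.duplicated(subset=["fly_id", "obs_index"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0]) + 2  # 1-based incl. header
        raise ValueError(f"duplicate (fly_id, obs_index) at CSV row {row}")

    paths: list[MovementPath] = []
    for fly_id, g in df.groupby("fly_id", sort=True):
        g = g.sort_values("obs_index")
        t = g["time_h"].to_numpy(dtype=float)
        if np.any(np.diff(t) < 0):
            i = int(np.flatnonzero(np.diff(t) < 0)[0])
            raise ValueError(
                f"non-monotone time for fly {fly_id!r} between obs "
                f"{int(g['obs_index'].iloc[i])} and {int(g['obs_index'].iloc[i + 1])}"
            )
        conf = g["confirmed"].astype(bool).to_numpy() if "confirmed" in g else np.ones(len(g), bool)
        if dialect == "xy":
            xs = g["x_m"].to_numpy(dtype=float)
            ys = g["y_m"].to_numpy(dtype=float)
        else:
            L = g["step_m"].to_numpy(dtype=float)
            h = _bearing_to_heading_rad(g["bearing_deg"].to_numpy(dtype=float))
            xs = np.cumsum(L * np.cos(h))
            ys = np.cumsum(L * np.sin(h))
        fixes = [
            ObservedFix(str(fly_id), int(oi), float(ti), float(x), float(y), bool(c))
            for oi, ti, x, y, c in zip(g["obs_index"], t, xs, ys, conf)
        ]
        paths.append(MovementPath(str(fly_id), fixes, experiment=experiment))
    return paths


def write_tracks(paths: Iterable[MovementPath], dest: str | IO[str],
                 dialect: str = "xy") -> None:
    """Write tracks as CSV; inverse of :func:`read_tracks`."""
    rows = []
    for p in paths:
        if dialect == "xy":
            for f in p.fixes:
                rows.append((f.fly_id, f.obs_index, f.time_h, f.x, f.y, f.confirmed))
        elif dialect == "polar":
            prev = None
            for f in p.fixes:
                if prev is None:
                    rows.append((f.fly_id, f.obs_index, f.time_h, 0.0, 0.0, f.confirmed))
                else:
                    dx, dy = f.x - prev.x, f.y - prev.y
                    L = math.hypot(dx, dy)
                    brg = _heading_to_bearing_deg(math.atan2(dy, dx)) if L > 0 else 0.0
                    rows.append((f.fly_id, f.obs_index, f.time_h, L, float(brg), f.confirmed))
                prev = f
        else:
            raise ValueError(f"unknown dialect {dialect!r}")
    cols = XY_COLUMNS if dialect == "xy" else POLAR_COLUMNS
    pd.DataFrame(rows, columns=cols).to_csv(dest, index=False)


def derive_steps(path: MovementPath, min_step: float = DEFAULT_MIN_STEP) -> StepSeries:
    """Derive step lengths, headings, and turning angles from a path.

    Consecutive fixes closer than ``min_step`` meters are merged into
    the earlier fix (position and time of the earlier fix are kept),
    since sub-resolution "moves" are measurement noise and zero-length
    steps leave the heading undefined.
    """
    if len(path.fixes) < 2:
        raise ValueError("need at least 2 fixes to derive steps")
    if min_step < 0:
        raise ValueError("min_step must be >= 0")
    kept = [path.fixes[0]]
    for f in path.fixes[1:]:
        last = kept[-1]
        if math.hypot(f.x - last.x, f.y - last.y) < min_step:
            continue
        kept.append(f)
    if len(kept) < 2:
        return StepSeries(np.empty(0), np.empty(0), np.empty(0),
                          fly_id=path.fly_id, empty=True)
    p = np.array([[f.x, f.y] for f in kept])
    d = np.diff(p, axis=0)
    lengths = np.hypot(d[:, 0], d[:, 1])
    headings = np.arctan2(d[:, 1], d[:, 0])
    headings = np.asarray(wrap_angle(headings))
    turning = np.asarray(wrap_angle(np.diff(headings)))
    return StepSeries(lengths, headings, turning, fly_id=path.fly_id)


def movement_rate(path: MovementPath) -> float:
    """Mean over consecutive fix pairs of distance moved / elapsed time (m/h)."""
    if len(path.fixes) < 2:
        raise ValueError("need at least 2 fixes")
    rates = []
    for a, b in zip(path.fixes[:-1], path.fixes[1:]):
        dt = b.time_h - a.time_h
        if dt <= 0:
            raise ValueError(
                f"zero or negative elapsed time between obs {a.obs_index} "
                f"and {b.obs_index} of fly {path.fly_id!r}"
            )
        rates.append(math.hypot(b.x - a.x, b.y - a.y) / dt)
    return float(np.mean(rates))
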