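"""Temporal covariate schedules z(t) for trap operation periods.

Each trap's operating interval (0, T_k] is tiled by half-open segments
(start, end] carrying a (possibly vector-valued) temporal covariate value.
For the canonical day/night analysis the covariate is a single binary
daytime indicator (z = 1 by day, 0 by night).  Piecewise-constant schedules
admit a closed-form time integral of the detection intensity; the model
layer relies on :meth:`Schedule.effective_durations` for that.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["Schedule", "ScheduleError", "build_day_night_schedule"]


class ScheduleError(ValueError):
    """Gap, overlap, or coverage failure in a temporal schedule."""


@dataclass
class Schedule:
    """Per-trap piecewise-constant temporal covariates.

    segments[k] is an (S_k, 2) array of (start, end] bounds and z[k] an
    (S_k, q) array of covariate values; together they must exactly tile
    (0, T_k].  q = 0 encodes a homogeneous process (γ(t) ≡ 1).
    """

    segments: list[np.ndarray]
    z: list[np.ndarray]

    def __post_init__(self) -> None:
        if len(self.segments) != len(self.z):
            raise ScheduleError("segments and z must have one entry per trap")
        self.segments = [np.atleast_2d(np.asarray(s, dtype=float)) for s in self.segments]
        q = None
        zz = []
        for k, (seg, zk) in enumerate(zip(self.segments, self.z)):
            zk = np.asarray(zk, dtype=float)
            if zk.ndim == 1:
                zk = zk[:, None]
            if q is None:
                q = zk.shape[1]
            elif zk.shape[1] != q:
                raise ScheduleError("temporal covariate dimension differs across traps")
            if seg.shape[0] != zk.shape[0]:
                raise ScheduleError(f"trap {k}: segment/covariate count mismatch")
            if seg.shape[0] == 0:
                raise ScheduleError(f"trap {k}: empty schedule")
            if not np.isclose(seg[0, 0], 0.0):
                raise ScheduleError(f"trap {k}: schedule must start at 0")
            if np.any(seg[:, 1] <= seg[:, 0]):
                raise ScheduleError(f"trap {k}: degenerate or reversed segment")
            if not np.allclose(seg[1:, 0], seg[:-1, 1]):
                raise ScheduleError(f"trap {k}: gap or overlap between segments")
            zz.append(zk)
        self.z = zz

    # -- constructors -------------------------------------------------------

    @classmethod
    def constant(cls, durations, z=None) -> "Schedule":
        """One segment per trap covering (0, T_k] with a fixed covariate.

        With ``z=None`` the covariate dimension is zero (homogeneous rate).
        """
        durations = np.atleast_1d(np.asarray(durations, dtype=float))
        q = 0 if z is None else np.atleast_1d(np.asarray(z, dtype=float)).size
        segs = [np.array([[0.0, t]]) for t in durations]
        if z is None:
            zs = [np.empty((1, 0)) for _ in durations]
        else:
            zrow = np.atleast_1d(np.asarray(z, dtype=float)).reshape(1, q)
            zs = [zrow.copy() for _ in durations]
        return cls(segs, zs)

    @classmethod
    def alternating_day_night(
        cls,
        durations,
        period: float = 1.0,
        day_fraction: float = 0.5,
        day_first: bool = True,
    ) -> "Schedule":
        """Alternating day/night segments with a binary daytime indicator.

        Every ``period`` time units contains ``day_fraction*period`` of
        daytime (z = 1); segments are truncated at T_k.
        """
        durations = np.atleast_1d(np.asarray(durations, dtype=float))
        if not 0.0 <= day_fraction <= 1.0:
            raise ScheduleError("day_fraction must be in [0, 1]")
        segs, zs = [], []
        for T in durations:
            bounds = [0.0]
            vals = []
            t = 0.0
            phase_day = day_first
            while t < T - 1e-12:
                frac = day_fraction if phase_day else 1.0 - day_fraction
                step = period * frac
                if step > 1e-12:
                    t2 = min(t + step, T)
                    bounds.append(t2)
                    vals.append(1.0 if phase_day else 0.0)
                    t = t2
                phase_day = not phase_day
            seg = np.column_stack([bounds[:-1], bounds[1:]])
            segs.append(seg)
            zs.append(np.array(vals)[:, None])
        return cls(segs, zs)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Schedule":
        """Build from a long table with columns trap_id, seg_start, seg_end, z1..zq."""
        zcols = sorted(
            (c for c in df.columns if c.startswith("z") and c[1:].isdigit()),
            key=lambda c: int(c[1:]),
        )
        segs, zs = [], []
        for _, grp in df.groupby("trap_id", sort=True):
            grp = grp.sort_values("seg_start")
            segs.append(grp[["seg_start", "seg_end"]].to_numpy(float))
            zs.append(grp[zcols].to_numpy(float) if zcols else np.empty((len(grp), 0)))
        return cls(segs, zs)

    # -- queries ------------------------------------------------------------

    @property
    def n_traps(self) -> int:
        return len(self.segments)

    @property
    def q(self) -> int:
        return self.z[0].shape[1]

    def durations(self) -> np.ndarray:
        return np.array([seg[-1, 1] for seg in self.segments])

    def z_at(self, k: int, times) -> np.ndarray:
        """Covariate values at given times for trap k ((S, q) -> (len(times), q))."""
        times = np.atleast_1d(np.asarray(times, dtype=float))
        seg = self.segments[k]
        if np.any(times <= 0) or np.any(times > seg[-1, 1] + 1e-9):
            raise ScheduleError(f"time outside (0, T_k] for trap {k}")
        # (start, end]: a time equal to a boundary belongs to the earlier segment
        idx = np.searchsorted(seg[:, 1], times, side="left")
        idx = np.minimum(idx, seg.shape[0] - 1)
        return self.z[k][idx]

    def flat(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(trap_index, segment_length, z) stacked over all traps' segments."""
        tidx = np.concatenate(
            [np.full(seg.shape[0], k) for k, seg in enumerate(self.segments)]
        )
        lens = np.concatenate([seg[:, 1] - seg[:, 0] for seg in self.segments])
        zmat = np.concatenate(self.z, axis=0)
        return tidx, lens, zmat

    def effective_durations(self, xi: np.ndarray) -> np.ndarray:
        """Per-trap ∫_0^{T_k} γ(t) dt = Σ_seg exp(ξ'z_seg)·len_seg.

        Equals T_k when ξ is empty or zero (homogeneous temporal process).
        """
        xi = np.atleast_1d(np.asarray(xi, dtype=float))
        if xi.size != self.q:
            raise ScheduleError(
                f"temporal-effect dimension {xi.size} != schedule covariate dimension {self.q}"
            )
        tidx, lens, zmat = self.flat()
        gamma = np.exp(zmat @ xi) if self.q else np.ones_like(lens)
        return np.bincount(tidx, weights=gamma * lens, minlength=self.n_traps)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k, (seg, zk) in enumerate(zip(self.segments, self.z)):
            for j in range(seg.shape[0]):
                row = {"trap_id": k, "seg_start": seg[j, 0], "seg_end": seg[j, 1]}
                for d in range(zk.shape[1]):
                    row[f"z{d + 1}"] = zk[j, d]
                rows.append(row)
        return pd.DataFrame(rows)


def build_day_night_schedule(sun_table: pd.DataFrame, deployments: pd.DataFrame) -> Schedule:
    """Alternating day/night schedule from sunrise/sunset times.

    Parameters
    ----------
    sun_table : DataFrame with columns date, sunrise, sunset
        One row per calendar date; times parseable by pandas (e.g. "06:00").
    deployments : DataFrame with columns trap_id, start, T
        ``start`` is the trap's deployment timestamp (ISO 8601); ``T`` its
        operating duration in days.  Trap-relative time is measured in days.

    The daytime indicator is z = 1 between sunrise and sunset.  The sun
    table must cover every date each trap operates.
    """
    sun = sun_table.copy()
    sun["date"] = pd.to_datetime(sun["date"]).dt.normalize()
    sun = sun.set_index("date").sort_index()

    segs, zs = [], []
    for _, row in deployments.sort_values("trap_id").iterrows():
        start = pd.to_datetime(row["start"])
        T = float(row["T"])
        end = start + pd.Timedelta(days=T)
        # collect day/night boundaries as absolute timestamps
        events = []  # (timestamp, z-after)
        date = start.normalize()
        while date < end + pd.Timedelta(days=1):
            if date not in sun.index:
                if date <= end - pd.Timedelta(seconds=1) and date >= start.normalize():
                    raise ScheduleError(f"sun table does not cover date {date.date()}")
                date += pd.Timedelta(days=1)
                continue
            srise = date + (pd.to_datetime(str(sun.loc[date, "sunrise"])) - pd.to_datetime("00:00"))
            sset = date + (pd.to_datetime(str(sun.loc[date, "sunset"])) - pd.to_datetime("00:00"))
            events.append((srise, 1.0))
            events.append((sset, 0.0))
            date += pd.Timedelta(days=1)
        events.sort(key=lambda e: e[0])
        # z value at the start of deployment
        z0 = 0.0
        for ts, zafter in events:
            if ts <= start:
                z0 = zafter
        bounds = [0.0]
        vals = []
        cur = z0
        for ts, zafter in events:
            if ts <= start or ts >= end:
                continue
            t_rel = (ts - start).total_seconds() / 86400.0
            bounds.append(t_rel)
            vals.append(cur)
            cur = zafter
        bounds.append(T)
        vals.append(cur)
        # merge zero-length segments
        seg = np.column_stack([bounds[:-1], bounds[1:]])
        keep = seg[:, 1] - seg[:, 0] > 1e-12
        segs.append(seg[keep])
        zs.append(np.asarray(vals)[keep, None])
    return Schedule(segs, zs)
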