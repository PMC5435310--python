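"""File readers/writers and run configuration.

Canonical plain-text schemas (all CSV with headers):

* grid:        cell_id, x, y, mask, v1..vp
* traps:       trap_id, x, y, T, w1..wp  (optional ``start`` ISO timestamp)
* detections:  individual_id, trap_id, time  — long format, one row per
               detection, trap-relative time; alternatively a ``timestamp``
               column (ISO 8601) converted using the trap's ``start``
* schedule:    trap_id, seg_start, seg_end, z1..zq
* chain:       iteration, parameter, value (tidy)
* map:         cell_id, x, y, mean, lo, hi

The long detection file is the primary data store; the n×K count matrix is
always derived from it, never stored.  Internal time is trap-relative and
continuous (days for timestamped data), which avoids discretization
artifacts such as the midnight problem.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
import yaml

from .geometry import Domain, TrapArray, read_grid_csv, read_traps_csv
from .model import DataError, SurveyData
from .predict import AbundanceMap
from .sampler import PosteriorChain
from .schedule import Schedule, build_day_night_schedule  # noqa: F401  (re-export)

__all__ = [
    "RunConfig",
    "parse_survey",
    "read_detections_csv",
    "write_detections_csv",
    "write_schedule_csv",
    "read_schedule_csv",
    "write_chain_csv",
    "read_chain_csv",
    "write_map_csv",
    "write_manifest",
    "build_day_night_schedule",
]


@dataclass
class RunConfig:
    """Flat configuration for a fitting run (YAML key-value file)."""

    grid: str
    traps: str
    detections: str
    schedule: str | None = None
    model: str = "full"
    iterations: int = 1200
    burn_in: int = 200
    coef_prior_sd: float = 10.0
    sigma_max: float | None = None
    map_resolution: float | None = None
    seed: int | None = None
    output: str = "."

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if cfg.model not in ("full", "restricted"):
            raise ValueError("model must be 'full' or 'restricted'")
        if cfg.model == "full" and cfg.schedule is None:
            raise ValueError(
                "full model requires a schedule file (or fit the restricted model)"
            )
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)


def read_detections_csv(path, traps: TrapArray, trap_starts=None) -> SurveyData:
    """Build a SurveyData from a long-format detection file.

    Individuals are indexed in order of first appearance.  Each time is
    validated against its trap's (0, T_k]; errors name the offending rows.
    """
    df = pd.read_csv(path)
    if df.empty:
        return SurveyData(traps, [])
    if "time" not in df.columns and "timestamp" in df.columns:
        if trap_starts is None:
            raise DataError(
                "timestamped detections require trap deployment start times"
            )
        starts = pd.to_datetime(pd.Series(trap_starts, index=traps.ids))
        ts = pd.to_datetime(df["timestamp"])
        df = df.copy()
        df["time"] = [
            (t - starts[tid]).total_seconds() / 86400.0
            for t, tid in zip(ts, df["trap_id"])
        ]
    required = {"individual_id", "trap_id", "time"}
    if not required.issubset(df.columns):
        raise DataError(f"detection file must contain columns {sorted(required)}")
    trap_pos = {tid: k for k, tid in enumerate(traps.ids)}
    bad = [i + 2 for i, tid in enumerate(df["trap_id"]) if tid not in trap_pos]
    if bad:
        raise DataError(f"unknown trap_id at detection file rows {bad[:10]}")
    kidx = df["trap_id"].map(trap_pos).to_numpy()
    t = df["time"].to_numpy(float)
    bad = [
        int(i) + 2
        for i in np.where((t <= 0) | (t > traps.durations[kidx] + 1e-9))[0]
    ]
    if bad:
        raise DataError(
            f"detection time outside the trap's (0, T_k] at rows {bad[:10]}"
        )
    order: list = []
    seen = set()
    for ind in df["individual_id"]:
        if ind not in seen:
            seen.add(ind)
            order.append(ind)
    K = traps.n_traps
    times = [[[] for _ in range(K)] for _ in order]
    pos = {ind: i for i, ind in enumerate(order)}
    for ind, k, tt in zip(df["individual_id"], kidx, t):
        times[pos[ind]][k].append(tt)
    times = [[np.sort(np.asarray(row_k)) for row_k in row] for row in times]
    return SurveyData(traps, times, ids=order)


def write_detections_csv(data: SurveyData, path) -> None:
    rows = []
    for i, row in enumerate(data.times):
        for k, t in enumerate(row):
            for tt in t:
                rows.append(
                    {
                        "individual_id": data.ids[i],
                        "trap_id": data.traps.ids[k],
                        "time": tt,
                    }
                )
    pd.DataFrame(rows, columns=["individual_id", "trap_id", "time"]).to_csv(
        path, index=False
    )


def write_schedule_csv(schedule: Schedule, path) -> None:
    schedule.to_frame().to_csv(path, index=False)


def read_schedule_csv(path) -> Schedule:
    return Schedule.from_frame(pd.read_csv(path))


def parse_survey(
    trap_path, detection_path, schedule_path=None, grid_path=None
) -> tuple[Domain | None, TrapArray, SurveyData, Schedule | None]:
    """Read the full survey bundle from the canonical CSV files."""
    traps = read_traps_csv(trap_path)
    domain = read_grid_csv(grid_path) if grid_path is not None else None
    trap_starts = None
    tdf = pd.read_csv(trap_path)
    if "start" in tdf.columns:
        trap_starts = tdf.set_index("trap_id")["start"]
    data = read_detections_csv(detection_path, traps, trap_starts=trap_starts)
    schedule = read_schedule_csv(schedule_path) if schedule_path is not None else None
    if schedule is not None:
        if schedule.n_traps != traps.n_traps:
            raise DataError("schedule must cover every trap")
        if not np.allclose(schedule.durations(), traps.durations, rtol=1e-6):
            raise DataError("schedule segments must exactly tile each trap's (0, T_k]")
    return domain, traps, data, schedule


def write_chain_csv(chain: PosteriorChain, path) -> None:
    chain.to_frame().to_csv(path, index=False)


def read_chain_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_map_csv(amap: AbundanceMap, path) -> None:
    amap.to_frame().to_csv(path, index=False)


def write_manifest(path, *, config: dict, seed, acceptance: dict, extra: dict | None = None) -> None:
    """JSON run manifest: config echo, seed, config hash, acceptance rates."""
    payload = {
        "config": config,
        "seed": seed,
        "config_hash": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest()[:16],
        "acceptance_rates": acceptance,
    }
    if extra:
        payload.update(extra)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=float)
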