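"""Per-minute-standardised behaviour variables from event logs.

The test room is divided into a 4 × 4 grid of 16 zones (ids 1–16, row-major
from the entrance wall).  Two doors face each other on the side walls: the
conspecifics' door (C) on the left and the human's door (H) on the right.
"Near a door" means occupying one of the (configurable) grid zones touching
that door's wall segment.

Six variables are computed per piglet × trial × phase, each relative to the
*upcoming* partner's door, plus the two door-specific occupancy times kept
separately for the door-preference analysis.  Time and count variables are
standardised per minute (× 60 / phase duration); the average time per zone
stays in seconds (phase duration / number of distinct zones visited).
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = ["ZoneMap", "DEFAULT_ZONE_MAP", "standardize_behaviours", "BEHAVIOUR_VARIABLES"]

BEHAVIOUR_VARIABLES = (
    "freezing_time",
    "avg_time_per_zone",
    "n_zones_explored",
    "watch_door_time",
    "watch_door_count",
    "near_door_time",
)


@dataclass
class ZoneMap:
    """16-zone grid with door-adjacent zone sets (configurable)."""

    n_zones: int = 16
    near_c: tuple[int, ...] = (5, 9)   # left-wall zones touching the C door
    near_h: tuple[int, ...] = (8, 12)  # right-wall zones touching the H door

    def __post_init__(self) -> None:
        zones = set(range(1, self.n_zones + 1))
        if not set(self.near_c) <= zones or not set(self.near_h) <= zones:
            raise ValueError("door-adjacent zones must be valid zone ids")
        if set(self.near_c) & set(self.near_h):
            raise ValueError("a zone cannot touch both doors")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ZoneMap":
        cfg = yaml.safe_load(Path(path).read_text())
        return cls(
            n_zones=cfg.get("n_zones", 16),
            near_c=tuple(cfg["near_c"]),
            near_h=tuple(cfg["near_h"]),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(
                {
                    "n_zones": self.n_zones,
                    "near_c": list(self.near_c),
                    "near_h": list(self.near_h),
                }
            )
        )


DEFAULT_ZONE_MAP = ZoneMap()


def _check_bounds(events: pd.DataFrame, duration: float) -> None:
    if (events["start_s"] < -1e-9).any() or (events["stop_s"] > duration + 1e-9).any():
        bad = events[
            (events["start_s"] < -1e-9) | (events["stop_s"] > duration + 1e-9)
        ].iloc[0]
        raise ValueError(
            f"event [{bad.start_s}, {bad.stop_s}] outside phase of {duration} s"
        )


def standardize_behaviours(
    events: pd.DataFrame,
    phases: pd.DataFrame,
    zone_map: ZoneMap | None = None,
) -> pd.DataFrame:
    """Build the behaviour-record table from an event log.

    ``events`` columns: piglet, trial, phase, event_type ∈ {zone, watch_c,
    watch_h, freeze}, start_s, stop_s, zone_id (zone events only).
    ``phases`` columns: piglet, trial, phase, duration_s, partner (plus any
    further design keys, carried through).

    A zone counts as explored from the moment its occupancy event starts.
    Simultaneous states (e.g. freezing while watching) are independent
    channels and may overlap.
    """
    zone_map = zone_map or DEFAULT_ZONE_MAP
    valid_zones = set(range(1, zone_map.n_zones + 1))
    near_c = set(zone_map.near_c)
    near_h = set(zone_map.near_h)

    grouped = dict(tuple(events.groupby(["piglet", "trial", "phase"])))
    rows = []
    for ph in phases.itertuples():
        key = (ph.piglet, ph.trial, ph.phase)
        dur = float(ph.duration_s)
        if dur <= 0:
            raise ValueError(f"non-positive phase duration for {key}")
        ev = grouped.get(key)
        if ev is None:
            ev = events.iloc[0:0]
        _check_bounds(ev, dur)
        per_min = 60.0 / dur

        zones = ev[ev["event_type"] == "zone"]
        zone_ids = zones["zone_id"].astype(int)
        if not set(zone_ids) <= valid_zones:
            bad = sorted(set(zone_ids) - valid_zones)
            raise ValueError(f"unknown zone id(s) {bad} for {key}")
        zdur = (zones["stop_s"] - zones["start_s"]).to_numpy()
        n_zones = int(zone_ids.nunique())
        time_near_c = float(zdur[zone_ids.isin(near_c)].sum())
        time_near_h = float(zdur[zone_ids.isin(near_h)].sum())

        freezes = ev[ev["event_type"] == "freeze"]
        freeze_time = float((freezes["stop_s"] - freezes["start_s"]).sum())

        upcoming = "watch_c" if ph.partner == "C" else "watch_h"
        watches = ev[ev["event_type"] == upcoming]
        watch_time = float((watches["stop_s"] - watches["start_s"]).sum())
        watch_count = int(len(watches))

        near_door = time_near_c if ph.partner == "C" else time_near_h
        rows.append(
            {
                "piglet": ph.piglet,
                "trial": ph.trial,
                "phase": ph.phase,
                "phase_duration_s": dur,
                "freezing_time": freeze_time * per_min,
                "avg_time_per_zone": dur / n_zones if n_zones else np.nan,
                "n_zones_explored": n_zones * per_min,
                "watch_door_time": watch_time * per_min,
                "watch_door_count": watch_count * per_min,
                "near_door_time": near_door * per_min,
                "near_c_door_time": time_near_c * per_min,
                "near_h_door_time": time_near_h * per_min,
            }
        )
    records = pd.DataFrame(rows)
    extra = [c for c in phases.columns if c not in records.columns]
    return records.merge(
        phases[["piglet", "trial", "phase", *extra]],
        on=["piglet", "trial", "phase"],
        how="left",
    )
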