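"""Intake and chamber-occupancy summaries on the zeitgeber clock.

Timestamps are seconds from experiment start, which coincides with lights-on,
so zeitgeber time (ZT: hours since lights-on, ZT0-12 light, ZT12-24 dark
under a 12:12 cycle) is plain modular arithmetic.  Intake is normalised to
body weight as ml/kg: (volume_ul / 1000) / (body_weight_g / 1000), i.e.
microlitres per gram.

All aggregations are zero-filled over the full (animal x substance x bin)
grid so heat-map matrices are dense and group means are over all animals,
and all of them conserve total volume / total chamber time exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stream_io import UNASSIGNED

__all__ = [
    "GRANULARITIES",
    "zt_of",
    "aggregate_intake",
    "chamber_occupancy",
    "heatmap_matrix",
    "to_matrix",
]

GRANULARITIES = ("total", "day", "phase", "day_zt")

SECONDS_PER_HOUR = 3600.0
SECONDS_PER_DAY = 86400.0


def zt_of(t_sec, lights_on_hour: float = 6.0):
    """Map seconds-from-start to (day index, ZT hour, phase).

    The experiment starts at lights-on (= ZT0), so ZT = (t / 3600) mod 24
    regardless of ``lights_on_hour`` (kept as a parameter because it anchors
    the wall-clock interpretation).  Day index is 1 + floor(t / 24 h); light
    phase is ZT [0, 12), dark is ZT [12, 24).  Accepts scalars or arrays.
    """
    t = np.asarray(t_sec, dtype=float)
    if (t < 0).any():
        raise ValueError("timestamps must be nonnegative")
    day = (t // SECONDS_PER_DAY).astype(int) + 1
    zt = (t / SECONDS_PER_HOUR) % 24.0
    zt_hour = np.floor(zt).astype(int)
    phase = np.where(zt_hour < 12, "light", "dark")
    if np.isscalar(t_sec):
        return int(day), int(zt_hour), str(phase[()])
    return day, zt_hour, phase


def _category_frame(stations: pd.DataFrame | None, events: pd.DataFrame) -> pd.DataFrame:
    src = stations if stations is not None else events
    cats = src[["substance", "dose_label"]].drop_duplicates()
    return cats.sort_values(["substance", "dose_label"], ignore_index=True)


def _bin_index(granularity: str, n_days: int) -> pd.DataFrame:
    if granularity == "total":
        return pd.DataFrame({"bin": ["total"]})
    if granularity == "day":
        return pd.DataFrame({"day": np.arange(1, n_days + 1)})
    if granularity == "phase":
        return pd.DataFrame({"phase": ["light", "dark"]})
    if granularity == "day_zt":
        grid = [(d, z) for d in range(1, n_days + 1) for z in range(24)]
        return pd.DataFrame(grid, columns=["day", "zt"])
    raise ValueError(f"unknown granularity {granularity!r}; use one of {GRANULARITIES}")


def aggregate_intake(
    events: pd.DataFrame,
    roster: pd.DataFrame,
    granularity: str = "total",
    stations: pd.DataFrame | None = None,
    n_days: int | None = None,
) -> pd.DataFrame:
    """Sum attributed drink volumes per animal x substance/dose x time bin.

    UNASSIGNED events are excluded.  The output grid is the full cross
    product of roster tags, substance/dose categories (from ``stations`` if
    given, else from the events) and time bins, zero-filled.  Columns:
    tag, substance, dose_label, the bin columns for the granularity,
    ``volume_ul`` and ``normalized_ml_per_kg``.
    """
    ev = events[events["tag"] != UNASSIGNED].copy()
    unknown = set(ev["tag"]) - set(roster["tag"])
    if unknown:
        raise ValueError(f"events with tags missing from roster: {sorted(unknown)}")
    if granularity not in GRANULARITIES:
        raise ValueError(f"unknown granularity {granularity!r}; use one of {GRANULARITIES}")

    if n_days is None:
        n_days = int(ev["t_sec"].max() // SECONDS_PER_DAY) + 1 if len(ev) else 1
    if len(ev):
        day, zt, phase = zt_of(ev["t_sec"].to_numpy())
        ev["day"], ev["zt"], ev["phase"] = day, zt, phase
    else:
        ev["day"] = pd.Series(dtype=int)
        ev["zt"] = pd.Series(dtype=int)
        ev["phase"] = pd.Series(dtype=str)
    ev["bin"] = "total"

    bin_cols = list(_bin_index(granularity, n_days).columns)
    grouped = (
        ev.groupby(["tag", "substance", "dose_label", *bin_cols], observed=True)["volume_ul"]
        .sum()
        .reset_index()
    )

    cats = _category_frame(stations, events)
    grid = (
        roster[["tag", "body_weight_g"]]
        .merge(cats, how="cross")
        .merge(_bin_index(granularity, n_days), how="cross")
    )
    out = grid.merge(grouped, on=["tag", "substance", "dose_label", *bin_cols], how="left")
    out["volume_ul"] = out["volume_ul"].astype(float).fillna(0.0)
    out["normalized_ml_per_kg"] = out["volume_ul"] / out["body_weight_g"]
    return out.drop(columns="body_weight_g")


def chamber_occupancy(bouts: pd.DataFrame, granularity: str = "day_zt",
                      n_days: int | None = None) -> pd.DataFrame:
    """Seconds in the drinking chambers (and visit counts) per animal x bin.

    A bout spanning a bin boundary contributes its exact overlap to each bin
    (so total seconds are conserved under any splitting of bouts); the visit
    count goes to the bin containing the bout start.
    """
    if granularity not in GRANULARITIES:
        raise ValueError(f"unknown granularity {granularity!r}; use one of {GRANULARITIES}")
    if len(bouts) and not bouts["t_start"].is_monotonic_increasing:
        raise ValueError("bouts must be sorted by t_start")
    if n_days is None:
        n_days = int(bouts["t_end"].max() // SECONDS_PER_DAY) + 1 if len(bouts) else 1

    if bouts.empty:
        cols = ["tag", *list(_bin_index(granularity, n_days).columns), "seconds", "visits"]
        out = pd.DataFrame(columns=cols)
        out["seconds"] = out["seconds"].astype(float)
        out["visits"] = out["visits"].astype(int)
        return out

    rows = []
    for tag, t0, t1 in bouts[["tag", "t_start", "t_end"]].itertuples(index=False):
        first = int(t0 // SECONDS_PER_HOUR)
        last = int(t1 // SECONDS_PER_HOUR)
        for h in range(first, last + 1):
            lo = max(t0, h * SECONDS_PER_HOUR)
            hi = min(t1, (h + 1) * SECONDS_PER_HOUR)
            if hi > lo or (t0 == t1 and h == first):
                rows.append((tag, h, hi - lo, 1 if h == first else 0))
    per_hour = pd.DataFrame(rows, columns=["tag", "abs_hour", "seconds", "visits"])

    tags = pd.DataFrame({"tag": sorted(bouts["tag"].unique())})
    if per_hour.empty:
        per_hour = pd.DataFrame(columns=["tag", "abs_hour", "seconds", "visits"])
        per_hour["abs_hour"] = per_hour["abs_hour"].astype(int)
    per_hour["day"] = per_hour["abs_hour"] // 24 + 1
    per_hour["zt"] = per_hour["abs_hour"] % 24
    per_hour["phase"] = np.where(per_hour["zt"] < 12, "light", "dark")
    per_hour["bin"] = "total"

    bin_cols = list(_bin_index(granularity, n_days).columns)
    grouped = (
        per_hour.groupby(["tag", *bin_cols], observed=True)[["seconds", "visits"]]
        .sum()
        .reset_index()
    )
    grid = tags.merge(_bin_index(granularity, n_days), how="cross")
    out = grid.merge(grouped, on=["tag", *bin_cols], how="left")
    out[["seconds", "visits"]] = out[["seconds", "visits"]].fillna(0.0)
    out["visits"] = out["visits"].astype(int)
    return out


def heatmap_matrix(
    table: pd.DataFrame,
    roster: pd.DataFrame,
    group_by: str = "sex",
    labels: pd.Series | None = None,
    value: str = "normalized_ml_per_kg",
) -> pd.DataFrame:
    """Group-mean day x ZT cells per substance, in long format.

    ``table`` must be an intake (or occupancy) table at day x ZT granularity.
    ``group_by`` is "sex" (joined from the roster) or "cluster" (joined from
    ``labels``, a Series indexed by tag).  Cell value is the arithmetic mean
    over the group's animals; because the input grid is zero-filled the mean
    is over all animals in the group.
    """
    if not {"day", "zt"}.issubset(table.columns):
        raise ValueError("table must be at day x ZT granularity")
    t = table.copy()
    if group_by == "sex":
        t = t.merge(roster[["tag", "sex"]], on="tag")
        t["group"] = t["sex"]
    elif group_by == "cluster":
        if labels is None:
            raise ValueError("cluster grouping requires labels")
        t["group"] = t["tag"].map(labels)
        if t["group"].isna().any():
            raise ValueError("labels do not cover all tags in the table")
    else:
        raise ValueError(f"unknown grouping key {group_by!r}")
    keys = ["group", "day", "zt"]
    if "substance" in t.columns:
        keys = ["group", "substance", "dose_label", "day", "zt"]
    out = t.groupby(keys, observed=True)[value].mean().reset_index()
    return out.rename(columns={value: "value"})


def to_matrix(heatmap_long: pd.DataFrame, group, substance=None, dose_label=None) -> pd.DataFrame:
    """Pivot one group's long-format heat map into a dense day x ZT matrix."""
    sel = heatmap_long[heatmap_long["group"] == group]
    if substance is not None:
        sel = sel[sel["substance"] == substance]
    if dose_label is not None:
        sel = sel[sel["dose_label"] == dose_label]
    return sel.pivot_table(index="day", columns="zt", values="value", aggfunc="mean")
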