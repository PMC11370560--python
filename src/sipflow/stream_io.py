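"""Readers for the two acquisition channels and their integration.

A home cage records two independent streams on a common clock: RFID antenna
detections of implanted tags at the drinking stations (nominally 100 Hz while
an animal is present) and volumetric drinking-monitor (VDM) samples (1 Hz,
microlitres).  Neither stream knows about the other; attribution of a drink
to an animal happens here by matching drink timestamps against the visit
bouts reconstructed from the RFID reads at the same station.

Timestamps are seconds since experiment start (floats).  The experiment is
assumed to start at lights-on, so zeitgeber time is directly computable
downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "UNASSIGNED",
    "StreamParseError",
    "StreamValidationError",
    "AssignmentResult",
    "read_rfid_stream",
    "read_vdm_stream",
    "read_animals",
    "read_stations",
    "collapse_visits",
    "assign_drinks",
]

UNASSIGNED = "UNASSIGNED"

RFID_COLUMNS = ("t_sec", "antenna", "tag")
VDM_COLUMNS = ("t_sec", "station", "volume_ul")
ANIMAL_COLUMNS = ("tag", "sex", "body_weight_g", "cage")
STATION_COLUMNS = ("station", "substance", "dose_label")


class StreamParseError(ValueError):
    """Malformed stream file (wrong columns or unparsable field)."""


class StreamValidationError(ValueError):
    """Parsable file whose values violate an invariant (e.g. volume < 0)."""


def _read_table(path, columns: tuple[str, ...], numeric: tuple[str, ...]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    except pd.errors.EmptyDataError:
        raise StreamParseError(f"{path}: empty file, expected header {columns}")
    got = tuple(df.columns)
    if set(got) != set(columns):
        raise StreamParseError(
            f"{path}: expected columns {sorted(columns)}, found {sorted(got)}"
        )
    df = df[list(columns)]
    for col in numeric:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header is line 1
            raise StreamParseError(
                f"{path}: line {line}: cannot parse {col}={df[col][bad.idxmax()]!r}"
            )
        if vals.isna().any():
            line = int(vals.isna().idxmax()) + 2
            raise StreamParseError(f"{path}: line {line}: missing value in {col}")
        df[col] = vals.astype(float)
    return df


def read_rfid_stream(path) -> pd.DataFrame:
    """Read ``t_sec,antenna,tag`` rows; return stably time-sorted reads."""
    df = _read_table(path, RFID_COLUMNS, numeric=("t_sec",))
    if (df["t_sec"] < 0).any():
        line = int((df["t_sec"] < 0).idxmax()) + 2
        raise StreamValidationError(f"{path}: line {line}: negative timestamp")
    return df.sort_values("t_sec", kind="stable", ignore_index=True)


def read_vdm_stream(path) -> pd.DataFrame:
    """Read ``t_sec,station,volume_ul`` rows; reject negative volumes."""
    df = _read_table(path, VDM_COLUMNS, numeric=("t_sec", "volume_ul"))
    if (df["t_sec"] < 0).any():
        line = int((df["t_sec"] < 0).idxmax()) + 2
        raise StreamValidationError(f"{path}: line {line}: negative timestamp")
    if (df["volume_ul"] < 0).any():
        line = int((df["volume_ul"] < 0).idxmax()) + 2
        raise StreamValidationError(f"{path}: line {line}: negative volume")
    return df.sort_values("t_sec", kind="stable", ignore_index=True)


def read_animals(path) -> pd.DataFrame:
    """Read the roster: ``tag,sex,body_weight_g,cage``; cages must be single-sex."""
    df = _read_table(path, ANIMAL_COLUMNS, numeric=("body_weight_g",))
    if df["tag"].duplicated().any():
        raise StreamValidationError(f"{path}: duplicate tags in roster")
    bad_sex = ~df["sex"].isin(["M", "F"])
    if bad_sex.any():
        raise StreamValidationError(f"{path}: sex must be M or F")
    if (df["body_weight_g"] <= 0).any():
        raise StreamValidationError(f"{path}: body weight must be positive")
    mixed = df.groupby("cage")["sex"].nunique()
    if (mixed > 1).any():
        raise StreamValidationError(
            f"{path}: mixed-sex cages: {mixed.index[mixed > 1].tolist()}"
        )
    return df.reset_index(drop=True)


def read_stations(path) -> pd.DataFrame:
    """Read the station map: ``station,substance,dose_label``."""
    df = _read_table(path, STATION_COLUMNS, numeric=())
    if df["station"].duplicated().any():
        raise StreamValidationError(f"{path}: duplicate station ids")
    return df.reset_index(drop=True)


def collapse_visits(reads: pd.DataFrame, max_gap: float = 1.0) -> pd.DataFrame:
    """Collapse RFID reads into visit bouts.

    A bout is a maximal run of reads of one (tag, antenna) pair whose
    successive gaps are <= ``max_gap`` seconds (default 1.0 s, bridging
    dropout at the nominal 100 Hz read rate).  Interleaved reads of other
    animals or stations do not break a bout.  Bout start/end are the first
    and last read times (both observed, so containment downstream uses the
    closed interval).

    Parameters
    ----------
    reads : DataFrame with columns t_sec, antenna, tag, sorted by t_sec.
    max_gap : maximum within-bout gap between consecutive reads, seconds.
    """
    if max_gap <= 0:
        raise ValueError("max_gap must be positive")
    if not reads["t_sec"].is_monotonic_increasing:
        raise ValueError("reads must be sorted by t_sec")
    if reads.empty:
        return pd.DataFrame(
            columns=["tag", "station", "t_start", "t_end", "n_reads"]
        ).astype({"t_start": float, "t_end": float, "n_reads": int})
    df = reads[["t_sec", "antenna", "tag"]].copy()
    gap = df.groupby(["tag", "antenna"], sort=False)["t_sec"].diff()
    new_bout = gap.isna() | (gap > max_gap)
    df["bout_id"] = new_bout.groupby(
        [df["tag"], df["antenna"]], sort=False
    ).cumsum()
    bouts = (
        df.groupby(["tag", "antenna", "bout_id"], sort=False)
        .agg(t_start=("t_sec", "first"), t_end=("t_sec", "last"), n_reads=("t_sec", "size"))
        .reset_index()
        .rename(columns={"antenna": "station"})
        .drop(columns="bout_id")
    )
    return bouts.sort_values(["t_start", "tag"], kind="stable", ignore_index=True)


@dataclass
class AssignmentResult:
    """Attributed drink events plus data-quality counters."""

    events: pd.DataFrame  # tag, station, substance, dose_label, t_sec, volume_ul
    n_unassigned: int
    n_overlap: int  # drinks falling inside bouts of >1 animal simultaneously


def _assign_station(t_drinks, starts, ends, tags, tolerance):
    """Attribute drink times to bouts at one station.

    Containment first (closed bout interval), then nearest boundary within
    ``tolerance``; ties broken by earlier bout start.  Returns (tag index or
    -1 per drink, overlap count).
    """
    cummax_end = np.maximum.accumulate(ends)
    out = np.full(t_drinks.size, -1, dtype=int)
    n_overlap = 0
    for i, t in enumerate(t_drinks):
        hi = int(np.searchsorted(starts, t, side="right"))  # bouts with start <= t
        best_contain = -1
        n_contain = 0
        best_near = -1
        best_dist = np.inf
        j = hi - 1
        # scan backwards while some earlier bout could still reach t - tolerance
        while j >= 0 and cummax_end[j] >= t - tolerance:
            if ends[j] >= t:
                n_contain += 1
                best_contain = j  # scanning right-to-left => ends at earliest start
            else:
                d = t - ends[j]
                if d <= tolerance and (
                    d < best_dist or (d == best_dist and (best_near == -1 or starts[j] < starts[best_near]))
                ):
                    best_dist = d
                    best_near = j
            j -= 1
        if best_contain >= 0:
            if n_contain > 1:
                n_overlap += 1
            out[i] = best_contain
            continue
        if hi < starts.size:
            d = starts[hi] - t
            if d <= tolerance and d < best_dist:
                best_dist = d
                best_near = hi
        if best_near >= 0:
            out[i] = best_near
    return out, n_overlap


def assign_drinks(
    drinks: pd.DataFrame,
    bouts: pd.DataFrame,
    roster: pd.DataFrame,
    stations: pd.DataFrame,
    tolerance: float = 2.0,
) -> AssignmentResult:
    """Integrate the VDM stream with visit bouts via common timestamps.

    Each drink row at station s, time t is attributed to the animal whose
    bout at s contains t; failing that, to the bout at s whose boundary is
    nearest within ``tolerance`` seconds; failing that it stays UNASSIGNED.
    Substance and dose are joined from the station map.  Deterministic:
    containment beats proximity, ties go to the earlier bout start.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    known_stations = set(stations["station"])
    unknown = set(drinks["station"]) - known_stations
    if unknown:
        raise StreamValidationError(f"drinks at unknown stations: {sorted(unknown)}")
    known_tags = set(roster["tag"])
    bad_tags = set(bouts["tag"]) - known_tags
    if bad_tags:
        raise StreamValidationError(f"bouts with tags not in roster: {sorted(bad_tags)}")
    if not drinks["t_sec"].is_monotonic_increasing:
        raise ValueError("drinks must be sorted by t_sec")

    events = drinks[["t_sec", "station", "volume_ul"]].copy()
    events["tag"] = UNASSIGNED
    n_overlap = 0
    for st, idx in events.groupby("station", sort=False).groups.items():
        b = bouts[bouts["station"] == st]
        if b.empty:
            continue
        b = b.sort_values(["t_start", "t_end"], kind="stable")
        starts = b["t_start"].to_numpy()
        ends = b["t_end"].to_numpy()
        tags = b["tag"].to_numpy()
        which, n_ov = _assign_station(
            events.loc[idx, "t_sec"].to_numpy(), starts, ends, tags, tolerance
        )
        n_overlap += n_ov
        assigned = which >= 0
        events.loc[idx[assigned], "tag"] = tags[which[assigned]]
    n_unassigned = int((events["tag"] == UNASSIGNED).sum())
    events = events.merge(stations, on="station", how="left")
    events = events[["tag", "station", "substance", "dose_label", "t_sec", "volume_ul"]]
    return AssignmentResult(events=events, n_unassigned=n_unassigned, n_overlap=n_overlap)
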