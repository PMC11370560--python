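"""Polysubstance co-use classification over fixed 60-minute windows.

A polysubstance window is one animal x one clock-aligned, non-overlapping
60-minute bin in which the animal consumed more than one substance.  Windows
are half-open [start, start + 60 min) and aligned to lights-on, so every
attributed drink event falls in exactly one window.  Two category modes:

* ``collapsed`` — {water, ethanol, fentanyl}: 2^3 - 1 = 7 possible
  non-empty substance combinations;
* ``dose`` — the five substance/dose categories: 2^5 - 1 = 31 combinations.

Per group, the distribution over combination sizes (the "outer ring" of a
nested pie chart) and over specific combinations (the "inner ring") is
tallied with zero counts retained, so tables across groups are conformable
for chi-square comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from . import stats_engine
from .stream_io import UNASSIGNED

__all__ = [
    "MODES",
    "CombinationDistribution",
    "category_universe",
    "combo_universe",
    "classify_windows",
    "combination_distribution",
    "compare_distributions",
]

MODES = ("collapsed", "dose")

SECONDS_PER_DAY = 86400.0

COMBO_SEP = "+"


def category_universe(mode: str) -> tuple:
    """The substance categories a window's set is drawn from."""
    if mode == "collapsed":
        return ("water", "ethanol", "fentanyl")
    if mode == "dose":
        return ("water", "ethanol:5%", "ethanol:10%", "fentanyl:5ug", "fentanyl:20ug")
    raise ValueError(f"unknown mode {mode!r}; use one of {MODES}")


def combo_universe(mode: str) -> tuple:
    """All 2^k - 1 non-empty combinations, as canonical sorted strings."""
    cats = category_universe(mode)
    combos = []
    for r in range(1, len(cats) + 1):
        for subset in combinations(cats, r):
            combos.append(COMBO_SEP.join(sorted(subset)))
    return tuple(combos)


def _event_category(events: pd.DataFrame, mode: str) -> pd.Series:
    if mode == "collapsed":
        return events["substance"].astype(str)
    cat = events["substance"].astype(str) + ":" + events["dose_label"].astype(str)
    return cat.where(events["substance"] != "water", "water")


def classify_windows(
    events: pd.DataFrame, mode: str = "collapsed", window_minutes: float = 60.0
) -> pd.DataFrame:
    """Per animal x 60-minute window, the set of substances consumed.

    Only attributed events with volume > 0 count.  Returns one row per
    non-empty window: tag, day (1-based), window (index within day), combo
    (canonical sorted ``+``-joined string), count (= combination size).
    Events exactly on a boundary belong to the later window (half-open
    convention).
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; use one of {MODES}")
    if window_minutes <= 0:
        raise ValueError("window_minutes must be positive")
    win_s = window_minutes * 60.0
    windows_per_day = int(round(SECONDS_PER_DAY / win_s))
    ev = events[(events["tag"] != UNASSIGNED) & (events["volume_ul"] > 0)].copy()
    if ev.empty:
        return pd.DataFrame(columns=["tag", "day", "window", "combo", "count"])
    ev["category"] = _event_category(ev, mode)
    abs_win = (ev["t_sec"] // win_s).astype(int)
    ev["day"] = abs_win // windows_per_day + 1
    ev["window"] = abs_win % windows_per_day
    out = (
        ev.groupby(["tag", "day", "window"], observed=True)["category"]
        .agg(lambda s: COMBO_SEP.join(sorted(set(s))))
        .rename("combo")
        .reset_index()
    )
    out["count"] = out["combo"].str.count(rf"\{COMBO_SEP}") + 1
    return out


@dataclass
class CombinationDistribution:
    """Window tallies for one group: by combination size and by combination.

    ``counts_by_size`` is the outer pie ring (1..k substances), zero-filled;
    ``counts_by_combo`` is the inner ring over the full combination universe,
    zero-filled.  Both sum to the number of windows.
    """

    mode: str
    group: str
    scope: str
    counts_by_size: dict
    counts_by_combo: dict

    @property
    def n_windows(self) -> int:
        return sum(self.counts_by_size.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"mode": self.mode, "group": self.group, "scope": self.scope,
             "ring": "outer", "category": str(k), "count": v}
            for k, v in self.counts_by_size.items()
        ] + [
            {"mode": self.mode, "group": self.group, "scope": self.scope,
             "ring": "inner", "category": k, "count": v}
            for k, v in self.counts_by_combo.items()
        ]
        return pd.DataFrame(rows)


def combination_distribution(
    windows: pd.DataFrame,
    mode: str,
    group_labels: pd.Series | None = None,
    scope: str = "all",
    day: int | None = None,
) -> dict:
    """Tally windows into per-group CombinationDistributions.

    ``group_labels`` maps tag -> group (sex, cluster); ``None`` puts every
    animal in one group named "all".  ``day`` restricts to a single day
    (scope becomes ``"day<d>"``).  Zero-count categories are retained.
    Returns {group label: CombinationDistribution}.
    """
    cats = category_universe(mode)
    combos = combo_universe(mode)
    w = windows
    if day is not None:
        w = w[w["day"] == day]
        scope = f"day{day}"
    if group_labels is None:
        groups = pd.Series("all", index=w["tag"].unique()) if len(w) else pd.Series(
            "all", index=pd.Index([], dtype=object)
        )
    else:
        groups = group_labels
        missing = set(w["tag"]) - set(groups.index)
        if missing:
            raise ValueError(f"windows with tags missing from group labels: {sorted(missing)}")
    out = {}
    group_values = sorted(pd.unique(groups), key=str) if len(groups) else ["all"]
    for g in group_values:
        tags = set(groups.index[groups == g]) if group_labels is not None else None
        wg = w if tags is None else w[w["tag"].isin(tags)]
        size_counts = wg["count"].value_counts() if len(wg) else pd.Series(dtype=int)
        combo_counts = wg["combo"].value_counts() if len(wg) else pd.Series(dtype=int)
        unknown = set(combo_counts.index) - set(combos)
        if unknown:
            raise ValueError(
                f"windows contain combinations outside the {mode} universe: {sorted(unknown)}"
            )
        out[g] = CombinationDistribution(
            mode=mode,
            group=str(g),
            scope=scope,
            counts_by_size={s: int(size_counts.get(s, 0)) for s in range(1, len(cats) + 1)},
            counts_by_combo={c: int(combo_counts.get(c, 0)) for c in combos},
        )
    return out


def compare_distributions(distributions, ring: str = "outer") -> stats_engine.TestResult:
    """Pearson chi-square across groups on one pie ring.

    ``distributions`` is a sequence (or dict) of 2+ conformable
    CombinationDistributions (same mode).  Categories with zero total across
    all groups are dropped before testing — their expected counts are
    undefined; df = (groups - 1)(kept categories - 1).
    """
    if isinstance(distributions, dict):
        distributions = list(distributions.values())
    if len(distributions) < 2:
        raise ValueError("need at least two distributions to compare")
    modes = {d.mode for d in distributions}
    if len(modes) != 1:
        raise ValueError(f"distributions mix modes {sorted(modes)}")
    if ring == "outer":
        rows = [list(d.counts_by_size.values()) for d in distributions]
    elif ring == "inner":
        rows = [list(d.counts_by_combo.values()) for d in distributions]
    else:
        raise ValueError(f"ring must be 'outer' or 'inner', got {ring!r}")
    table = np.asarray(rows, dtype=float)
    return stats_engine.chi_square_test(table)
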