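"""Two-bottle-choice style preference indices.

Substance preference over water is the classical ratio of consumed volumes

    pref = V_substance / (V_substance + V_water)

with both water stations and, for the substance, both doses pooled; dose
preference within a substance is V_high / (V_high + V_low) (high = 10%
ethanol or 20 ug/ml fentanyl).  0.5 is indifference.  When the denominator
is zero the index is undefined and reported as NaN with ``defined=False``
rather than imputed at 0.5, which would manufacture indifference; undefined
animals are excluded pairwise from group statistics.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["substance_preference", "dose_preference", "preference_long"]

HIGH_DOSE = {"ethanol": "10%", "fentanyl": "20ug"}
LOW_DOSE = {"ethanol": "5%", "fentanyl": "5ug"}


def _scoped_volumes(intake: pd.DataFrame, scope: str) -> pd.DataFrame:
    """Collapse an intake table to (tag[, day], substance, dose_label, volume)."""
    keys = ["tag", "substance", "dose_label"]
    if scope == "day":
        if "day" not in intake.columns:
            raise ValueError("intake table lacks a day column for scope='day'")
        keys.insert(1, "day")
    elif scope != "total":
        raise ValueError(f"scope must be 'total' or 'day', got {scope!r}")
    return intake.groupby(keys, observed=True)["volume_ul"].sum().reset_index()


def _ratio_frame(num: pd.Series, den_extra: pd.Series, kind: str, index_cols) -> pd.DataFrame:
    total = num.add(den_extra, fill_value=0.0)
    value = num.divide(total)  # 0/0 -> NaN
    out = value.rename("value").reset_index()
    out["defined"] = total.reindex(value.index).gt(0).to_numpy()
    out.loc[~out["defined"], "value"] = float("nan")
    out.insert(len(index_cols), "kind", kind)
    return out


def substance_preference(intake: pd.DataFrame, substance: str, scope: str = "total") -> pd.DataFrame:
    """Per-animal preference of ``substance`` (all doses) over water.

    ``intake`` is a long intake table (see ``aggregate_intake``) at total or
    day granularity.  Returns columns tag[, day], kind, value, defined; the
    kind is e.g. ``"ethanol/water"``.
    """
    if substance not in ("ethanol", "fentanyl"):
        raise ValueError(f"unknown substance {substance!r}")
    vols = _scoped_volumes(intake, scope)
    keys = ["tag", "day"] if scope == "day" else ["tag"]
    v_sub = vols[vols["substance"] == substance].groupby(keys)["volume_ul"].sum()
    v_wat = vols[vols["substance"] == "water"].groupby(keys)["volume_ul"].sum()
    idx = vols.groupby(keys).size().index  # full tag (x day) universe
    v_sub = v_sub.reindex(idx, fill_value=0.0)
    v_wat = v_wat.reindex(idx, fill_value=0.0)
    return _ratio_frame(v_sub, v_wat, f"{substance}/water", keys)


def dose_preference(intake: pd.DataFrame, substance: str, scope: str = "total") -> pd.DataFrame:
    """Per-animal preference of the high over the low dose of ``substance``."""
    if substance not in HIGH_DOSE:
        raise ValueError(f"{substance!r} does not have two dose levels")
    vols = _scoped_volumes(intake, scope)
    doses = set(vols.loc[vols["substance"] == substance, "dose_label"])
    if not {HIGH_DOSE[substance], LOW_DOSE[substance]} <= doses:
        raise ValueError(
            f"intake table lacks both {substance} doses "
            f"({HIGH_DOSE[substance]}, {LOW_DOSE[substance]}); found {sorted(doses)}"
        )
    keys = ["tag", "day"] if scope == "day" else ["tag"]
    sub = vols[vols["substance"] == substance]
    v_hi = sub[sub["dose_label"] == HIGH_DOSE[substance]].groupby(keys)["volume_ul"].sum()
    v_lo = sub[sub["dose_label"] == LOW_DOSE[substance]].groupby(keys)["volume_ul"].sum()
    idx = vols.groupby(keys).size().index
    v_hi = v_hi.reindex(idx, fill_value=0.0)
    v_lo = v_lo.reindex(idx, fill_value=0.0)
    return _ratio_frame(v_hi, v_lo, f"{substance}-dose", keys)


def preference_long(intake_total: pd.DataFrame, intake_day: pd.DataFrame) -> pd.DataFrame:
    """All four preference kinds at total and per-day scope, stacked long.

    Columns: tag, kind, scope, value, defined — the on-disk layout of
    ``preference_long.csv``.
    """
    frames = []
    for substance in ("ethanol", "fentanyl"):
        for fn in (substance_preference, dose_preference):
            t = fn(intake_total, substance, scope="total")
            t["scope"] = "total"
            frames.append(t[["tag", "kind", "scope", "value", "defined"]])
            d = fn(intake_day, substance, scope="day")
            d["scope"] = "day" + d["day"].astype(str)
            frames.append(d[["tag", "kind", "scope", "value", "defined"]])
    return pd.concat(frames, ignore_index=True)
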