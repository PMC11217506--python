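"""Murine mRECIST response scoring.

For each mouse the percent tumor-volume change relative to the day of
irradiation,

    dV_d = 100 * (V_d - V_start) / V_start,

and its running average over measured days in [0, d] are evaluated at every
measured day d >= 0.  Best response (BR) is the minimum of dV_d over days
>= ``min_day`` (default 7); best average response (BAR) is the minimum of the
running average over the same window.  The response call uses strict
inequalities, evaluated in precedence order:

    mCR:  BR < -95  and BAR < -40
    mPR:  BR < -50  and BAR < -20
    mSD:  BR <  35  and BAR <  30
    mPD:  not otherwise categorized

A mouse with no anchored starting volume or no measurement at day >=
``min_day`` is *unevaluable* — a first-class outcome, never silently dropped.

The running average printed as (sum over [0,d] of dV)/d is ill-defined at
d = 0 and under-counts on non-daily schedules; the default here is the
count-based mean over measured days in [0, d], which reduces to the printed
form for daily sampling.  The literal day-number denominator is available via
``denominator="day"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from preclin.io import GrowthCurve, MRECISTResult, ValidationError

CALLS = ("mCR", "mPR", "mSD", "mPD")
UNEVALUABLE = "unevaluable"

DEFAULT_MIN_DAY = 7

# (call, BR upper bound, BAR upper bound) in precedence order; strict "<"
_THRESHOLDS = (
    ("mCR", -95.0, -40.0),
    ("mPR", -50.0, -20.0),
    ("mSD", 35.0, 30.0),
)


@dataclass
class ChangeSeries:
    """Percent volume change and its running average at measured days >= 0."""

    mouse_id: str
    days: np.ndarray
    delta_v: np.ndarray
    delta_v_bar: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=int)
        self.delta_v = np.asarray(self.delta_v, dtype=float)
        if np.any(self.days < 0):
            raise ValidationError("ChangeSeries is defined for days >= 0 only")


def percent_volume_change(curve: GrowthCurve) -> ChangeSeries | None:
    """dV_d (%) at every measured post-irradiation day.

    Returns ``None`` (unevaluable) when the curve has no starting-volume
    anchor or no measurement at day >= 0.
    """
    if curve.v_start is None or curve.v_start <= 0:
        return None
    post = curve.days >= 0
    if not post.any():
        return None
    days = curve.days[post]
    delta = 100.0 * (curve.volumes[post] - curve.v_start) / curve.v_start
    return ChangeSeries(mouse_id=curve.mouse_id, days=days, delta_v=delta)


def running_average_change(series: ChangeSeries, denominator: str = "count") -> ChangeSeries:
    """Fill in the running average of dV over measured days in [0, d].

    ``denominator="count"`` (default) divides by the number of measured days;
    ``"day"`` divides by the day number d itself (with the day-0 average
    defined as 0), matching daily-sampling conventions literally.
    """
    csum = np.cumsum(series.delta_v)
    if denominator == "count":
        denom = np.arange(1, series.days.size + 1, dtype=float)
    elif denominator == "day":
        denom = series.days.astype(float)
        denom[denom == 0] = np.inf  # dVbar_0 := 0
    else:
        raise ValidationError(f"unknown denominator rule {denominator!r}")
    series.delta_v_bar = csum / denom
    return series


def _min_from(series_days: np.ndarray, values: np.ndarray, min_day: int) -> float | None:
    window = series_days >= min_day
    return float(values[window].min()) if window.any() else None


def best_response(series: ChangeSeries, min_day: int = DEFAULT_MIN_DAY) -> float | None:
    """BR: minimum dV_d over measured days >= ``min_day``; None if no such day."""
    return _min_from(series.days, series.delta_v, min_day)


def best_average_response(series: ChangeSeries, min_day: int = DEFAULT_MIN_DAY) -> float | None:
    """BAR: minimum running-average change over measured days >= ``min_day``."""
    if series.delta_v_bar is None:
        running_average_change(series)
    return _min_from(series.days, series.delta_v_bar, min_day)


def classify_response(br: float | None, bar: float | None) -> str:
    """Four-way call from (BR, BAR); unevaluable inputs propagate."""
    if br is None or bar is None or not (np.isfinite(br) and np.isfinite(bar)):
        return UNEVALUABLE
    for call, br_lim, bar_lim in _THRESHOLDS:
        if br < br_lim and bar < bar_lim:
            return call
    return "mPD"


def score_curve(
    curve: GrowthCurve,
    min_day: int = DEFAULT_MIN_DAY,
    denominator: str = "count",
) -> MRECISTResult:
    """Full mRECIST scoring of one growth curve."""
    series = percent_volume_change(curve)
    if series is None:
        return MRECISTResult(curve.mouse_id, np.nan, np.nan, UNEVALUABLE, curve.group)
    running_average_change(series, denominator=denominator)
    br = best_response(series, min_day)
    bar = best_average_response(series, min_day)
    call = classify_response(br, bar)
    return MRECISTResult(
        curve.mouse_id,
        br if br is not None else np.nan,
        bar if bar is not None else np.nan,
        call,
        curve.group,
    )


def cohort_waterfall(
    curves,
    min_day: int = DEFAULT_MIN_DAY,
    denominator: str = "count",
) -> pd.DataFrame:
    """Per-mouse BAR table in waterfall order (BAR descending).

    Columns: mouse_id, group, br, bar, call.  Unevaluable mice keep NaN
    br/bar and sort last.
    """
    results = [score_curve(c, min_day, denominator) for c in curves]
    df = pd.DataFrame(
        [
            {"mouse_id": r.mouse_id, "group": r.group, "br": r.br, "bar": r.bar, "call": r.call}
            for r in results
        ],
        columns=["mouse_id", "group", "br", "bar", "call"],
    )
    return df.sort_values("bar", ascending=False, na_position="last").reset_index(drop=True)


def response_rates(waterfall: pd.DataFrame, by_group: bool = False) -> pd.DataFrame:
    """Percent of evaluable mice in each response category.

    Returns a table with one row per (group,) or a single "all" row, columns
    mCR/mPR/mSD/mPD rates (%) and the evaluable count n.
    """
    def rates(sub: pd.DataFrame) -> dict:
        ev = sub[sub["call"] != UNEVALUABLE]
        n = len(ev)
        out = {"n": n}
        for call in CALLS:
            out[call] = 100.0 * (ev["call"] == call).sum() / n if n else np.nan
        return out

    if by_group:
        rows = {g: rates(sub) for g, sub in waterfall.groupby("group", sort=True)}
    else:
        rows = {"all": rates(waterfall)}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "group"
    return out
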