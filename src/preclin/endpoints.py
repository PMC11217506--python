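"""Survival and growth-magnitude endpoints.

Time-to-volume analysis treats the first measured day at or above a volume
threshold (500 or 1000 mm^3 by convention) as the event; a curve that never
crosses is right-censored at its last observed day.  No interpolation between
measurement days is performed.  Kaplan-Meier estimation and the Mantel-Cox
logrank test are delegated to lifelines.

The cumulative (bilateral) volume is the sum of the primary and secondary
tumor volumes on a given day; on mismatched schedules the side missing a day
contributes its last observed value, and days before a side's first
measurement contribute 0.

The AUC metric integrates volume over [0, study_end] with the trapezoid rule;
curves ending early (welfare exit, endpoint reached) are extended
horizontally at the last measured value — last value carried forward — so
early dropouts are partially corrected for rather than dropped.

The local-response criterion calls a mouse a responder when the
post-irradiation nadir is at most 50% of the peak volume preceding it
(a 50%-or-more decrease).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

from preclin.io import GrowthCurve, SurvivalRecord, ValidationError


@dataclass(frozen=True)
class NadirResult:
    mouse_id: str
    v_max: float
    nadir: float
    ratio: float
    responder: bool


@dataclass(frozen=True)
class AUCResult:
    mouse_id: str
    auc: float  # mm^3 * days over [0, study_end]
    extended: bool


@dataclass
class KMEstimate:
    """Product-limit survivor function; ``median`` is the smallest event time
    with S(t) <= 0.5, or inf when never reached."""

    times: np.ndarray
    survival: np.ndarray
    median: float
    n: int

    @property
    def median_reached(self) -> bool:
        return np.isfinite(self.median)


def cumulative_volume(
    primary: GrowthCurve, secondary: GrowthCurve | None
) -> GrowthCurve:
    """Bilateral burden: pointwise sum on the union of measured days."""
    if secondary is None:
        return replace(primary, tumor_site="primary")
    if primary.mouse_id != secondary.mouse_id:
        raise ValidationError(
            f"cannot sum curves of different mice "
            f"({primary.mouse_id!r} vs {secondary.mouse_id!r})"
        )
    days = np.union1d(primary.days, secondary.days)

    def contribution(curve: GrowthCurve) -> np.ndarray:
        # last observed value carried forward; 0 before the first measurement
        idx = np.searchsorted(curve.days, days, side="right") - 1
        vals = np.where(idx >= 0, curve.volumes[np.maximum(idx, 0)], 0.0)
        return vals

    total = contribution(primary) + contribution(secondary)
    exit_reason = (
        "welfare"
        if "welfare" in (primary.exit_reason, secondary.exit_reason)
        else primary.exit_reason
    )
    v_start = None
    if (days == 0).any():
        v_start = float(total[days == 0][0])
    return GrowthCurve(
        mouse_id=primary.mouse_id,
        group=primary.group,
        days=days,
        volumes=total,
        tumor_site="primary",
        v_start=v_start,
        followup_end=max(primary.followup_end or 0, secondary.followup_end or 0),
        exit_reason=exit_reason,
    )


def time_to_threshold(
    curve: GrowthCurve, threshold_mm3: float, scope: str = "single"
) -> SurvivalRecord:
    """First measured post-irradiation day with volume >= threshold, else a
    censoring at the last observed day."""
    if threshold_mm3 <= 0:
        raise ValidationError("threshold must be positive")
    post = curve.days >= 0
    if not post.any():
        raise ValidationError(f"curve {curve.mouse_id!r} has no post-irradiation measurements")
    days = curve.days[post]
    vols = curve.volumes[post]
    crossed = np.nonzero(vols >= threshold_mm3)[0]
    if crossed.size:
        return SurvivalRecord(
            curve.mouse_id, curve.group, int(days[crossed[0]]), True, threshold_mm3, scope
        )
    return SurvivalRecord(
        curve.mouse_id, curve.group, int(days[-1]), False, threshold_mm3, scope
    )


def km_estimate(records) -> KMEstimate:
    """Kaplan-Meier product-limit estimate over a set of survival records."""
    records = list(records)
    if not records:
        raise ValidationError("km_estimate needs at least one record")
    times = [r.time_days for r in records]
    events = [r.event for r in records]
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    sf = kmf.survival_function_
    return KMEstimate(
        times=sf.index.to_numpy(dtype=float),
        survival=sf.iloc[:, 0].to_numpy(dtype=float),
        median=float(kmf.median_survival_time_),
        n=len(records),
    )


def logrank(records_a, records_b) -> tuple[float, float]:
    """Mantel-Cox logrank comparison of two groups: (chi-square, two-sided p)."""
    records_a, records_b = list(records_a), list(records_b)
    if not records_a or not records_b:
        raise ValidationError("both groups must be non-empty")
    if not any(r.event for r in records_a + records_b):
        warnings.warn("no events in either group; logrank is uninformative", stacklevel=2)
        return 0.0, 1.0
    res = logrank_test(
        [r.time_days for r in records_a],
        [r.time_days for r in records_b],
        event_observed_A=[r.event for r in records_a],
        event_observed_B=[r.event for r in records_b],
    )
    return float(res.test_statistic), float(res.p_value)


def nadir_response(curve: GrowthCurve) -> NadirResult | None:
    """Local-response call: nadir <= 50% of the preceding peak.

    The nadir is the minimum post-irradiation volume (first occurrence); the
    reference peak V_max is the maximum over measured days up to and
    including the nadir day.  Returns None (unevaluable) with fewer than two
    post-irradiation measurements.
    """
    post = curve.days >= 0
    if post.sum() < 2:
        return None
    days = curve.days[post]
    vols = curve.volumes[post]
    nadir_idx = int(np.argmin(vols))
    nadir = float(vols[nadir_idx])
    v_max = float(vols[: nadir_idx + 1].max())
    ratio = nadir / v_max
    return NadirResult(curve.mouse_id, v_max, nadir, ratio, responder=ratio <= 0.5)


def auc_lvcf(curve: GrowthCurve, study_end: int) -> AUCResult:
    """Trapezoidal growth AUC over [0, study_end] with horizontal extension.

    A curve ending before ``study_end`` contributes its last measured value
    for the remaining days (flagged ``extended``); a curve measured beyond
    ``study_end`` is integrated up to ``study_end`` exactly, interpolating
    the boundary value.
    """
    post = (curve.days >= 0) & (curve.days <= study_end)
    if not post.any():
        raise ValidationError(f"curve {curve.mouse_id!r} has no measurements in [0, {study_end}]")
    days = curve.days[post].astype(float)
    vols = curve.volumes[post]
    beyond = curve.days > study_end
    if beyond.any():
        # boundary value at study_end between the last inside and first outside day
        d0, v0 = days[-1], vols[-1]
        d1 = float(curve.days[beyond][0])
        v1 = float(curve.volumes[beyond][0])
        v_end = v0 + (v1 - v0) * (study_end - d0) / (d1 - d0)
        days = np.append(days, float(study_end))
        vols = np.append(vols, v_end)
    auc = float(np.trapezoid(vols, days))
    extended = bool(days[-1] < study_end)
    if extended:
        auc += float(vols[-1]) * (study_end - days[-1])
    return AUCResult(curve.mouse_id, auc, extended)


def survival_table(records) -> pd.DataFrame:
    rows = [
        {
            "mouse_id": r.mouse_id,
            "group": r.group,
            "time_days": r.time_days,
            "event": int(r.event),
            "threshold_mm3": r.threshold_mm3,
            "scope": r.scope,
        }
        for r in records
    ]
    return pd.DataFrame(
        rows, columns=["mouse_id", "group", "time_days", "event", "threshold_mm3", "scope"]
    )
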