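"""Synthetic cohort generator.

Emulates the measurement process of a mouse radiotherapy efficacy study:
subcutaneous tumors measured by caliper on a Monday/Wednesday/Friday-like
schedule, exponential growth or treatment-induced regression, multiplicative
log-normal measurement noise, and humane-endpoint truncation at the burden
limits (single tumor 1500 mm^3, cumulative bilateral burden 2000 mm^3).

Three responder classes span the qualitative behaviours seen in treated
cohorts:

* ``non_responder``       — exponential growth V(t) = V0 * exp(g t)
* ``transient_responder`` — regression at rate r for a delay period, then
                            regrowth at rate g from the nadir
* ``durable_responder``   — regression to below the 1 mm^3 caliper detection
                            floor and flat thereafter (a complete response)

Defaults are calibrated to the modelled study: mean initial volume 80 mm^3 at
the day of tumor irradiation, and a growth rate such that an untreated tumor
crosses 1000 mm^3 around day 14.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from preclin.io import BioluminescenceRecord, GrowthCurve, ValidationError

RESPONDER_CLASSES = ("non_responder", "transient_responder", "durable_responder")

DETECTION_FLOOR_MM3 = 1.0


def default_schedule(followup_end: int = 60) -> tuple[int, ...]:
    """Measurement days: three times a week (offsets 0, 2, 4 of each week)."""
    days = [7 * w + o for w in range(followup_end // 7 + 1) for o in (0, 2, 4)]
    return tuple(d for d in days if d <= followup_end)


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a simulated cohort.

    ``class_mixture`` gives the probabilities of (non_responder,
    transient_responder, durable_responder); ``noise_cv`` is the coefficient
    of variation of the mean-one log-normal measurement noise.
    """

    n_mice: int = 10
    class_mixture: tuple[float, float, float] = (1.0, 0.0, 0.0)
    v0_mm3: float = 80.0
    growth_rate: float = 0.19    # per day; 80 mm^3 crosses 1000 mm^3 by day 14
    regression_rate: float = 0.25
    regrowth_delay_days: int = 7
    noise_cv: float = 0.15
    schedule_days: tuple[int, ...] = field(default_factory=default_schedule)
    followup_end: int = 60
    burden_limit_single: float = 1500.0
    burden_limit_cumulative: float = 2000.0
    group: str = "simulated"
    bilateral: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        mix = np.asarray(self.class_mixture, dtype=float)
        if mix.shape != (3,) or np.any(mix < 0) or not math.isclose(mix.sum(), 1.0, abs_tol=1e-9):
            raise ValidationError("class_mixture must be 3 probabilities summing to 1")
        if self.n_mice < 0:
            raise ValidationError("n_mice must be >= 0")
        if self.v0_mm3 <= 0 or self.growth_rate <= 0 or self.regression_rate <= 0:
            raise ValidationError("v0, growth_rate and regression_rate must be positive")
        if self.noise_cv < 0:
            raise ValidationError("noise_cv must be >= 0")
        if not self.schedule_days or min(self.schedule_days) < 0:
            raise ValidationError("schedule_days must be non-empty and non-negative")


def _lognormal_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Mean-one multiplicative noise with coefficient of variation ``cv``."""
    if cv == 0:
        return np.ones(n)
    sigma = math.sqrt(math.log(1.0 + cv**2))
    return rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma, size=n)


def _true_volume(responder_class: str, t: np.ndarray, v0: float, spec: CohortSpec) -> np.ndarray:
    g, r, delay = spec.growth_rate, spec.regression_rate, spec.regrowth_delay_days
    if responder_class == "non_responder":
        v = v0 * np.exp(g * t)
    elif responder_class == "transient_responder":
        nadir = v0 * math.exp(-r * delay)
        v = np.where(t <= delay, v0 * np.exp(-r * t), nadir * np.exp(g * (t - delay)))
    elif responder_class == "durable_responder":
        v = v0 * np.exp(-r * t)
    else:
        raise ValidationError(f"unknown responder class {responder_class!r}")
    return np.maximum(v, DETECTION_FLOOR_MM3)


def simulate_growth_curve(
    responder_class: str,
    spec: CohortSpec,
    rng: np.random.Generator,
    mouse_id: str = "m0",
    tumor_site: str = "primary",
) -> GrowthCurve:
    """One noisy growth curve, truncated at the single-tumor burden limit.

    The scheduled measurement that would breach the limit is not emitted; the
    curve ends at the previous measured day with ``exit_reason="welfare"``.
    """
    days = np.asarray(sorted(d for d in spec.schedule_days if d <= spec.followup_end))
    v0 = spec.v0_mm3 * _lognormal_factors(rng, spec.noise_cv, 1)[0]
    true = _true_volume(responder_class, days.astype(float), v0, spec)
    noise = _lognormal_factors(rng, spec.noise_cv, days.size)
    vols = np.maximum(true * noise, DETECTION_FLOOR_MM3)
    # pin the day-0 measurement to the drawn starting volume (noise already in v0)
    if days.size and days[0] == 0:
        vols[0] = max(v0, DETECTION_FLOOR_MM3)

    exit_reason = "study_end"
    over = np.nonzero(vols > spec.burden_limit_single)[0]
    if over.size:
        cut = over[0]
        days, vols = days[:cut], vols[:cut]
        exit_reason = "welfare"
    return GrowthCurve(
        mouse_id=mouse_id,
        group=spec.group,
        days=days,
        volumes=vols,
        tumor_site=tumor_site,
        v_start=float(vols[0]) if days.size and days[0] == 0 else None,
        followup_end=int(days[-1]) if exit_reason == "welfare" and days.size else spec.followup_end,
        exit_reason=exit_reason,
    )


def _truncate_cumulative(
    primary: GrowthCurve, secondary: GrowthCurve, limit: float
) -> tuple[GrowthCurve, GrowthCurve]:
    """Cut both curves before the first shared day whose summed burden
    exceeds the cumulative limit."""
    common = np.intersect1d(primary.days, secondary.days)
    if not common.size:
        return primary, secondary
    p_idx = np.searchsorted(primary.days, common)
    s_idx = np.searchsorted(secondary.days, common)
    total = primary.volumes[p_idx] + secondary.volumes[s_idx]
    over = np.nonzero(total > limit)[0]
    if not over.size:
        return primary, secondary
    cut_day = common[over[0]]

    def cut(curve: GrowthCurve) -> GrowthCurve:
        keep = curve.days < cut_day
        return replace(
            curve,
            days=curve.days[keep],
            volumes=curve.volumes[keep],
            followup_end=int(curve.days[keep][-1]) if keep.any() else curve.followup_end,
            exit_reason="welfare",
        )

    return cut(primary), cut(secondary)


def simulate_cohort(spec: CohortSpec) -> tuple[list[GrowthCurve], list[str]]:
    """Simulate ``spec.n_mice`` mice; returns (curves, true class labels).

    Fully reproducible: per-mouse substreams are spawned deterministically
    from ``spec.seed``.  With ``bilateral=True`` each mouse carries a primary
    and a secondary tumor of the same responder class, jointly truncated at
    the cumulative burden limit.
    """
    root = np.random.SeedSequence(spec.seed)
    mix_rng = np.random.default_rng(root.spawn(1)[0])
    classes = [
        RESPONDER_CLASSES[i]
        for i in mix_rng.choice(3, size=spec.n_mice, p=np.asarray(spec.class_mixture))
    ]
    curves: list[GrowthCurve] = []
    substreams = root.spawn(spec.n_mice + 1)[1:]
    for i, (cls, ss) in enumerate(zip(classes, substreams)):
        rng = np.random.default_rng(ss)
        mouse_id = f"{spec.group}-{i:03d}"
        primary = simulate_growth_curve(cls, spec, rng, mouse_id, "primary")
        if spec.bilateral:
            secondary = simulate_growth_curve(cls, spec, rng, mouse_id, "secondary")
            primary, secondary = _truncate_cumulative(
                primary, secondary, spec.burden_limit_cumulative
            )
            curves.extend([primary, secondary])
        else:
            curves.append(primary)
    return curves, classes


def simulate_bioluminescence(
    n_mice: int,
    positive_fraction: float,
    signal_ratio: float,
    background_mean: float = 100.0,
    seed: int = 0,
    baseline_signal: float = 500.0,
    noise_cv: float = 0.0,
) -> tuple[list[BioluminescenceRecord], list[bool]]:
    """Ex vivo lymph-node radiance tables: 3 stations x 2 sides per mouse.

    A "positive" mouse carries tumor signal in one draining node whose
    background-corrected radiance is ``signal_ratio`` times the contralateral
    baseline in expectation; all other nodes sit at the baseline.  Returns the
    records and the true positivity labels.
    """
    if not (0.0 <= positive_fraction <= 1.0):
        raise ValidationError("positive_fraction must be in [0, 1]")
    if signal_ratio <= 0:
        raise ValidationError("signal_ratio must be positive")
    rng = np.random.default_rng(seed)
    records: list[BioluminescenceRecord] = []
    labels: list[bool] = []
    stations = ("axillary", "brachial", "inguinal")
    for i in range(n_mice):
        positive = bool(rng.random() < positive_fraction)
        labels.append(positive)
        hot_station = stations[rng.integers(3)] if positive else None
        for station in stations:
            for side in ("draining", "contralateral"):
                mean = baseline_signal
                if positive and side == "draining" and station == hot_station:
                    mean = baseline_signal * signal_ratio
                corrected = mean * _lognormal_factors(rng, noise_cv, 1)[0]
                background = background_mean * _lognormal_factors(rng, noise_cv, 1)[0]
                records.append(
                    BioluminescenceRecord(
                        mouse_id=f"b-{i:03d}",
                        station=station,
                        side=side,
                        radiance=corrected + background,
                        background=background,
                    )
                )
    return records, labels
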