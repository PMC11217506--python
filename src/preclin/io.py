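"""Domain types and CSV input/output.

All stages share a handful of small record types: a caliper `Measurement`,
a per-mouse `GrowthCurve`, and result records for mRECIST, survival,
bioluminescence and normalized metrics.  Time is measured in integer days
relative to the day of tumor irradiation (day 0); pre-irradiation days are
negative.  Volumes are mm^3, computed from caliper length L (largest
diameter) and perpendicular width W as V = L * W^2 / 2.

CSV dialects are plain comma-separated UTF-8 with a header row:

* measurements:     mouse_id, group, tumor_site, day, length_mm, width_mm,
                    volume_mm3 (volume optional when L/W are given)
* bioluminescence:  mouse_id, station, side, radiance, background
* metrics:          mouse_id, group, metric_name, value, mass_mg, experiment_id
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

TUMOR_SITES = ("primary", "secondary")
STATIONS = ("axillary", "brachial", "inguinal")
SIDES = ("draining", "contralateral")
EXIT_REASONS = ("study_end", "endpoint_reached", "welfare", "excluded")

MEASUREMENT_COLUMNS = [
    "mouse_id", "group", "tumor_site", "day", "length_mm", "width_mm", "volume_mm3",
]
BIOLUM_COLUMNS = ["mouse_id", "station", "side", "radiance", "background"]
METRIC_COLUMNS = ["mouse_id", "group", "metric_name", "value", "mass_mg", "experiment_id"]

# v_start fallback window: if no day-0 measurement exists, the nearest
# measurement in [-2, 0] anchors the percent-change series.
ANCHOR_WINDOW_DAYS = 2


class ValidationError(ValueError):
    """Raised for malformed input records or out-of-contract arguments."""


def caliper_volume(length_mm: float, width_mm: float) -> float:
    """Tumor volume (mm^3) from caliper length and width: V = L * W^2 / 2.

    L is the largest diameter and W the diameter perpendicular to it, so
    ``length_mm >= width_mm > 0`` is required; swapped dimensions are the
    caller's bug and raise rather than being silently reordered.
    """
    if not (width_mm > 0):
        raise ValidationError(f"width must be positive, got {width_mm}")
    if not (length_mm >= width_mm):
        raise ValidationError(
            f"length ({length_mm}) must be >= width ({width_mm}); "
            "check for swapped caliper dimensions"
        )
    return length_mm * width_mm**2 / 2.0


@dataclass(frozen=True)
class Measurement:
    """One caliper observation of one tumor on one day."""

    mouse_id: str
    group: str
    day: int
    volume_mm3: float
    length_mm: float | None = None
    width_mm: float | None = None
    tumor_site: str = "primary"

    def __post_init__(self) -> None:
        if self.tumor_site not in TUMOR_SITES:
            raise ValidationError(f"unknown tumor_site {self.tumor_site!r}")
        if not (self.volume_mm3 > 0):
            raise ValidationError(
                f"volume must be positive, got {self.volume_mm3} "
                f"(mouse {self.mouse_id}, day {self.day})"
            )
        if self.length_mm is not None and self.width_mm is not None:
            if not (self.length_mm >= self.width_mm > 0):
                raise ValidationError(
                    f"need length >= width > 0, got L={self.length_mm}, "
                    f"W={self.width_mm} (mouse {self.mouse_id}, day {self.day})"
                )


@dataclass
class GrowthCurve:
    """Time-ordered volumes of one tumor in one mouse.

    ``v_start`` anchors the percent-change series: the day-0 volume, or the
    nearest measurement within two days before irradiation; ``None`` marks a
    curve that cannot be scored by mRECIST.
    """

    mouse_id: str
    group: str
    days: np.ndarray
    volumes: np.ndarray
    tumor_site: str = "primary"
    v_start: float | None = None
    followup_end: int | None = None
    exit_reason: str = "study_end"

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=int)
        self.volumes = np.asarray(self.volumes, dtype=float)
        if self.days.shape != self.volumes.shape:
            raise ValidationError("days and volumes must have equal length")
        if self.days.size and np.any(np.diff(self.days) <= 0):
            raise ValidationError(f"days must be strictly increasing (mouse {self.mouse_id})")
        if self.days.size and np.any(self.volumes <= 0):
            raise ValidationError(f"volumes must be positive (mouse {self.mouse_id})")
        if self.exit_reason not in EXIT_REASONS:
            raise ValidationError(f"unknown exit_reason {self.exit_reason!r}")
        if self.followup_end is None and self.days.size:
            self.followup_end = int(self.days[-1])

    def volume_at(self, day: int) -> float | None:
        idx = np.nonzero(self.days == day)[0]
        return float(self.volumes[idx[0]]) if idx.size else None

    @property
    def n_measurements(self) -> int:
        return int(self.days.size)


@dataclass(frozen=True)
class MRECISTResult:
    mouse_id: str
    br: float
    bar: float
    call: str  # mCR / mPR / mSD / mPD / unevaluable
    group: str = ""


@dataclass(frozen=True)
class SurvivalRecord:
    """Time to a volume threshold, right-censored at the last observed day."""

    mouse_id: str
    group: str
    time_days: int
    event: bool
    threshold_mm3: float
    scope: str = "single"  # single | cumulative

    def __post_init__(self) -> None:
        if self.time_days < 0:
            raise ValidationError("time_days must be >= 0")
        if self.scope not in ("single", "cumulative"):
            raise ValidationError(f"unknown scope {self.scope!r}")


@dataclass(frozen=True)
class BioluminescenceRecord:
    """Average radiance (p/s/cm^2/sr) of one lymph node, with its plate
    background; ``corrected`` is radiance minus background clamped at 0."""

    mouse_id: str
    station: str
    side: str
    radiance: float
    background: float
    corrected: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.station not in STATIONS:
            raise ValidationError(f"unknown station {self.station!r}")
        if self.side not in SIDES:
            raise ValidationError(f"unknown side {self.side!r}")
        if self.radiance < 0 or self.background < 0:
            raise ValidationError("radiance and background must be non-negative")
        if self.corrected is None:
            object.__setattr__(
                self, "corrected", max(self.radiance - self.background, 0.0)
            )


@dataclass(frozen=True)
class NormalizedMetric:
    mouse_id: str
    group: str
    metric_name: str
    raw_value: float
    normalizer: str
    normalized_value: float


# ---------------------------------------------------------------------------
# CSV readers / writers


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")


def read_measurements(path: str | Path) -> list[Measurement]:
    """Read and validate a long-format caliper measurement table.

    Volume is taken from ``volume_mm3`` when present, otherwise computed from
    ``length_mm``/``width_mm``.  Duplicate (mouse, tumor_site, day) rows are a
    hard error — never averaged — because they indicate an upstream data fault.
    """
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ["mouse_id", "group", "day"], path)
    if "tumor_site" not in df.columns:
        df["tumor_site"] = "primary"

    dup = df.duplicated(subset=["mouse_id", "tumor_site", "day"], keep=False)
    if dup.any():
        first = df.index[dup][0]
        row = df.loc[first]
        raise ValidationError(
            f"{path}: duplicate measurement for mouse {row['mouse_id']!r}, "
            f"site {row['tumor_site']!r}, day {row['day']} (row {first + 2})"
        )

    out: list[Measurement] = []
    for idx, row in df.iterrows():
        try:
            day = int(row["day"])
            length = row.get("length_mm")
            width = row.get("width_mm")
            length = None if pd.isna(length) else float(length)
            width = None if pd.isna(width) else float(width)
            volume = row.get("volume_mm3")
            volume = None if pd.isna(volume) else float(volume)
            if volume is None:
                if length is None or width is None:
                    raise ValidationError("neither volume_mm3 nor length/width given")
                volume = caliper_volume(length, width)
            out.append(
                Measurement(
                    mouse_id=str(row["mouse_id"]),
                    group=str(row["group"]),
                    day=day,
                    volume_mm3=volume,
                    length_mm=length,
                    width_mm=width,
                    tumor_site=str(row["tumor_site"]),
                )
            )
        except (ValueError, TypeError, ValidationError) as exc:
            raise ValidationError(f"{path}: row {idx + 2}: {exc}") from exc
    return out


def measurements_to_frame(measurements: Iterable[Measurement]) -> pd.DataFrame:
    rows = [
        {
            "mouse_id": m.mouse_id,
            "group": m.group,
            "tumor_site": m.tumor_site,
            "day": m.day,
            "length_mm": m.length_mm,
            "width_mm": m.width_mm,
            "volume_mm3": m.volume_mm3,
        }
        for m in measurements
    ]
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)


def write_measurements(measurements: Iterable[Measurement], path: str | Path) -> None:
    measurements_to_frame(measurements).to_csv(path, index=False)


def read_bioluminescence(path: str | Path) -> list[BioluminescenceRecord]:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, BIOLUM_COLUMNS, path)
    out = []
    for idx, row in df.iterrows():
        try:
            out.append(
                BioluminescenceRecord(
                    mouse_id=str(row["mouse_id"]),
                    station=str(row["station"]),
                    side=str(row["side"]),
                    radiance=float(row["radiance"]),
                    background=float(row["background"]),
                )
            )
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"{path}: row {idx + 2}: {exc}") from exc
    return out


def write_bioluminescence(records: Iterable[BioluminescenceRecord], path: str | Path) -> None:
    rows = [
        {
            "mouse_id": r.mouse_id,
            "station": r.station,
            "side": r.side,
            "radiance": r.radiance,
            "background": r.background,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=BIOLUM_COLUMNS).to_csv(path, index=False)


def read_metrics(path: str | Path) -> pd.DataFrame:
    """Read a summary-metric table (flow counts, MFIs, cytokines ...)."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ["mouse_id", "group", "metric_name", "value"], path)
    for optional in ("mass_mg", "experiment_id"):
        if optional not in df.columns:
            df[optional] = np.nan
    return df[METRIC_COLUMNS]


# ---------------------------------------------------------------------------
# Curve assembly


def _anchor_volume(days: np.ndarray, volumes: np.ndarray) -> float | None:
    """Day-0 volume, else the nearest measurement within [-ANCHOR_WINDOW, 0]."""
    exact = np.nonzero(days == 0)[0]
    if exact.size:
        return float(volumes[exact[0]])
    window = np.nonzero((days >= -ANCHOR_WINDOW_DAYS) & (days < 0))[0]
    if window.size:
        return float(volumes[window[np.argmax(days[window])]])
    return None


def build_curves(
    measurements: Sequence[Measurement],
    followup_end: int | None = None,
) -> list[GrowthCurve]:
    """Assemble one GrowthCurve per (mouse, tumor_site).

    Mice are conserved: a mouse that cannot be anchored or has fewer than two
    measurements appears with ``exit_reason="excluded"`` rather than being
    silently dropped.
    """
    df = measurements_to_frame(measurements)
    curves: list[GrowthCurve] = []
    for (mouse, site), sub in df.groupby(["mouse_id", "tumor_site"], sort=True):
        sub = sub.sort_values("day")
        days = sub["day"].to_numpy(dtype=int)
        vols = sub["volume_mm3"].to_numpy(dtype=float)
        group = str(sub["group"].iloc[0])
        v_start = _anchor_volume(days, vols)
        excluded = days.size < 2 or v_start is None
        end = followup_end if followup_end is not None else int(days[-1])
        curves.append(
            GrowthCurve(
                mouse_id=str(mouse),
                group=group,
                days=days,
                volumes=vols,
                tumor_site=str(site),
                v_start=v_start,
                followup_end=end,
                exit_reason="excluded" if excluded else "study_end",
            )
        )
    return curves
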