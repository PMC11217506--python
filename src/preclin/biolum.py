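"""Draining-lymph-node metastasis calling from ex vivo bioluminescence.

Each mouse contributes six nodes (axillary, brachial, inguinal; draining and
contralateral non-draining side).  The plate background — an empty well with
imaging medium — is subtracted from every region of interest, clamping at 0.
The draining node with the highest corrected signal is divided by the
corrected signal of the *same-station* contralateral node; a fold change
strictly greater than 4 (a 300% increase over the non-draining node) calls
the mouse metastasis-positive.
"""

from __future__ import annotations

from collections import defaultdict
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from preclin.io import BioluminescenceRecord, ValidationError

DEFAULT_CUTOFF = 4.0


class CorrectedSignal(NamedTuple):
    value: float
    clamped: bool  # True when radiance <= background (signal at/below floor)


class FoldChangeResult(NamedTuple):
    mouse_id: str
    fold: float | None  # None = unevaluable
    station: str | None


def background_correct(radiance: float, background: float) -> CorrectedSignal:
    """Background-subtracted radiance, clamped at 0 and flagged at the floor."""
    if radiance < 0 or background < 0:
        raise ValidationError("radiance and background must be non-negative")
    value = radiance - background
    if value <= 0:
        return CorrectedSignal(0.0, True)
    return CorrectedSignal(value, False)


def cutoff_from_percent_increase(percent_increase: float) -> float:
    """Fold-change cutoff equivalent to a percent increase over the
    non-draining node: +300% over baseline is a fold change of 4."""
    return 1.0 + percent_increase / 100.0


def dln_fold_change(records: Sequence[BioluminescenceRecord]) -> FoldChangeResult:
    """Max-signal draining node over its same-station contralateral node.

    A zero corrected contralateral signal makes the ratio undefined; the
    mouse is returned as unevaluable (fold None) rather than infinite.
    """
    records = list(records)
    if not records:
        raise ValidationError("no bioluminescence records given")
    mouse_ids = {r.mouse_id for r in records}
    if len(mouse_ids) != 1:
        raise ValidationError(f"records span multiple mice: {sorted(mouse_ids)}")
    mouse_id = records[0].mouse_id

    draining = [r for r in records if r.side == "draining"]
    contra = {r.station: r for r in records if r.side == "contralateral"}
    paired = [r for r in draining if r.station in contra]
    if not paired:
        raise ValidationError(f"mouse {mouse_id!r} has no draining/contralateral station pair")

    best = max(paired, key=lambda r: r.corrected)
    denom = contra[best.station].corrected
    if denom <= 0:
        return FoldChangeResult(mouse_id, None, best.station)
    return FoldChangeResult(mouse_id, best.corrected / denom, best.station)


def classify_positivity(fold: float, cutoff: float = DEFAULT_CUTOFF) -> bool:
    """Metastasis call: fold change strictly greater than the cutoff."""
    if fold < 0:
        raise ValidationError("fold change must be non-negative")
    return fold > cutoff


def cohort_positivity(
    records: Sequence[BioluminescenceRecord], cutoff: float = DEFAULT_CUTOFF
) -> tuple[pd.DataFrame, float]:
    """Per-mouse fold changes and calls plus the cohort positivity rate.

    The rate (%) is positives over evaluable mice; unevaluable mice (zero
    contralateral signal) are reported but excluded from the denominator.
    """
    by_mouse: dict[str, list[BioluminescenceRecord]] = defaultdict(list)
    for r in records:
        by_mouse[r.mouse_id].append(r)
    rows = []
    for mouse_id in sorted(by_mouse):
        res = dln_fold_change(by_mouse[mouse_id])
        rows.append(
            {
                "mouse_id": mouse_id,
                "fold": np.nan if res.fold is None else res.fold,
                "station": res.station,
                "positive": None if res.fold is None else classify_positivity(res.fold, cutoff),
            }
        )
    df = pd.DataFrame(rows, columns=["mouse_id", "fold", "station", "positive"])
    evaluable = df["positive"].notna()
    rate = (
        100.0 * df.loc[evaluable, "positive"].astype(bool).sum() / evaluable.sum()
        if evaluable.any()
        else float("nan")
    )
    return df, rate
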