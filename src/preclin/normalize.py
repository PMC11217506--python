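"""Metric normalization rules for flow-cytometry, cytokine, qPCR and
transwell-migration summaries.

All rules are simple ratios or offsets, but each has a fixed convention the
downstream statistics depend on: per-mg counts use the dissociated tumor
mass, percent-of-control is computed against the control-group mean within
an experiment batch, MFIs subtract the matched isotype control (negative
results are kept, flagged, not clamped), qPCR quantities divide by the
reference gene, and transwell counts divide by the serum-attractant baseline.
"""

from __future__ import annotations

from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from preclin.io import ValidationError


def absolute_count(pct_total: float, total_cells: float) -> float:
    """Cells in a gated population: (% of total) x absolute cell count."""
    if not (0.0 <= pct_total <= 100.0):
        raise ValidationError(f"pct_total must be in [0, 100], got {pct_total}")
    if total_cells < 0:
        raise ValidationError("total_cells must be non-negative")
    return pct_total / 100.0 * total_cells


def per_mg(count: float, mass_mg: float) -> float:
    """Cell count normalized to dissociated tumor mass (per mg)."""
    if mass_mg <= 0:
        raise ValidationError(f"mass must be positive, got {mass_mg}")
    return count / mass_mg


def normalize_to_control(value: float, control_values: Sequence[float]) -> float:
    """Value as percent of the control-sample mean of the same experiment."""
    control = np.asarray(control_values, dtype=float)
    if control.size == 0:
        raise ValidationError("control_values must be non-empty")
    mean = control.mean()
    if mean <= 0:
        raise ValidationError(f"control mean must be positive, got {mean}")
    return 100.0 * value / mean


class CorrectedMFI(NamedTuple):
    value: float
    below_isotype: bool


def isotype_corrected_mfi(mfi: float, isotype_mfi: float) -> CorrectedMFI:
    """Sample MFI minus matched isotype-control MFI.

    Negative values (staining below the isotype background) are reported
    as-is with a flag; clamping would bias group means.
    """
    if mfi < 0 or isotype_mfi < 0:
        raise ValidationError("MFI values must be non-negative")
    value = mfi - isotype_mfi
    return CorrectedMFI(value, value < 0)


def migration_index(migrated: float, baseline_migrated: float) -> float:
    """Transwell migration relative to the serum-attractant baseline."""
    if baseline_migrated <= 0:
        raise ValidationError("baseline migration must be positive")
    if migrated < 0:
        raise ValidationError("migrated count must be non-negative")
    return migrated / baseline_migrated


def reference_gene_ratio(target_quantity: float, reference_quantity: float) -> float:
    """Target transcript quantity normalized to the reference gene."""
    if reference_quantity <= 0:
        raise ValidationError("reference quantity must be positive")
    return target_quantity / reference_quantity


def normalize_table_to_control(
    metrics: pd.DataFrame, control_group: str
) -> pd.DataFrame:
    """Percent-of-control normalization of a metrics table.

    Applied within (experiment_id, metric_name) batches, each value is scaled
    to the mean of the control group's values for that batch.  Returns the
    table with a ``normalized_value`` column added.
    """
    required = {"mouse_id", "group", "metric_name", "value"}
    if not required.issubset(metrics.columns):
        raise ValidationError(f"metrics table needs columns {sorted(required)}")
    df = metrics.copy()
    if "experiment_id" not in df.columns:
        df["experiment_id"] = "exp1"
    df["experiment_id"] = df["experiment_id"].fillna("exp1")

    df["normalized_value"] = np.nan
    for key, batch in df.groupby(["experiment_id", "metric_name"], sort=False):
        controls = batch.loc[batch["group"] == control_group, "value"]
        if controls.empty:
            raise ValidationError(f"no control samples ({control_group!r}) in batch {key}")
        df.loc[batch.index, "normalized_value"] = [
            normalize_to_control(v, controls.to_numpy()) for v in batch["value"]
        ]
    return df
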