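"""Collapse trial-level data to study x trial-type condition means.

The study-level analysis unit pairs, for each study and trial type, the
mean RT of the young group (x axis of a Brinley plot) with the mean RT of
the old group (y axis).  Means pool all trials of all participants in the
cell with equal weight; under the balanced design this equals the mean of
participant means (asserted in tests).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .cases import AgeGroup, TrialType
from .errors import FormatError, StructuralError
from .simulate import validate_trial_table

__all__ = [
    "study_condition_means",
    "write_study_means",
    "read_study_means",
    "STUDY_MEANS_COLUMNS",
]

logger = logging.getLogger(__name__)

STUDY_MEANS_COLUMNS = ("study_id", "trial_type", "young_mean_rt", "old_mean_rt")


def study_condition_means(table: pd.DataFrame) -> pd.DataFrame:
    """One row per study x trial type with paired young/old mean RTs."""
    validate_trial_table(table)
    cell = (
        table.groupby(["study_id", "trial_type", "age_group"], observed=True)["rt_ms"]
        .mean()
        .unstack("age_group")
    )
    for age in (AgeGroup.YOUNG.value, AgeGroup.OLD.value):
        if age not in cell.columns or cell[age].isna().any():
            bad = (
                cell.index.get_level_values("study_id").unique().tolist()
                if age not in cell.columns
                else cell.index[cell[age].isna()].get_level_values("study_id").unique().tolist()
            )
            raise StructuralError(f"study(ies) missing {age} group data: {bad}")
    per_study_types = cell.reset_index().groupby("study_id", observed=True)["trial_type"].nunique()
    incomplete = per_study_types[per_study_types < 2].index.tolist()
    if incomplete:
        raise StructuralError(f"study(ies) missing a trial type: {incomplete}")
    out = (
        cell.rename(
            columns={AgeGroup.YOUNG.value: "young_mean_rt", AgeGroup.OLD.value: "old_mean_rt"}
        )
        .rename_axis(columns=None)
        .reset_index()
        .sort_values(["study_id", "trial_type"], kind="mergesort")
        .reset_index(drop=True)
    )
    return out[list(STUDY_MEANS_COLUMNS)]


def _validate_study_means(means: pd.DataFrame, source: str = "study means") -> pd.DataFrame:
    missing = [c for c in STUDY_MEANS_COLUMNS if c not in means.columns]
    if missing:
        raise FormatError(f"{source} missing column(s): {missing}")
    extra = [c for c in means.columns if c not in STUDY_MEANS_COLUMNS]
    if extra:
        logger.warning("%s: ignoring extra column(s) %s", source, extra)
    means = means[list(STUDY_MEANS_COLUMNS)].copy()
    bad_tt = set(means["trial_type"].unique()) - {t.value for t in TrialType}
    if bad_tt:
        raise FormatError(f"{source}: unknown trial_type value(s): {sorted(bad_tt)}")
    vals = means[["young_mean_rt", "old_mean_rt"]].to_numpy(dtype=float)
    if not np.isfinite(vals).all() or (vals <= 0).any():
        raise FormatError(f"{source}: means must be finite and positive")
    return means


def write_study_means(means: pd.DataFrame, path: str | Path) -> None:
    """Write study-condition means as CSV."""
    _validate_study_means(means).to_csv(path, index=False)


def read_study_means(path: str | Path) -> pd.DataFrame:
    """Read a study-means CSV (also accepts externally produced tables)."""
    try:
        means = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty study-means file") from exc
    return _validate_study_means(means, source=str(path))
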