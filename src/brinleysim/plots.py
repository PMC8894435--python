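"""Standard and modified Brinley plots.

The standard plot scatters old-group against young-group condition means
with one OLS trend line per trial type and no reference line.  The
modified plot instead draws, for each study, a segment from its congruent
point to its incongruent point plus a unit-slope no-age-difference
reference line; a segment steeper than the reference line marks a
study-level Age x Trial Type interaction and elevation above the line
marks an overall age effect.  Numeric assertions about the display go
through :func:`segment_geometry`; images are smoke-tested only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .cases import TrialType
from .errors import StructuralError

__all__ = ["PlotSpec", "standard_brinley_plot", "modified_brinley_plot", "segment_geometry"]

logger = logging.getLogger(__name__)

_MARKERS = {TrialType.CONGRUENT.value: "o", TrialType.INCONGRUENT.value: "^"}
_COLORS = {TrialType.CONGRUENT.value: "#1f77b4", TrialType.INCONGRUENT.value: "#d62728"}


@dataclass
class PlotSpec:
    """Output and styling options shared by both plot types."""

    path: str | Path
    image_format: str = "svg"          # svg or png
    axis_limits: tuple[float, float] | None = None  # shared by both axes
    show_reference_line: bool = True   # modified plot only
    connect_conditions: bool = True    # modified plot only
    show_condition_fits: bool = True   # standard plot only
    xlabel: str = "Young mean RT (ms)"
    ylabel: str = "Old mean RT (ms)"
    title: str = ""

    def __post_init__(self) -> None:
        if self.image_format not in ("svg", "png"):
            raise ValueError(f"image_format must be svg or png, got {self.image_format}")


def _limits(means: pd.DataFrame, spec: PlotSpec) -> tuple[float, float]:
    if spec.axis_limits is not None:
        return spec.axis_limits
    vals = means[["young_mean_rt", "old_mean_rt"]].to_numpy(dtype=float)
    lo, hi = float(vals.min()), float(vals.max())
    pad = 0.05 * max(hi - lo, 1.0)
    return lo - pad, hi + pad


def _finish(ax, means: pd.DataFrame, spec: PlotSpec) -> Path:
    lo, hi = _limits(means, spec)
    ax.set_xlim(lo, hi)
    ax.set_ylim(lo, hi)
    ax.set_aspect("equal")
    ax.set_xlabel(spec.xlabel)
    ax.set_ylabel(spec.ylabel)
    if spec.title:
        ax.set_title(spec.title)
    ax.legend(loc="upper left", frameon=False)
    path = Path(spec.path)
    ax.figure.savefig(path, format=spec.image_format, bbox_inches="tight")
    plt.close(ax.figure)
    return path


def standard_brinley_plot(means: pd.DataFrame, spec: PlotSpec) -> Path:
    """Scatter of condition means with one OLS line per trial type."""
    if means["study_id"].nunique() < 2:
        raise StructuralError("standard Brinley plot needs >= 2 studies")
    fig, ax = plt.subplots(figsize=(5, 5))
    for tt, sub in means.groupby("trial_type", observed=True):
        x = sub["young_mean_rt"].to_numpy(dtype=float)
        y = sub["old_mean_rt"].to_numpy(dtype=float)
        ax.scatter(x, y, marker=_MARKERS[tt], color=_COLORS[tt], s=25, label=tt)
        if spec.show_condition_fits:
            if np.ptp(x) <= 1e-12:
                logger.warning("degenerate x-variance for %s: no fit line drawn", tt)
                continue
            slope, intercept = np.polyfit(x, y, 1)
            xs = np.array([x.min(), x.max()])
            ax.plot(xs, intercept + slope * xs, color=_COLORS[tt], lw=1.5)
    return _finish(ax, means, spec)


def modified_brinley_plot(means: pd.DataFrame, spec: PlotSpec) -> Path:
    """Per-study congruent-to-incongruent segments plus the identity line."""
    geom = segment_geometry(means)  # validates structure
    wide = _wide(means)
    fig, ax = plt.subplots(figsize=(5, 5))
    lo, hi = _limits(means, spec)
    if spec.show_reference_line:
        ax.plot([lo, hi], [lo, hi], color="0.4", ls="--", lw=1,
                label="no-age-difference reference")
    if spec.connect_conditions:
        for _, row in wide.iterrows():
            ax.plot(
                [row["young_congruent"], row["young_incongruent"]],
                [row["old_congruent"], row["old_incongruent"]],
                color="0.6", lw=0.8, zorder=1,
            )
    ax.scatter(wide["young_congruent"], wide["old_congruent"],
               marker=_MARKERS["congruent"], color=_COLORS["congruent"],
               s=25, zorder=2, label="congruent")
    ax.scatter(wide["young_incongruent"], wide["old_incongruent"],
               marker=_MARKERS["incongruent"], color=_COLORS["incongruent"],
               s=25, zorder=2, label="incongruent")
    return _finish(ax, means, spec)


def _wide(means: pd.DataFrame) -> pd.DataFrame:
    piv = means.pivot_table(
        index="study_id",
        columns="trial_type",
        values=["young_mean_rt", "old_mean_rt"],
        observed=True,
    )
    needed = [
        ("young_mean_rt", TrialType.CONGRUENT.value),
        ("young_mean_rt", TrialType.INCONGRUENT.value),
        ("old_mean_rt", TrialType.CONGRUENT.value),
        ("old_mean_rt", TrialType.INCONGRUENT.value),
    ]
    for col in needed:
        if col not in piv.columns or piv[col].isna().any():
            bad = (
                piv.index.tolist()
                if col not in piv.columns
                else piv.index[piv[col].isna()].tolist()
            )
            raise StructuralError(f"study(ies) missing a condition: {bad}")
    out = pd.DataFrame(
        {
            "young_congruent": piv[("young_mean_rt", "congruent")],
            "young_incongruent": piv[("young_mean_rt", "incongruent")],
            "old_congruent": piv[("old_mean_rt", "congruent")],
            "old_incongruent": piv[("old_mean_rt", "incongruent")],
        }
    )
    return out.reset_index()


def segment_geometry(means: pd.DataFrame) -> pd.DataFrame:
    """Per-study segment slope and elevation above the reference line.

    slope = (old_incong - old_cong) / (young_incong - young_cong); NaN when
    the young contrast is zero (undefined, not an error).  elevation = mean
    over both conditions of (old - young).  These are the two numeric
    summaries of what the modified plot displays.
    """
    wide = _wide(means)
    dy = wide["young_incongruent"] - wide["young_congruent"]
    dold = wide["old_incongruent"] - wide["old_congruent"]
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.where(np.abs(dy) > 1e-12, dold / dy, np.nan)
    elevation = (
        (wide["old_congruent"] - wide["young_congruent"])
        + (wide["old_incongruent"] - wide["young_incongruent"])
    ) / 2.0
    return pd.DataFrame(
        {"study_id": wide["study_id"], "slope": slope, "elevation": elevation}
    )
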