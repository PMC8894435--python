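"""Case library for the simulated multi-study Stroop designs.

Eight cases share a common 2 (Age: young/old) x 2 (Trial Type:
congruent/incongruent) factorial layout with per-cell normal RT means and
SDs, 50 studies of 50 participants per age group, 20 trials per trial type,
and AR(1) intertrial correlation rho = 0.60.  They differ in the generative
cell means (which effects are truly present) and in how between-study
"disturbance" variability is injected:

* Cases A-F: a single per-study random shift added to all four cell means
  (a grand-mean shift; it cancels exactly from every within-study contrast).
* Case G: the grand shift plus independent per-study random increments to
  each of the four cell means, perturbing the Age x Trial Type interaction
  (and, incidentally, the main effects) randomly across studies.
* Case H: the grand shift plus a *systematic* increment ``kappa * shift``
  to the old-incongruent cell, so slower studies carry larger interactions.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping

import yaml

from .errors import InvalidParameterError

__all__ = [
    "AgeGroup",
    "TrialType",
    "DisturbanceKind",
    "CellSpec",
    "DisturbanceScheme",
    "CaseSpec",
    "build_case_library",
    "load_overrides",
    "apply_overrides",
    "CASE_IDS",
]

CASE_IDS = ("A", "B", "C", "D", "E", "F", "G", "H")

# Defaults for the disturbance magnitudes (not printed in the published
# design).  sigma_study is calibrated so that the restricted Brinley slope
# attenuates to ~0.99; sigma_interaction (the per-cell disturbance SD of
# Case G) is calibrated so that the same slope attenuates to ~0.72 under
# the additional per-cell noise.  See docs/methods.md.
DEFAULT_SIGMA_STUDY = 100.0
DEFAULT_SIGMA_INTERACTION = 62.0
DEFAULT_KAPPA = 1.5


class AgeGroup(str, enum.Enum):
    YOUNG = "young"
    OLD = "old"


class TrialType(str, enum.Enum):
    CONGRUENT = "congruent"
    INCONGRUENT = "incongruent"


class DisturbanceKind(str, enum.Enum):
    GRAND_SHIFT = "grand_shift"
    GRAND_PLUS_RANDOM_INTERACTION = "grand_plus_random_interaction"
    GRAND_PLUS_SYSTEMATIC_INTERACTION = "grand_plus_systematic_interaction"


@dataclass(frozen=True)
class CellSpec:
    """Normal RT distribution for one Age x Trial Type cell (milliseconds)."""

    age_group: AgeGroup
    trial_type: TrialType
    mean_rt: float
    sd_rt: float

    def __post_init__(self) -> None:
        if not self.mean_rt > 0:
            raise InvalidParameterError(f"mean_rt must be > 0, got {self.mean_rt}")
        if not self.sd_rt >= 0:
            raise InvalidParameterError(f"sd_rt must be >= 0, got {self.sd_rt}")


@dataclass(frozen=True)
class DisturbanceScheme:
    """Between-study variability model.

    ``sigma_study`` is the SD (ms) of the per-study grand shift g_i added to
    all four cell means.  ``sigma_interaction`` is the SD of the additional
    independent per-cell increments (random-interaction kind only; one draw
    per cell per study, so the interaction contrast gains a
    N(0, 4*sigma_interaction^2) increment).  ``kappa`` maps the grand shift
    to a systematic increment delta_i = kappa * g_i on the old-incongruent
    cell (systematic kind only).  Parameters not used by ``kind`` are
    ignored.
    """

    kind: DisturbanceKind
    sigma_study: float = DEFAULT_SIGMA_STUDY
    sigma_interaction: float = DEFAULT_SIGMA_INTERACTION
    kappa: float = DEFAULT_KAPPA

    def __post_init__(self) -> None:
        if self.sigma_study < 0:
            raise InvalidParameterError("sigma_study must be >= 0")
        if self.sigma_interaction < 0:
            raise InvalidParameterError("sigma_interaction must be >= 0")


@dataclass(frozen=True)
class CaseSpec:
    """Full parameterization of one simulated multi-study case."""

    case_id: str
    cells: tuple[CellSpec, ...]
    disturbance: DisturbanceScheme
    n_per_group: int = 50
    n_trials_per_type: int = 20
    n_studies: int = 50
    ar_rho: float = 0.60
    description: str = ""

    def __post_init__(self) -> None:
        combos = {(c.age_group, c.trial_type) for c in self.cells}
        expected = {(a, t) for a in AgeGroup for t in TrialType}
        if len(self.cells) != 4 or combos != expected:
            raise InvalidParameterError(
                "cells must contain each (age_group, trial_type) combination exactly once"
            )
        if not (0 <= self.ar_rho < 1):
            raise InvalidParameterError(f"ar_rho must be in [0, 1), got {self.ar_rho}")
        for name in ("n_per_group", "n_trials_per_type", "n_studies"):
            if getattr(self, name) < 1:
                raise InvalidParameterError(f"{name} must be >= 1")

    def cell(self, age_group: AgeGroup | str, trial_type: TrialType | str) -> CellSpec:
        age_group = AgeGroup(age_group)
        trial_type = TrialType(trial_type)
        for c in self.cells:
            if c.age_group == age_group and c.trial_type == trial_type:
                return c
        raise KeyError((age_group, trial_type))  # unreachable given invariants

    @property
    def interaction_contrast(self) -> float:
        """(oldIncong - oldCong) - (youngIncong - youngCong) of the generative means."""
        m = {
            (c.age_group, c.trial_type): c.mean_rt for c in self.cells
        }
        return (
            m[(AgeGroup.OLD, TrialType.INCONGRUENT)]
            - m[(AgeGroup.OLD, TrialType.CONGRUENT)]
        ) - (
            m[(AgeGroup.YOUNG, TrialType.INCONGRUENT)]
            - m[(AgeGroup.YOUNG, TrialType.CONGRUENT)]
        )


def _cells(yc, yi, oc, oi, sd_young, sd_old) -> tuple[CellSpec, ...]:
    return (
        CellSpec(AgeGroup.YOUNG, TrialType.CONGRUENT, yc, sd_young),
        CellSpec(AgeGroup.YOUNG, TrialType.INCONGRUENT, yi, sd_young),
        CellSpec(AgeGroup.OLD, TrialType.CONGRUENT, oc, sd_old),
        CellSpec(AgeGroup.OLD, TrialType.INCONGRUENT, oi, sd_old),
    )


def build_case_library() -> dict[str, CaseSpec]:
    """Return the eight standard cases keyed by letter.

    Cell means/SDs follow the published simulation design: young congruent
    700 (150) etc.; Case B exaggerates the old-incongruent mean to 1,000;
    Case C removes the interaction (old incongruent 850); Case D has a
    trial-type effect only; Case E an age effect only; Case F all nulls;
    Cases G and H reuse Case A's cells with richer disturbance schemes.
    """
    shift = DisturbanceScheme(DisturbanceKind.GRAND_SHIFT)
    lib = {
        "A": CaseSpec("A", _cells(700, 800, 750, 900, 150, 200), shift,
                      description="All studies had same interaction"),
        "B": CaseSpec("B", _cells(700, 800, 750, 1000, 150, 200), shift,
                      description="Increased interaction magnitude"),
        "C": CaseSpec("C", _cells(700, 800, 750, 850, 150, 200), shift,
                      description="No interaction"),
        "D": CaseSpec("D", _cells(700, 900, 700, 900, 150, 150), shift,
                      description="Only main effect of trial type"),
        "E": CaseSpec("E", _cells(700, 700, 900, 900, 150, 150), shift,
                      description="Only main effect of age"),
        "F": CaseSpec("F", _cells(800, 800, 800, 800, 150, 150), shift,
                      description="All null effects"),
        "G": CaseSpec("G", _cells(700, 800, 750, 900, 150, 200),
                      DisturbanceScheme(DisturbanceKind.GRAND_PLUS_RANDOM_INTERACTION),
                      description="Random study-level interaction sizes"),
        "H": CaseSpec("H", _cells(700, 800, 750, 900, 150, 200),
                      DisturbanceScheme(DisturbanceKind.GRAND_PLUS_SYSTEMATIC_INTERACTION),
                      description="Stronger interactions for some studies"),
    }
    return lib


# ---------------------------------------------------------------------------
# Case-override config files (YAML or JSON; YAML is a superset of JSON so a
# single loader covers both dialects).

_CELL_KEYS = {
    "young_congruent": (AgeGroup.YOUNG, TrialType.CONGRUENT),
    "young_incongruent": (AgeGroup.YOUNG, TrialType.INCONGRUENT),
    "old_congruent": (AgeGroup.OLD, TrialType.CONGRUENT),
    "old_incongruent": (AgeGroup.OLD, TrialType.INCONGRUENT),
}


def load_overrides(path: str | Path) -> dict:
    """Load a case-override mapping from a YAML/JSON config file."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        return {}
    if not isinstance(data, Mapping):
        raise InvalidParameterError(f"config {path} must be a mapping, got {type(data).__name__}")
    return dict(data)


def apply_overrides(spec: CaseSpec, overrides: Mapping) -> CaseSpec:
    """Return ``spec`` with fields replaced from an override mapping.

    Recognised keys: ``n_per_group``, ``n_trials_per_type``, ``n_studies``,
    ``ar_rho``; ``cells`` (mapping cell name -> {mean, sd}); ``disturbance``
    (mapping with ``kind``, ``sigma_study``, ``sigma_interaction``,
    ``kappa``).  Unknown keys raise so typos do not silently pass.
    """
    overrides = dict(overrides)
    simple = {}
    for key in ("n_per_group", "n_trials_per_type", "n_studies", "ar_rho"):
        if key in overrides:
            simple[key] = overrides.pop(key)
    if "cells" in overrides:
        cell_over = overrides.pop("cells")
        new_cells = []
        for c in spec.cells:
            name = next(k for k, v in _CELL_KEYS.items() if v == (c.age_group, c.trial_type))
            if name in cell_over:
                entry = cell_over[name]
                c = replace(c, mean_rt=entry.get("mean", c.mean_rt), sd_rt=entry.get("sd", c.sd_rt))
            new_cells.append(c)
        simple["cells"] = tuple(new_cells)
    if "disturbance" in overrides:
        d_over = dict(overrides.pop("disturbance"))
        d = spec.disturbance
        if "kind" in d_over:
            d_over["kind"] = DisturbanceKind(d_over["kind"])
        simple["disturbance"] = replace(d, **d_over)
    if overrides:
        raise InvalidParameterError(f"unknown override keys: {sorted(overrides)}")
    return replace(spec, **simple)
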