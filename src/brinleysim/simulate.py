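"""Trial-level RT simulation with AR(1) intertrial dependence.

Each participant contributes one interleaved sequence of 2*T trials
(congruent, incongruent, congruent, ...).  A single standardized AR(1)
process z_t (mean 0, variance 1, lag-1 correlation ``ar_rho``) spans the
whole sequence, so trials are correlated both within and across trial
types; the RT at position t is ``cell_mean(t) + cell_sd(t) * z_t``.  No
truncation, censoring or error trials are simulated.

Reproducibility: one master ``numpy.random.SeedSequence`` per case is split
into a disturbance substream plus one substream per study, and each study
substream spawns one child per participant.  Because substreams are keyed
by position, enlarging ``n_studies`` (or adding participants) never alters
the draws of earlier studies or participants.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import toeplitz

from .cases import AgeGroup, CaseSpec, DisturbanceKind, TrialType
from .errors import FormatError, InvalidParameterError, StructuralError

__all__ = [
    "ar1_correlation",
    "draw_study_disturbances",
    "simulate_participant",
    "simulate_case",
    "write_trial_table",
    "read_trial_table",
    "validate_trial_table",
    "TRIAL_TABLE_COLUMNS",
]

TRIAL_TABLE_COLUMNS = (
    "study_id",
    "participant_id",
    "age_group",
    "trial_type",
    "trial_index",
    "rt_ms",
)

CELL_ORDER = (
    "young_congruent",
    "young_incongruent",
    "old_congruent",
    "old_incongruent",
)


def ar1_correlation(n: int, rho: float) -> np.ndarray:
    """AR(1) correlation matrix with entry (i, j) = rho**|i - j|."""
    if n < 1:
        raise InvalidParameterError(f"n must be >= 1, got {n}")
    if not (0 <= rho < 1):
        raise InvalidParameterError(f"rho must be in [0, 1), got {rho}")
    return toeplitz(rho ** np.arange(n))


def draw_study_disturbances(
    spec: CaseSpec, study_count: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Per-study disturbance-adjusted cell means.

    Returns a DataFrame with one row per study and the four cell-mean
    columns ``young_congruent .. old_incongruent`` (ms).  The grand shift
    g_i ~ N(0, sigma_study^2) is added to all four cells.  The
    random-interaction scheme (Case G) additionally adds an independent
    N(0, sigma_interaction^2) increment to every cell; the systematic
    scheme (Case H) adds kappa * g_i to the old-incongruent cell only.
    """
    if study_count < 1:
        raise InvalidParameterError(f"study_count must be >= 1, got {study_count}")
    d = spec.disturbance
    # One row of standard normals per study (grand shift + per-cell slots),
    # drawn row-wise so study i's draws are unchanged when study_count grows.
    draws = rng.standard_normal((study_count, 5))
    g = d.sigma_study * draws[:, 0]

    base = {
        "young_congruent": spec.cell(AgeGroup.YOUNG, TrialType.CONGRUENT).mean_rt,
        "young_incongruent": spec.cell(AgeGroup.YOUNG, TrialType.INCONGRUENT).mean_rt,
        "old_congruent": spec.cell(AgeGroup.OLD, TrialType.CONGRUENT).mean_rt,
        "old_incongruent": spec.cell(AgeGroup.OLD, TrialType.INCONGRUENT).mean_rt,
    }
    out = pd.DataFrame({k: base[k] + g for k in CELL_ORDER})
    if d.kind is DisturbanceKind.GRAND_PLUS_RANDOM_INTERACTION:
        for j, k in enumerate(CELL_ORDER):
            out[k] = out[k] + d.sigma_interaction * draws[:, 1 + j]
    elif d.kind is DisturbanceKind.GRAND_PLUS_SYSTEMATIC_INTERACTION:
        out["old_incongruent"] = out["old_incongruent"] + d.kappa * g
    if (out[list(CELL_ORDER)].to_numpy() <= 0).any():
        raise InvalidParameterError(
            "disturbance draws produced non-positive cell means; "
            "reduce sigma_study/sigma_interaction relative to the cell means"
        )
    return out


def _ar1_path(eps: np.ndarray, rho: float) -> np.ndarray:
    """Standardized AR(1) path(s) from standard-normal innovations.

    ``eps`` has shape (..., n).  z_0 = eps_0 and
    z_t = rho * z_{t-1} + sqrt(1 - rho^2) * eps_t, so every z_t is
    marginally N(0, 1) with lag-k correlation rho**k.
    """
    z = np.empty_like(eps)
    z[..., 0] = eps[..., 0]
    a = np.sqrt(1.0 - rho**2)
    for t in range(1, eps.shape[-1]):
        z[..., t] = rho * z[..., t - 1] + a * eps[..., t]
    return z


def trial_type_sequence(n_trials_per_type: int) -> np.ndarray:
    """Deterministic alternation congruent, incongruent, congruent, ..."""
    return np.tile(
        np.array([TrialType.CONGRUENT.value, TrialType.INCONGRUENT.value]),
        n_trials_per_type,
    )


def simulate_participant(
    cell_means: Sequence[float],
    cell_sds: Sequence[float],
    n_trials_per_type: int,
    ar_rho: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One participant's ordered RT sequence.

    ``cell_means``/``cell_sds`` are (congruent, incongruent) pairs for this
    participant's age group (already disturbance-adjusted).  Returns
    ``(rt, trial_types)`` of length ``2 * n_trials_per_type``.
    """
    if not (0 <= ar_rho < 1):
        raise InvalidParameterError(f"ar_rho must be in [0, 1), got {ar_rho}")
    if n_trials_per_type < 1:
        raise InvalidParameterError("n_trials_per_type must be >= 1")
    mean_c, mean_i = (float(x) for x in cell_means)
    sd_c, sd_i = (float(x) for x in cell_sds)
    if sd_c < 0 or sd_i < 0:
        raise InvalidParameterError("cell sds must be >= 0")
    n = 2 * n_trials_per_type
    z = _ar1_path(rng.standard_normal(n), ar_rho)
    types = trial_type_sequence(n_trials_per_type)
    congruent = types == TrialType.CONGRUENT.value
    means = np.where(congruent, mean_c, mean_i)
    sds = np.where(congruent, sd_c, sd_i)
    return means + sds * z, types


def simulate_case(spec: CaseSpec, seed: int) -> pd.DataFrame:
    """Simulate a full multi-study case as a long-format trial table.

    Returns a DataFrame with columns ``study_id, participant_id, age_group,
    trial_type, trial_index, rt_ms`` and exactly
    ``n_studies * 2 * n_per_group * 2 * n_trials_per_type`` rows.
    Fully reproducible given (spec, seed).
    """
    master = np.random.SeedSequence(seed)
    children = master.spawn(spec.n_studies + 1)
    adjusted = draw_study_disturbances(
        spec, spec.n_studies, np.random.default_rng(children[0])
    )

    n = spec.n_per_group
    T = spec.n_trials_per_type
    n_part = 2 * n
    seq_len = 2 * T
    types = trial_type_sequence(T)
    congruent = types == TrialType.CONGRUENT.value
    sds = {
        AgeGroup.YOUNG: (
            spec.cell(AgeGroup.YOUNG, TrialType.CONGRUENT).sd_rt,
            spec.cell(AgeGroup.YOUNG, TrialType.INCONGRUENT).sd_rt,
        ),
        AgeGroup.OLD: (
            spec.cell(AgeGroup.OLD, TrialType.CONGRUENT).sd_rt,
            spec.cell(AgeGroup.OLD, TrialType.INCONGRUENT).sd_rt,
        ),
    }

    rt_blocks = []
    for s in range(spec.n_studies):
        part_streams = children[s + 1].spawn(n_part)
        eps = np.stack(
            [np.random.default_rng(c).standard_normal(seq_len) for c in part_streams]
        )
        z = _ar1_path(eps, spec.ar_rho)
        row = adjusted.iloc[s]
        # (n_part, seq_len) cell-mean and sd matrices: first n rows young
        mean_mat = np.empty((n_part, seq_len))
        sd_mat = np.empty((n_part, seq_len))
        mean_mat[:n] = np.where(congruent, row["young_congruent"], row["young_incongruent"])
        mean_mat[n:] = np.where(congruent, row["old_congruent"], row["old_incongruent"])
        sd_mat[:n] = np.where(congruent, *sds[AgeGroup.YOUNG])
        sd_mat[n:] = np.where(congruent, *sds[AgeGroup.OLD])
        rt_blocks.append(mean_mat + sd_mat * z)

    rt = np.concatenate(rt_blocks).ravel()
    study_ids = np.repeat(
        [f"S{s + 1:03d}" for s in range(spec.n_studies)], n_part * seq_len
    )
    pid_one_study = np.repeat([f"P{j + 1:03d}" for j in range(n_part)], seq_len)
    participant_ids = np.char.add(
        np.char.add(study_ids, "_"), np.tile(pid_one_study, spec.n_studies)
    )
    age = np.repeat(
        [AgeGroup.YOUNG.value] * n + [AgeGroup.OLD.value] * n, seq_len
    )
    table = pd.DataFrame(
        {
            "study_id": study_ids,
            "participant_id": participant_ids,
            "age_group": np.tile(age, spec.n_studies),
            "trial_type": np.tile(types, spec.n_studies * n_part),
            "trial_index": np.tile(np.arange(1, seq_len + 1), spec.n_studies * n_part),
            "rt_ms": rt,
        }
    )
    return table


def validate_trial_table(table: pd.DataFrame) -> None:
    """Raise if ``table`` violates the trial-table schema or structure."""
    missing = [c for c in TRIAL_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"trial table missing column(s): {missing}")
    if len(table) == 0:
        raise FormatError("trial table has no rows")
    if not np.isfinite(table["rt_ms"].to_numpy(dtype=float)).all():
        raise FormatError("trial table contains non-finite rt_ms values")
    bad_age = set(table["age_group"].unique()) - {a.value for a in AgeGroup}
    if bad_age:
        raise FormatError(f"unknown age_group value(s): {sorted(bad_age)}")
    bad_tt = set(table["trial_type"].unique()) - {t.value for t in TrialType}
    if bad_tt:
        raise FormatError(f"unknown trial_type value(s): {sorted(bad_tt)}")
    counts = table.groupby(["participant_id", "trial_type"], observed=True).size()
    if counts.nunique() != 1:
        raise StructuralError("unbalanced trial counts per participant x trial type")


def write_trial_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write the trial table as CSV (full float precision, round-trip safe)."""
    validate_trial_table(table)
    table.to_csv(path, index=False)


def read_trial_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a trial-table CSV."""
    try:
        table = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty trial table file") from exc
    validate_trial_table(table)
    table["trial_index"] = table["trial_index"].astype(int)
    table["rt_ms"] = table["rt_ms"].astype(float)
    return table
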