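"""Shared fixtures: small and full-size simulated realizations.

Session-scoped so expensive simulations/fits are shared across test
modules.  Seeds are fixed; none of them were tuned to test outcomes.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import pytest

import brinleysim as bs

logging.disable(logging.WARNING)


@pytest.fixture(scope="session")
def library():
    return bs.build_case_library()


@pytest.fixture(scope="session")
def small_spec(library):
    """Case A scaled down for fast structural tests."""
    return replace(library["A"], n_studies=6, n_per_group=4, n_trials_per_type=5)


@pytest.fixture(scope="session")
def small_table(small_spec):
    return bs.simulate_case(small_spec, 123)


@pytest.fixture(scope="session")
def case_a_table(library):
    """One full-size Case A realization (50 studies x 100 x 40 trials)."""
    return bs.simulate_case(library["A"], 20260917)


@pytest.fixture(scope="session")
def case_a_means(case_a_table):
    return bs.study_condition_means(case_a_table)


def zero_noise_spec(library, case_id="A", n_studies=3, n_per_group=2, n_trials=2):
    """Deterministic variant: all cell SDs and disturbances zero."""
    spec = library[case_id]
    cells = tuple(replace(c, sd_rt=0.0) for c in spec.cells)
    dist = replace(spec.disturbance, sigma_study=0.0, sigma_interaction=0.0)
    return replace(
        spec,
        cells=cells,
        disturbance=dist,
        n_studies=n_studies,
        n_per_group=n_per_group,
        n_trials_per_type=n_trials,
    )


def standardized_residuals(spec, seed):
    """(participants, 2T) matrix of (rt - generative cell mean) / cell sd.

    Only valid for specs with zero disturbance (cell means known exactly).
    """
    import numpy as np

    table = bs.simulate_case(spec, seed)
    n_seq = 2 * spec.n_trials_per_type
    rt = table["rt_ms"].to_numpy().reshape(-1, n_seq)
    young = table["age_group"].to_numpy().reshape(-1, n_seq)[:, 0] == "young"
    means = np.empty_like(rt)
    sds = np.empty_like(rt)
    for age, mask in (("young", young), ("old", ~young)):
        mc = spec.cell(age, "congruent")
        mi = spec.cell(age, "incongruent")
        means[mask] = np.tile([mc.mean_rt, mi.mean_rt], spec.n_trials_per_type)
        sds[mask] = np.tile([mc.sd_rt, mi.sd_rt], spec.n_trials_per_type)
    return (rt - means) / sds
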