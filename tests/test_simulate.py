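"""Simulator oracles: AR(1) structure, disturbances, determinism, CSV I/O."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import brinleysim as bs
from brinleysim.errors import FormatError, InvalidParameterError
from conftest import standardized_residuals, zero_noise_spec  # noqa: F401 (zero_noise_spec used below)


# ---------------------------------------------------------------------------
# ar1_correlation


def test_ar1_correlation_examples():
    np.testing.assert_allclose(
        bs.ar1_correlation(3, 0.6),
        [[1, 0.6, 0.36], [0.6, 1, 0.6], [0.36, 0.6, 1]],
    )
    np.testing.assert_array_equal(bs.ar1_correlation(2, 0.0), np.eye(2))
    np.testing.assert_array_equal(bs.ar1_correlation(1, 0.9), [[1.0]])


@pytest.mark.parametrize("n, rho", [(0, 0.5), (3, 1.0), (3, -0.1)])
def test_ar1_correlation_invalid_parameters(n, rho):
    with pytest.raises(InvalidParameterError):
        bs.ar1_correlation(n, rho)


@given(n=st.integers(1, 12), rho=st.floats(0.0, 0.95))
@settings(max_examples=30, deadline=None, derandomize=True)
def test_ar1_correlation_is_valid_correlation_matrix(n, rho):
    m = bs.ar1_correlation(n, rho)
    assert np.allclose(m, m.T)
    assert np.allclose(np.diag(m), 1.0)
    assert np.linalg.eigvalsh(m).min() > 0  # positive definite


# ---------------------------------------------------------------------------
# draw_study_disturbances


def test_zero_sigma_disturbance_is_identity(library):
    spec = replace(library["A"], disturbance=replace(library["A"].disturbance, sigma_study=0.0))
    adj = bs.draw_study_disturbances(spec, 10, np.random.default_rng(0))
    assert (adj["young_congruent"] == 700).all()
    assert (adj["old_incongruent"] == 900).all()


def test_grand_shift_cancels_in_interaction_contrast(library):
    """A common per-study shift leaves the double difference at exactly 50 ms."""
    adj = bs.draw_study_disturbances(library["A"], 50, np.random.default_rng(7))
    contrast = (adj["old_incongruent"] - adj["old_congruent"]) - (
        adj["young_incongruent"] - adj["young_congruent"]
    )
    np.testing.assert_allclose(contrast, 50.0, rtol=0, atol=1e-12)
    # and the shift really moved all four cells identically
    shift = adj["young_congruent"] - 700
    assert shift.std() > 0
    np.testing.assert_allclose(adj["old_congruent"] - 750, shift)


def test_systematic_interaction_is_affine_in_grand_shift(library):
    """Case H: adjusted contrast = 50 + kappa * g_i, so corr(g, contrast) = 1."""
    adj = bs.draw_study_disturbances(library["H"], 50, np.random.default_rng(11))
    g = adj["young_congruent"] - 700
    contrast = (adj["old_incongruent"] - adj["old_congruent"]) - (
        adj["young_incongruent"] - adj["young_congruent"]
    )
    np.testing.assert_allclose(contrast, 50 + 1.5 * g, atol=1e-9)
    assert np.corrcoef(g, contrast)[0, 1] == pytest.approx(1.0, abs=1e-12)


def test_random_interaction_perturbs_every_cell_independently(library):
    """Case G adds independent per-cell noise on top of the grand shift, so
    the interaction contrast gains variance 4*sigma_interaction^2."""
    sigma = library["G"].disturbance.sigma_interaction
    adj = bs.draw_study_disturbances(library["G"], 2000, np.random.default_rng(3))
    base = {"young_congruent": 700, "young_incongruent": 800,
            "old_congruent": 750, "old_incongruent": 900}
    dev = pd.DataFrame({k: adj[k] - v for k, v in base.items()})
    # each cell deviation: grand shift (100) + own cell noise
    expected_sd = np.sqrt(100**2 + sigma**2)
    for col in dev:
        assert dev[col].std() == pytest.approx(expected_sd, rel=0.1)
    contrast = (dev["old_incongruent"] - dev["old_congruent"]) - (
        dev["young_incongruent"] - dev["young_congruent"]
    )
    assert contrast.mean() == pytest.approx(0, abs=4 * 2 * sigma / np.sqrt(2000))
    assert contrast.std() == pytest.approx(2 * sigma, rel=0.1)
    # cell increments beyond the shared shift are mutually independent
    resid = dev.sub(dev.mean(axis=1), axis=0)
    corr = resid.corr().to_numpy()
    assert np.all(np.abs(corr[~np.eye(4, dtype=bool)]) < 0.5)


# ---------------------------------------------------------------------------
# simulate_participant / AR structure


def test_zero_noise_participant_is_deterministic_alternation():
    rt, types = bs.simulate_participant(
        (700, 800), (0, 0), 3, 0.6, np.random.default_rng(0)
    )
    np.testing.assert_array_equal(rt, [700, 800, 700, 800, 700, 800])
    assert list(types) == ["congruent", "incongruent"] * 3


_standardized_residual_matrix = standardized_residuals


def _big_spec(library, rho):
    spec = library["A"]
    return replace(
        spec,
        n_studies=1,
        n_per_group=5000,
        ar_rho=rho,
        disturbance=replace(spec.disturbance, sigma_study=0.0),
    )


def test_lag_autocorrelation_matches_ar1(library):
    """Empirical lag-k autocorrelation ~ rho^k over 10,000 participants."""
    z = _standardized_residual_matrix(_big_spec(library, 0.6), 42)
    for k in (1, 2, 3):
        r = np.corrcoef(z[:, :-k].ravel(), z[:, k:].ravel())[0, 1]
        assert r == pytest.approx(0.6**k, abs=0.02)
    # lag-2 at the tighter documented tolerance
    r2 = np.corrcoef(z[:, :-2].ravel(), z[:, 2:].ravel())[0, 1]
    assert r2 == pytest.approx(0.36, abs=0.01)


def test_zero_rho_gives_independent_trials(library):
    z = _standardized_residual_matrix(_big_spec(library, 0.0), 43)
    r = np.corrcoef(z[:, :-1].ravel(), z[:, 1:].ravel())[0, 1]
    assert abs(r) < 0.01


# ---------------------------------------------------------------------------
# simulate_case


def test_case_row_count_and_structure(library):
    spec = replace(library["A"], n_studies=3)
    table = bs.simulate_case(spec, 5)
    assert len(table) == 3 * (50 + 50) * 40
    counts = table.groupby(["participant_id", "trial_type"], observed=True).size()
    assert (counts == 20).all()
    per_study = table.groupby(["study_id", "age_group"], observed=True)[
        "participant_id"
    ].nunique()
    assert (per_study == 50).all()


def test_simulated_cell_means_match_generative_values(case_a_table, library):
    """Grand cell means within 4 Monte-Carlo SEs of the generative means."""
    spec = library["A"]
    for age in ("young", "old"):
        for tt in ("congruent", "incongruent"):
            cell = spec.cell(age, tt)
            sub = case_a_table[
                (case_a_table["age_group"] == age)
                & (case_a_table["trial_type"] == tt)
            ]
            # study-level means are exchangeable; their spread estimates the
            # MC error of the grand mean (covers AR inflation + disturbance)
            study_means = sub.groupby("study_id", observed=True)["rt_ms"].mean()
            se = study_means.std(ddof=1) / np.sqrt(len(study_means))
            assert abs(study_means.mean() - cell.mean_rt) < 4 * se


def test_same_spec_and_seed_give_identical_csv(small_spec, tmp_path):
    p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
    bs.write_trial_table(bs.simulate_case(small_spec, 99), p1)
    bs.write_trial_table(bs.simulate_case(small_spec, 99), p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_extending_n_studies_preserves_earlier_studies(small_spec):
    t_small = bs.simulate_case(small_spec, 7)
    t_big = bs.simulate_case(replace(small_spec, n_studies=9), 7)
    first = t_big[t_big["study_id"].isin(t_small["study_id"].unique())]
    pd.testing.assert_frame_equal(
        first.reset_index(drop=True), t_small.reset_index(drop=True)
    )


# ---------------------------------------------------------------------------
# trial-table CSV round trip


def test_trial_table_roundtrip(small_table, tmp_path):
    path = tmp_path / "t.csv"
    bs.write_trial_table(small_table, path)
    back = bs.read_trial_table(path)
    pd.testing.assert_frame_equal(back, small_table)


def test_read_trial_table_missing_column(small_table, tmp_path):
    path = tmp_path / "bad.csv"
    small_table.drop(columns=["rt_ms"]).to_csv(path, index=False)
    with pytest.raises(FormatError, match="rt_ms"):
        bs.read_trial_table(path)


def test_read_trial_table_empty_file(tmp_path):
    path = tmp_path / "empty.csv"
    path.write_text("")
    with pytest.raises(FormatError):
        bs.read_trial_table(path)
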