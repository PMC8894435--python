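"""Study-level Brinley mixed regression and the nested model comparison."""

import numpy as np
import pandas as pd
import pytest

import brinleysim as bs
from brinleysim.brinley import BrinleyFit
from brinleysim.errors import StructuralError


@pytest.fixture(scope="module")
def collinear_means():
    rows = []
    for s in range(5):
        yc = 650 + 20 * s
        yi = yc + 80
        rows.append((f"S{s}", "congruent", float(yc), float(yc + 100)))
        rows.append((f"S{s}", "incongruent", float(yi), float(yi + 100)))
    return pd.DataFrame(
        rows, columns=["study_id", "trial_type", "young_mean_rt", "old_mean_rt"]
    )


@pytest.fixture(scope="module")
def case_a_fits(case_a_means):
    restricted = bs.fit_brinley(case_a_means, include_interaction=False)
    full = bs.fit_brinley(case_a_means, include_interaction=True)
    return restricted, full


def test_exact_affine_relation_recovered(collinear_means):
    """old = young + 100 exactly -> slope 1, intercept 100, no interaction."""
    fit = bs.fit_brinley(collinear_means, include_interaction=False)
    assert fit.beta["beta2"] == pytest.approx(1.0, abs=1e-6)
    assert fit.beta["beta0"] == pytest.approx(100.0, abs=1e-4)
    assert fit.beta["beta1"] == pytest.approx(0.0, abs=1e-6)
    assert fit.var_intercept == pytest.approx(0.0, abs=1e-8)
    assert fit.var_slope == pytest.approx(0.0, abs=1e-8)
    assert fit.var_residual == pytest.approx(0.0, abs=1e-8)
    assert fit.r2_marginal == pytest.approx(1.0, abs=1e-6)


def test_case_a_restricted_betas_match_published_values(case_a_fits):
    """Restricted fit on Case A: beta1 ~ 50.03 (3 x 2.21), beta2 in [0.93, 1.05]."""
    restricted, _ = case_a_fits
    assert restricted.beta["beta1"] == pytest.approx(50.03, abs=3 * 2.21)
    assert 0.93 <= restricted.beta["beta2"] <= 1.05
    assert restricted.r2_marginal == pytest.approx(0.99, abs=0.02)


def test_moment_slope_cross_check(case_a_means):
    """Per-condition method-of-moments slope cov(old,young)/var(young)
    brackets the mixed-model slope (independent oracle on the same data)."""
    slopes = []
    for _, sub in case_a_means.groupby("trial_type", observed=True):
        x = sub["young_mean_rt"].to_numpy()
        y = sub["old_mean_rt"].to_numpy()
        slopes.append(np.cov(x, y)[0, 1] / np.var(x, ddof=1))
    fit = bs.fit_brinley(case_a_means, include_interaction=False)
    assert fit.beta["beta2"] == pytest.approx(np.mean(slopes), rel=0.10)


def test_fit_identities_and_nesting(case_a_fits):
    restricted, full = case_a_fits
    for fit, k in ((restricted, 5), (full, 6)):
        assert fit.n_parameters == k
        assert fit.deviance == pytest.approx(-2 * fit.loglik)
        assert fit.aic == pytest.approx(fit.deviance + 2 * k)
        assert fit.bic == pytest.approx(fit.deviance + k * np.log(fit.n_obs))
        assert 0 <= fit.r2_marginal <= 1
        assert fit.var_intercept >= 0 and fit.var_slope >= 0
        assert fit.cov_intercept_slope**2 <= fit.var_intercept * fit.var_slope + 1e-8
    assert full.loglik >= restricted.loglik - 1e-6


def test_compare_models_on_case_a_prefers_restricted(case_a_fits):
    restricted, full = case_a_fits
    comp = bs.compare_models(full, restricted)
    assert comp.df_diff == 1
    assert comp.delta_chi2 >= 0
    assert comp.p_value > 0.05
    assert comp.preferred_model == "restricted"


def test_compare_models_identical_deviance():
    fit = BrinleyFit(
        include_interaction=False, beta={}, se={}, p={},
        var_intercept=0, var_slope=0, cov_intercept_slope=0, var_residual=1,
        loglik=-10.0, n_obs=20, n_parameters=5, r2_marginal=0.5,
        converged=True, boundary=False,
    )
    full = BrinleyFit(
        include_interaction=True, beta={}, se={}, p={},
        var_intercept=0, var_slope=0, cov_intercept_slope=0, var_residual=1,
        loglik=-10.0, n_obs=20, n_parameters=6, r2_marginal=0.5,
        converged=True, boundary=False,
    )
    comp = bs.compare_models(full, fit)
    assert comp.delta_chi2 == 0
    assert comp.p_value == pytest.approx(1.0)
    assert comp.preferred_model == "restricted"


def test_marginal_r2_edge_cases():
    design = pd.DataFrame(
        {
            "study_id": ["S1", "S1", "S2", "S2"],
            "trial_type": ["congruent", "incongruent"] * 2,
            "young_mean_rt": [700.0, 800.0, 720.0, 820.0],
            "old_mean_rt": [750.0, 900.0, 770.0, 920.0],
        }
    )
    base = dict(
        include_interaction=False, se={}, p={},
        var_intercept=0.0, var_slope=0.0, cov_intercept_slope=0.0,
        loglik=0.0, n_obs=4, n_parameters=5, r2_marginal=np.nan,
        converged=True, boundary=False,
    )
    # no random/residual variance, nonconstant predictor -> 1
    fit = BrinleyFit(beta={"beta0": 0, "beta1": 10, "beta2": 1}, var_residual=0.0, **base)
    assert bs.marginal_r2(fit, design) == pytest.approx(1.0)
    # intercept-only fixed part -> 0
    fit0 = BrinleyFit(beta={"beta0": 5, "beta1": 0, "beta2": 0}, var_residual=3.0, **base)
    assert bs.marginal_r2(fit0, design) == pytest.approx(0.0)


def test_fit_requires_enough_complete_studies(collinear_means):
    with pytest.raises(StructuralError):
        bs.fit_brinley(collinear_means.iloc[:4], include_interaction=False)
    broken = collinear_means[
        ~(
            (collinear_means["study_id"] == "S2")
            & (collinear_means["trial_type"] == "incongruent")
        )
    ]
    with pytest.raises(StructuralError, match="S2"):
        bs.fit_brinley(broken, include_interaction=False)
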