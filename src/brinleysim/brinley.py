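"""Study-level Brinley meta-regression with nested model comparison.

The model regresses old-group condition means on young-group condition
means across studies:

    old_ij = b0 + b1*TT_j + b2*young_ij + b3*TT_j*young_ij
             + u0_i + u1_i*young_ij + e_ij

with TT coded 0 (congruent) / 1 (incongruent), a per-study random
intercept u0 and random slope u1 with unstructured 2x2 covariance, and the
interaction term b3 present only in the full model.  Fits maximize the
full marginal likelihood (ML, not REML) so that the likelihood-ratio test
of full vs restricted on 1 df is valid.

With two observations per study and a bivariate random effect this model
sits at the edge of identifiability (as many random effects as
observations), and generic mixed-model optimizers land in different local
optima for the two nested fits, which corrupts the small likelihood-ratio
statistics the comparison turns on.  We therefore fit by direct
optimization of the profiled deviance: the fixed effects and the residual
variance are profiled out in closed form (each study contributes a 2x2
marginal covariance block), leaving a 3-parameter log-Cholesky
parameterization of the relative random-effects covariance that is shared
by both models.  A deterministic multistart grid plus a warm start of the
full model at the restricted optimum makes the fits symmetric and
guarantees delta-chi-square >= 0 (the restricted optimum is a feasible
point of the full model).  ``statsmodels``' MixedLM serves as an
independent cross-check in the test suite.

AIC/BIC bookkeeping: the reported parameter counts follow the published
convention (restricted 5, full 6) rather than the literal free-parameter
count of the unstructured model (7/8); deviance = -2*loglik, so
aic = deviance + 2*k and bic = deviance + k*log(n_obs) with k in {5, 6}.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .cases import TrialType
from .errors import FitFailureError, StructuralError

__all__ = [
    "BrinleyFit",
    "ModelComparison",
    "fit_brinley",
    "fit_brinley_models",
    "marginal_r2",
    "compare_models",
]

logger = logging.getLogger(__name__)

_N_PARAMETERS = {False: 5, True: 6}  # reported-df convention
_SIGMA2_FLOOR = 1e-12
_BOUNDARY_TOL = 1e-7

# Deterministic multistart grid for the log-Cholesky parameters (a, b, c)
# of the relative RE covariance; covers tiny-to-large variance ratios.
_STARTS = [
    np.array([a, b, 0.0])
    for a in (-6.0, -1.0, 1.5, 4.0)
    for b in (-6.0, -1.0, 1.5, 4.0)
] + [np.array([-12.0, -12.0, 0.0])]
_BOUNDS = [(-15.0, 12.0), (-15.0, 12.0), (-200.0, 200.0)]


@dataclass
class BrinleyFit:
    """Fitted study-level mixed regression (ML)."""

    include_interaction: bool
    beta: dict[str, float]           # beta0, beta1, beta2 (+ beta3 if full)
    se: dict[str, float]
    p: dict[str, float]              # Wald tests, normal reference
    var_intercept: float             # var(u0_i)
    var_slope: float                 # var(u1_i)
    cov_intercept_slope: float
    var_residual: float
    loglik: float
    n_obs: int
    n_parameters: int
    r2_marginal: float
    converged: bool
    boundary: bool                   # singular random-effects covariance
    design: pd.DataFrame = field(repr=False, default=None)
    theta: np.ndarray = field(repr=False, default=None)  # internal optimum

    @property
    def deviance(self) -> float:
        return -2.0 * self.loglik

    @property
    def aic(self) -> float:
        return self.deviance + 2 * self.n_parameters

    @property
    def bic(self) -> float:
        return self.deviance + self.n_parameters * np.log(self.n_obs)


@dataclass
class ModelComparison:
    """Likelihood-ratio comparison of the nested Brinley models."""

    delta_chi2: float
    df_diff: int
    p_value: float
    preferred_model: str  # "restricted" or "full"


def _design_frame(means: pd.DataFrame) -> pd.DataFrame:
    df = means.copy()
    df["tt"] = (df["trial_type"] == TrialType.INCONGRUENT.value).astype(float)
    return df


class _ProfiledModel:
    """Profiled ML for the two-obs-per-group random-slope model.

    Works on standardized x internally; ``theta = (a, b, c)`` parameterizes
    the relative RE covariance Psi_rel = L L' with L = [[e^a, 0], [c, e^b]],
    so the marginal covariance of group i is sigma2 * (Z_i Psi_rel Z_i' + I).
    """

    def __init__(self, df: pd.DataFrame, include_interaction: bool):
        order = np.lexsort((df["tt"].to_numpy(), df["study_id"].to_numpy()))
        df = df.iloc[order]
        self.y = df["old_mean_rt"].to_numpy(dtype=float)
        x_raw = df["young_mean_rt"].to_numpy(dtype=float)
        tt = df["tt"].to_numpy(dtype=float)
        self.x_mean = float(x_raw.mean())
        self.x_scale = float(x_raw.std()) or 1.0
        x = (x_raw - self.x_mean) / self.x_scale
        cols = [np.ones_like(x), tt, x] + ([tt * x] if include_interaction else [])
        self.X = np.column_stack(cols)
        self.S = df["study_id"].nunique()
        self.n = len(df)
        # (S, 2, k) group-blocked views; groups are contiguous after sorting
        self.Z = np.column_stack([np.ones_like(x), x]).reshape(self.S, 2, 2)
        self.Xg = self.X.reshape(self.S, 2, -1)
        self.yg = self.y.reshape(self.S, 2)

    @staticmethod
    def _psi_rel(theta: np.ndarray) -> np.ndarray:
        L = np.array([[np.exp(theta[0]), 0.0], [theta[2], np.exp(theta[1])]])
        return L @ L.T

    def _blocks(self, theta: np.ndarray):
        psi = self._psi_rel(theta)
        V = self.Z @ psi @ np.swapaxes(self.Z, 1, 2) + np.eye(2)
        det = V[:, 0, 0] * V[:, 1, 1] - V[:, 0, 1] * V[:, 1, 0]
        inv = (
            np.stack(
                [
                    np.stack([V[:, 1, 1], -V[:, 0, 1]], axis=-1),
                    np.stack([-V[:, 1, 0], V[:, 0, 0]], axis=-1),
                ],
                axis=1,
            )
            / det[:, None, None]
        )
        return inv, det

    def profile(self, theta: np.ndarray):
        """GLS beta, profiled sigma2 and -2 loglik at relative covariance theta."""
        W, det = self._blocks(theta)
        if not np.all(det > 0) or not np.all(np.isfinite(det)):
            return None
        XtW = np.einsum("sik,sij->skj", self.Xg, W)
        A = np.einsum("skj,sjl->kl", XtW, self.Xg)
        b = np.einsum("skj,sj->k", XtW, self.yg)
        try:
            beta = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            return None
        resid = self.yg - np.einsum("sjk,k->sj", self.Xg, beta)
        rss = float(np.einsum("sj,sjk,sk->", resid, W, resid))
        sigma2 = max(rss / self.n, _SIGMA2_FLOOR)
        neg2ll = (
            self.n * (np.log(2 * np.pi * sigma2) + 1.0)
            + float(np.log(det).sum())
        )
        return dict(beta=beta, sigma2=sigma2, neg2ll=neg2ll, A=A, theta=theta)

    def objective(self, theta: np.ndarray) -> float:
        out = self.profile(theta)
        return out["neg2ll"] if out is not None else 1e12

    def fit(self, extra_starts: list[np.ndarray] = ()) -> dict:
        best = None
        for start in list(_STARTS) + list(extra_starts):
            res = optimize.minimize(
                self.objective, start, method="L-BFGS-B", bounds=_BOUNDS
            )
            if best is None or res.fun < best.fun:
                best = res
        # polish with a derivative-free pass (profiled surface can be kinky
        # near singular Psi)
        res = optimize.minimize(
            self.objective, best.x, method="Nelder-Mead",
            options=dict(xatol=1e-10, fatol=1e-10, maxiter=2000),
        )
        if res.fun < best.fun:
            best = res
        out = self.profile(best.x)
        if out is None:
            raise FitFailureError("profiled likelihood undefined at optimum")
        out["success"] = bool(best.success or res.success)
        return out


def fit_brinley(
    means: pd.DataFrame,
    include_interaction: bool,
    extra_starts: list[np.ndarray] | None = None,
) -> BrinleyFit:
    """Fit the Brinley mixed model to study-condition means by ML.

    ``extra_starts`` adds warm starts in the shared variance-parameter
    space (used by :func:`fit_brinley_models` to optimize the two nested
    fits symmetrically).
    """
    n_studies = means["study_id"].nunique()
    if n_studies < 3:
        raise StructuralError(f"need >= 3 studies, got {n_studies}")
    per_study = means.groupby("study_id", observed=True)["trial_type"].nunique()
    if (per_study < 2).any():
        raise StructuralError(
            f"study(ies) missing a trial type: {per_study[per_study < 2].index.tolist()}"
        )
    df = _design_frame(means)
    model = _ProfiledModel(df, include_interaction)

    extra = list(extra_starts) if extra_starts is not None else []
    if include_interaction and not extra:
        # Warm start at the restricted optimum: a feasible point of the full
        # model, so the full-model deviance can never exceed the restricted
        # one beyond optimizer tolerance.
        nested = _ProfiledModel(df, include_interaction=False).fit()
        extra.append(nested["theta"])
    out = model.fit(extra_starts=extra)

    # Map back to the raw young-mean scale.
    m, s = model.x_mean, model.x_scale
    sigma2 = out["sigma2"]
    psi = sigma2 * model._psi_rel(out["theta"])
    var_int = psi[0, 0] - 2 * (m / s) * psi[0, 1] + (m / s) ** 2 * psi[1, 1]
    var_slope = psi[1, 1] / s**2
    cov_is = (psi[0, 1] - (m / s) * psi[1, 1]) / s

    k = model.X.shape[1]
    C = np.zeros((k, k))
    C[0, 0] = 1.0
    C[0, 2] = -m / s
    C[1, 1] = 1.0
    C[2, 2] = 1.0 / s
    if include_interaction:
        C[1, 3] = -m / s
        C[3, 3] = 1.0 / s
    beta_raw = C @ out["beta"]
    cov_beta = sigma2 * np.linalg.inv(out["A"])
    se_raw = np.sqrt(np.clip(np.diag(C @ cov_beta @ C.T), 0.0, None))

    names = ["beta0", "beta1", "beta2"] + (["beta3"] if include_interaction else [])
    beta = dict(zip(names, beta_raw.tolist()))
    se = dict(zip(names, se_raw.tolist()))
    z = np.divide(
        beta_raw, se_raw, out=np.full_like(beta_raw, np.inf), where=se_raw > 0
    )
    p = dict(zip(names, (2 * stats.norm.sf(np.abs(z))).tolist()))

    re_cov = np.array([[var_int, cov_is], [cov_is, var_slope]])
    eigmin = float(np.linalg.eigvalsh(re_cov).min())
    boundary = eigmin <= _BOUNDARY_TOL * max(1.0, float(np.abs(re_cov).max()))
    if boundary:
        logger.warning(
            "Brinley fit (%s model): random-effects covariance is singular/boundary",
            "full" if include_interaction else "restricted",
        )

    fit = BrinleyFit(
        include_interaction=include_interaction,
        beta=beta,
        se=se,
        p=p,
        var_intercept=float(max(var_int, 0.0)),
        var_slope=float(max(var_slope, 0.0)),
        cov_intercept_slope=float(cov_is),
        var_residual=float(sigma2),
        loglik=-0.5 * float(out["neg2ll"]),
        n_obs=model.n,
        n_parameters=_N_PARAMETERS[include_interaction],
        r2_marginal=np.nan,
        converged=bool(out["success"]),
        boundary=boundary,
        design=df,
        theta=np.asarray(out["theta"]),
    )
    fit.r2_marginal = marginal_r2(fit)
    return fit


def fit_brinley_models(
    means: pd.DataFrame,
) -> tuple[BrinleyFit, BrinleyFit, "ModelComparison"]:
    """Fit restricted and full models symmetrically and compare them.

    The full fit is warm-started at the restricted variance optimum and the
    restricted fit is then re-polished from the full optimum (the two
    models share the variance-parameter space), so the likelihood-ratio
    statistic reflects the models rather than optimizer luck.
    """
    restricted = fit_brinley(means, include_interaction=False)
    full = fit_brinley(means, True, extra_starts=[restricted.theta])
    repolish = fit_brinley(means, False, extra_starts=[full.theta])
    if repolish.loglik > restricted.loglik + 1e-9:
        restricted = repolish
    return restricted, full, compare_models(full, restricted)


def marginal_r2(fit: BrinleyFit, design: pd.DataFrame | None = None) -> float:
    """Nakagawa-Schielzeth marginal R^2 of a Brinley fit.

    Variance of the fixed-effect predictor over the observed design divided
    by that variance plus the random-effect variance evaluated at the
    observed covariates plus the residual variance.
    """
    df = fit.design if design is None else _design_frame(design)
    x = df["young_mean_rt"].to_numpy(dtype=float)
    tt = df["tt"].to_numpy(dtype=float)
    eta = fit.beta["beta0"] + fit.beta["beta1"] * tt + fit.beta["beta2"] * x
    if fit.include_interaction:
        eta = eta + fit.beta["beta3"] * tt * x
    var_fixed = float(np.var(eta))
    # z_i' Psi z_i averaged over observations, z = (1, young)
    var_re = float(
        np.mean(
            fit.var_intercept
            + 2.0 * fit.cov_intercept_slope * x
            + fit.var_slope * x**2
        )
    )
    total = var_fixed + max(var_re, 0.0) + max(fit.var_residual, 0.0)
    if total <= 0:
        return 0.0
    return float(np.clip(var_fixed / total, 0.0, 1.0))


def compare_models(full: BrinleyFit, restricted: BrinleyFit) -> ModelComparison:
    """Delta-chi-square test of the interaction term (1 df, alpha 0.05)."""
    if restricted.include_interaction or not full.include_interaction:
        raise ValueError("expected (full with interaction, restricted without)")
    if restricted.n_obs != full.n_obs:
        raise ValueError("models were fit to different data")
    delta = restricted.deviance - full.deviance
    if delta < -1e-6:
        raise FitFailureError(
            f"negative likelihood-ratio statistic ({delta:.3g}): "
            "full-model optimum is worse than restricted despite warm start"
        )
    delta = max(delta, 0.0)
    df_diff = 1
    p_value = float(stats.chi2.sf(delta, df_diff))
    return ModelComparison(
        delta_chi2=float(delta),
        df_diff=df_diff,
        p_value=p_value,
        preferred_model="full" if p_value < 0.05 else "restricted",
    )
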