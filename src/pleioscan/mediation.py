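"""Causal mediation decomposition for replicated pleiotropic variants.

Two linear models are fit with heteroskedasticity-robust (sandwich)
covariances and no mediator-by-genotype interaction:

    mediator ~ genotype + covariates
    outcome  ~ mediator + genotype + covariates

Quasi-Bayesian Monte-Carlo simulation draws parameter vectors from the
normal approximation around each fit; per draw the average causal mediation
effect (ACME) is the product of the genotype->mediator and mediator->outcome
coefficients (exact for linear no-interaction models), the average direct
effect (ADE) is the genotype coefficient of the outcome model, and the total
effect is their sum -- an identity that holds draw by draw. Point estimates
are the analytic products so that total = ADE + ACME holds exactly;
confidence intervals and p-values come from the simulation draws.

Sensitivity to unmeasured mediator-outcome confounding follows the
linear-structural-equation identity for correlated model errors: the ACME
as a function of the error correlation rho crosses zero exactly at the
observed residual correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

DIRECTION_PRIORS = ("inflammation", "adiposity")


def choose_direction(
    snp_prior: str, adiposity_trait: str = "BMI"
) -> tuple[str, str]:
    """Map a SNP's prior trait association to (mediator, outcome) roles.

    A variant primarily known for inflammation is tested with CRP as the
    mediator and the adiposity trait as the outcome; an adiposity-prior
    variant is tested the other way around.
    """
    if snp_prior == "inflammation":
        return "CRP", adiposity_trait
    if snp_prior == "adiposity":
        return adiposity_trait, "CRP"
    raise ValueError(
        f"unknown prior {snp_prior!r}; assign one of {DIRECTION_PRIORS} "
        "explicitly"
    )


@dataclass
class MediationModelFit:
    """One fitted component model with robust covariance."""

    role: str  # "mediator_model" | "outcome_model"
    params: pd.Series
    vcov: pd.DataFrame
    residual_sd: float
    n: int
    # retained data for the sensitivity identity
    _X: pd.DataFrame = field(repr=False, default=None)
    _y: np.ndarray = field(repr=False, default=None)


@dataclass
class MediationResult:
    acme: float
    acme_ci: tuple[float, float]
    acme_p: float
    ade: float
    ade_ci: tuple[float, float]
    ade_p: float
    total: float
    total_ci: tuple[float, float]
    total_p: float
    n_sims: int
    seed: int
    mediator_name: str = "mediator"
    outcome_name: str = "outcome"
    acme_median: float = np.nan
    ade_median: float = np.nan
    total_median: float = np.nan


@dataclass
class SensitivityCurve:
    rho_grid: np.ndarray
    acme_at_rho: np.ndarray
    rho_zero_crossing: float | None


def fit_models(
    dosage: pd.Series | np.ndarray,
    mediator: pd.Series | np.ndarray,
    outcome: pd.Series | np.ndarray,
    covariates: pd.DataFrame,
) -> tuple[MediationModelFit, MediationModelFit]:
    """Fit the mediator and outcome models on complete cases.

    Covariates typically hold age, sex and the leading genetic PCs. Both
    fits use HC0 sandwich covariances; collinear covariate columns are
    dropped with a warning by the underlying pinv-based solver.
    """
    df = pd.DataFrame(covariates).copy()
    df.insert(0, "genotype", np.asarray(dosage, dtype=float))
    med = np.asarray(mediator, dtype=float)
    out = np.asarray(outcome, dtype=float)
    complete = (
        ~df.isna().any(axis=1).to_numpy() & ~np.isnan(med) & ~np.isnan(out)
    )
    df = df.loc[complete].reset_index(drop=True)
    med = med[complete]
    out = out[complete]

    X_med = sm.add_constant(df, has_constant="add")
    fit_med = sm.OLS(med, X_med).fit(cov_type="HC0")

    X_out = X_med.copy()
    X_out.insert(1, "mediator", med)
    fit_out = sm.OLS(out, X_out).fit(cov_type="HC0")

    med_fit = MediationModelFit(
        role="mediator_model",
        params=fit_med.params,
        vcov=pd.DataFrame(fit_med.cov_params(), index=fit_med.params.index,
                          columns=fit_med.params.index),
        residual_sd=float(np.sqrt(fit_med.mse_resid)),
        n=int(fit_med.nobs),
        _X=X_med,
        _y=med,
    )
    out_fit = MediationModelFit(
        role="outcome_model",
        params=fit_out.params,
        vcov=pd.DataFrame(fit_out.cov_params(), index=fit_out.params.index,
                          columns=fit_out.params.index),
        residual_sd=float(np.sqrt(fit_out.mse_resid)),
        n=int(fit_out.nobs),
        _X=X_out,
        _y=out,
    )
    return med_fit, out_fit


def _draw_params(fit: MediationModelFit, n_sims: int,
                 rng: np.random.Generator) -> pd.DataFrame:
    V = fit.vcov.to_numpy()
    # ridge-repair a numerically non-PSD sandwich
    min_eig = np.linalg.eigvalsh(V).min()
    if min_eig < 0:
        V = V + (1e-12 - min_eig) * np.eye(V.shape[0])
    L = np.linalg.cholesky(V)
    draws = fit.params.to_numpy()[None, :] + \
        rng.standard_normal((n_sims, V.shape[0])) @ L.T
    return pd.DataFrame(draws, columns=fit.params.index)


def _mc_p(draws: np.ndarray) -> float:
    neg = float(np.mean(draws < 0))
    pos = float(np.mean(draws > 0))
    return min(1.0, 2.0 * min(neg, pos))


def mediate(
    med_fit: MediationModelFit,
    out_fit: MediationModelFit,
    n_sims: int = 1000,
    seed: int = 0,
    mediator_name: str = "mediator",
    outcome_name: str = "outcome",
) -> MediationResult:
    """Quasi-Bayesian mediation decomposition.

    The genotype contrast is a one-allele increment on the dosage scale.
    Point estimates are the analytic product/coefficient values; the
    percentile CIs and two-sided Monte-Carlo p-values summarize ``n_sims``
    parameter draws.
    """
    if "genotype" not in med_fit.params or "genotype" not in out_fit.params:
        raise ValueError("both fits must include a genotype term")
    rng = np.random.default_rng(seed)
    d_med = _draw_params(med_fit, n_sims, rng)
    d_out = _draw_params(out_fit, n_sims, rng)
    acme_draws = d_med["genotype"].to_numpy() * d_out["mediator"].to_numpy()
    ade_draws = d_out["genotype"].to_numpy()
    total_draws = acme_draws + ade_draws

    a_hat = float(med_fit.params["genotype"])
    b_hat = float(out_fit.params["mediator"])
    c_hat = float(out_fit.params["genotype"])

    def ci(d):
        lo, hi = np.percentile(d, [2.5, 97.5])
        return (float(lo), float(hi))

    return MediationResult(
        acme=a_hat * b_hat,
        acme_ci=ci(acme_draws),
        acme_p=_mc_p(acme_draws),
        ade=c_hat,
        ade_ci=ci(ade_draws),
        ade_p=_mc_p(ade_draws),
        total=a_hat * b_hat + c_hat,
        total_ci=ci(total_draws),
        total_p=_mc_p(total_draws),
        n_sims=n_sims,
        seed=seed,
        mediator_name=mediator_name,
        outcome_name=outcome_name,
        acme_median=float(np.median(acme_draws)),
        ade_median=float(np.median(ade_draws)),
        total_median=float(np.median(total_draws)),
    )


def sensitivity(
    med_fit: MediationModelFit,
    out_fit: MediationModelFit,
    result: MediationResult,
    rho_grid: np.ndarray,
) -> SensitivityCurve:
    """ACME as a function of the mediator/outcome error correlation rho.

    Let eps1 be the mediator-model residuals and eps2 the residuals of the
    reduced-form outcome model (outcome on genotype and covariates, the
    mediator omitted), with second moments s11, s12, s22. The
    bias-corrected mediator coefficient at error correlation rho is

        b(rho) = (s12 - rho * sqrt((s11*s22 - s12^2) / (1 - rho^2))) / s11

    and ACME(rho) = a_hat * b(rho). At rho = 0 this reproduces the point
    estimate exactly; ACME crosses zero at the observed residual
    correlation rho* = s12 / sqrt(s11 * s22).
    """
    rho = np.asarray(rho_grid, dtype=float)
    if np.any(np.abs(rho) >= 1):
        raise ValueError("rho grid must lie strictly inside (-1, 1)")
    if med_fit._X is None or out_fit._X is None:
        raise ValueError("fits must retain their data for sensitivity")

    X1 = med_fit._X.to_numpy(dtype=float)
    eps1 = med_fit._y - X1 @ np.linalg.lstsq(X1, med_fit._y, rcond=None)[0]
    X_red = out_fit._X.drop(columns=["mediator"]).to_numpy(dtype=float)
    eps2 = out_fit._y - X_red @ np.linalg.lstsq(X_red, out_fit._y,
                                                rcond=None)[0]
    n = eps1.size
    s11 = float(eps1 @ eps1) / n
    s22 = float(eps2 @ eps2) / n
    s12 = float(eps1 @ eps2) / n

    a_hat = float(med_fit.params["genotype"])
    det = max(s11 * s22 - s12 * s12, 0.0)
    b_rho = (s12 - rho * np.sqrt(det / (1.0 - rho**2))) / s11
    acme = a_hat * b_rho

    rho_star = s12 / np.sqrt(s11 * s22) if s11 > 0 and s22 > 0 else None
    crossing = None
    if rho_star is not None and np.sign(acme[0]) != np.sign(acme[-1]):
        crossing = float(rho_star)
    return SensitivityCurve(rho_grid=rho, acme_at_rho=acme,
                            rho_zero_crossing=crossing)


def total_effect(ade: float, acme: float) -> float:
    """Total effect identity for linear no-interaction mediation:
    the direct and mediated components sum to the total."""
    return ade + acme


def mediation_table(results: dict[str, MediationResult],
                    genes: dict[str, str] | None = None) -> pd.DataFrame:
    """Tabulate mediation results (one row per SNP)."""
    rows = []
    for snp, r in results.items():
        rows.append(
            {
                "SNP": snp,
                "GENE": (genes or {}).get(snp, "."),
                "MEDIATOR": r.mediator_name,
                "OUTCOME": r.outcome_name,
                "ADE": r.ade,
                "ADE_CI_LO": r.ade_ci[0],
                "ADE_CI_HI": r.ade_ci[1],
                "ADE_P": r.ade_p,
                "ACME": r.acme,
                "ACME_CI_LO": r.acme_ci[0],
                "ACME_CI_HI": r.acme_ci[1],
                "ACME_P": r.acme_p,
                "TOTAL": r.total,
                "TOTAL_CI_LO": r.total_ci[0],
                "TOTAL_CI_HI": r.total_ci[1],
                "TOTAL_P": r.total_p,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["SNP", "GENE", "MEDIATOR", "OUTCOME",
                 "ADE", "ADE_CI_LO", "ADE_CI_HI", "ADE_P",
                 "ACME", "ACME_CI_LO", "ACME_CI_HI", "ACME_P",
                 "TOTAL", "TOTAL_CI_LO", "TOTAL_CI_HI", "TOTAL_P"],
    )
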