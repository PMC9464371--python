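"""Phenotype preparation: transform, outlier exclusion, residualization, INT.

The four analysis traits are CRP (log scale), BMI, and sex-stratified
waist-to-hip ratio (WHR, multiplied by 100). The fixed pipeline order is
transform -> outlier exclusion -> covariate residualization -> inverse
normal transform; the INT residuals are the GWAS outcomes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_data import CohortTable

logger = logging.getLogger(__name__)

ANALYSIS_TRAITS = ("CRP", "BMI", "WHR_men", "WHR_women")

#: SD multipliers for the single-pass outlier rule, per trait.
OUTLIER_K = {"CRP": 3.0, "BMI": 4.0, "WHR_men": 4.0, "WHR_women": 4.0}


@dataclass
class AnalysisTrait:
    """One prepared trait: INT residuals indexed by retained individuals."""

    trait_name: str
    int_residuals: pd.Series
    n_excluded_outlier: int = 0
    n_excluded_missing: int = 0
    audit: pd.DataFrame = field(default_factory=pd.DataFrame)


def log_transform(crp: np.ndarray | pd.Series) -> np.ndarray:
    """Natural log, defined only for strictly positive values."""
    values = np.asarray(crp, dtype=float)
    bad = np.where(~(values > 0))[0]
    if bad.size:
        raise ValueError(
            f"non-positive value at row {bad[0]} ({values[bad[0]]}); "
            "log transform requires values > 0"
        )
    return np.log(values)


def flag_outliers(values: np.ndarray | pd.Series, k: float) -> np.ndarray:
    """Boolean mask of values more than k SDs from the mean (single pass).

    Mean and SD are computed once on non-missing values; there is no
    iterative re-flagging. A zero SD (constant input) flags nothing.
    """
    if k <= 0:
        raise ValueError("k must be > 0")
    v = np.asarray(values, dtype=float)
    ok = ~np.isnan(v)
    if ok.sum() < 3:
        raise ValueError("need at least 3 non-missing values")
    mu = v[ok].mean()
    sd = v[ok].std(ddof=0)
    mask = np.zeros(v.shape, dtype=bool)
    if sd > 0:
        mask[ok] = np.abs(v[ok] - mu) > k * sd
    return mask


def residualize(
    y: np.ndarray | pd.Series, design: np.ndarray | pd.DataFrame
) -> np.ndarray:
    """Least-squares residuals of y on the design (collinear columns dropped).

    Residuals are orthogonal to every retained column. Rank-deficient
    designs are repaired by dropping dependent columns with a warning.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(design, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != y.shape[0]:
        raise ValueError("design rows must align with y")
    X = _drop_collinear(X)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def _drop_collinear(X: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Keep a maximal independent subset of columns via pivoted QR."""
    from scipy.linalg import qr

    _, r, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    rank = int((diag > tol * diag[0]).sum()) if diag.size else 0
    if rank < X.shape[1]:
        dropped = sorted(piv[rank:])
        logger.warning("dropping %d collinear design column(s): %s",
                       X.shape[1] - rank, dropped)
        X = X[:, sorted(piv[:rank])]
    return X


def inverse_normal_transform(
    residuals: np.ndarray | pd.Series, offset: float = 0.5
) -> np.ndarray:
    """Rank-based inverse normal transform.

    Maps value_i to Phi^-1((rank_i - offset) / (n - 2*offset + 1)) with
    average ranks for ties. The default offset 0.5 is the rankit
    ``(rank - 0.5)/n``; ``offset=0.375`` gives the Blom variant.
    """
    v = np.asarray(residuals, dtype=float)
    n = v.size
    if n < 2:
        raise ValueError("need at least 2 values")
    ranks = stats.rankdata(v, method="average")
    return stats.norm.ppf((ranks - offset) / (n - 2.0 * offset + 1.0))


def build_design(
    covariates: pd.DataFrame,
    *,
    include_sex: bool = True,
    extra: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Covariate design: intercept, age, age^2, sex, center/cohort dummies,
    age-by-sex interaction, plus any extra columns (e.g. BMI for WHR)."""
    age = covariates["age"].to_numpy(dtype=float)
    cols: dict[str, np.ndarray] = {
        "intercept": np.ones(len(covariates)),
        "age": age,
        "age2": age**2,
    }
    if include_sex and "sex" in covariates:
        sex = covariates["sex"].to_numpy(dtype=float)
        cols["sex"] = sex
        cols["age_x_sex"] = age * sex
    for cat in ("center", "cohort", "study"):
        if cat in covariates:
            levels = sorted(pd.unique(covariates[cat].astype(str)))
            for lev in levels[1:]:  # first level (alphabetical) = reference
                cols[f"{cat}_{lev}"] = (
                    covariates[cat].astype(str) == lev
                ).to_numpy(dtype=float)
    if extra:
        cols.update(extra)
    return pd.DataFrame(cols, index=covariates.index)


def prepare_traits(
    cohort: CohortTable, int_offset: float = 0.5
) -> dict[str, AnalysisTrait]:
    """Build the four analysis traits from a cohort table.

    CRP is log-transformed with a 3-SD outlier rule; BMI and the
    sex-stratified WHR traits (100 * waist / hip) use a 4-SD rule. WHR
    models additionally adjust for BMI. Exclusions are audited per trait.
    """
    phen = cohort.phenotypes
    cov = cohort.covariates
    idx = phen.index

    whr = 100.0 * phen["waist"].to_numpy() / phen["hip"].to_numpy()
    whr_missing = (
        phen["waist"].isna() | phen["hip"].isna()
    ).to_numpy()
    sex = cov["sex"].to_numpy(dtype=float)

    out: dict[str, AnalysisTrait] = {}

    raw = {
        "CRP": log_transform(phen["crp"]),
        "BMI": phen["bmi"].to_numpy(dtype=float),
    }
    strata = {
        "CRP": np.ones(len(idx), dtype=bool),
        "BMI": np.ones(len(idx), dtype=bool),
        "WHR_men": (sex == 0) & ~whr_missing,
        "WHR_women": (sex == 1) & ~whr_missing,
    }
    raw["WHR_men"] = whr
    raw["WHR_women"] = whr

    for trait in ANALYSIS_TRAITS:
        keep = strata[trait] & ~np.isnan(raw[trait])
        values = raw[trait][keep]
        sub_idx = idx[keep]
        mask = flag_outliers(values, OUTLIER_K[trait])
        audit = pd.DataFrame(
            {
                "individual": sub_idx[mask],
                "trait": trait,
                "reason": "outlier",
                "value": values[mask],
                "threshold_sd": OUTLIER_K[trait],
            }
        )
        values = values[~mask]
        sub_idx = sub_idx[~mask]

        sub_cov = cov.loc[sub_idx]
        stratified = trait.startswith("WHR")
        extra = None
        if stratified:
            extra = {"bmi": phen.loc[sub_idx, "bmi"].to_numpy(dtype=float)}
        design = build_design(sub_cov, include_sex=not stratified, extra=extra)
        resid = residualize(values, design)
        int_vals = inverse_normal_transform(resid, offset=int_offset)
        if stratified:
            sex_val = 0.0 if trait == "WHR_men" else 1.0
            n_missing = int(((sex == sex_val)
                             & (whr_missing | np.isnan(whr))).sum())
        else:
            n_missing = int(np.isnan(raw[trait]).sum())
        out[trait] = AnalysisTrait(
            trait_name=trait,
            int_residuals=pd.Series(int_vals, index=sub_idx, name=trait),
            n_excluded_outlier=int(mask.sum()),
            n_excluded_missing=n_missing,
            audit=audit,
        )
    return out
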