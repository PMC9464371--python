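"""Synthetic cohort and summary-statistic generator.

Produces individual-level data with the statistical structure the
adiposity--inflammation pleiotropy pipeline assumes: log-normal CRP,
approximately normal BMI/WHR, correlated trait residuals, family (cluster)
structure, and SNPs whose effects fall into four ground-truth classes:

``pleiotropic``
    direct effects on both log-CRP and an adiposity trait,
``mediated``
    a direct effect on one trait that propagates to the other through an
    explicit mediator path (coefficient ``mediation_coeff``),
``single_trait``
    a direct effect on exactly one trait,
``null``
    no effect.

Every generated column is reproducible bit-for-bit from the config seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

EFFECT_CLASSES = ("pleiotropic", "mediated", "single_trait", "null")
ADIPOSITY_TRAITS = ("BMI", "WHR")

#: Latent trait order used throughout: log-CRP, BMI, WHR (x100 scale).
TRAIT_ORDER = ("logcrp", "bmi", "whr")

# Fixed-effect plumbing for covariates; residualization removes these, they
# exist so the prep stage has something real to adjust for.
_INTERCEPTS = {"logcrp": 0.94, "bmi": 29.2, "whr": 95.5}
_AGE_SLOPES = {"logcrp": 0.004, "bmi": 0.02, "whr": 0.05}
_FEMALE_SHIFTS = {"logcrp": 0.30, "bmi": 0.0, "whr": -8.5}
_CENTER_SHIFTS = {"logcrp": 0.10, "bmi": 0.20, "whr": 0.30}

#: Default residual correlation of (log-CRP, BMI, WHR) errors; modest
#: positive dependence as seen between inflammation and adiposity measures.
DEFAULT_TRAIT_CORR = np.array(
    [
        [1.00, 0.30, 0.25],
        [0.30, 1.00, 0.45],
        [0.25, 0.45, 1.00],
    ]
)

CRP_FLOOR = 1e-4  # assay detection limit; keeps log defined


@dataclass(frozen=True)
class SnpSpec:
    """Ground-truth specification of one simulated SNP."""

    id: str
    maf: float
    effect_class: str = "null"
    beta_crp: float = 0.0
    beta_adip: float = 0.0
    target_adiposity: str = "BMI"
    chrom: str = "1"
    pos: int = 0
    info: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.maf <= 0.5:
            raise ValueError(
                f"SNP {self.id}: maf must be in (0, 0.5], got {self.maf}"
            )
        if self.effect_class not in EFFECT_CLASSES:
            raise ValueError(
                f"SNP {self.id}: unknown effect_class {self.effect_class!r}"
            )
        if self.target_adiposity not in ADIPOSITY_TRAITS:
            raise ValueError(
                f"SNP {self.id}: target_adiposity must be one of "
                f"{ADIPOSITY_TRAITS}"
            )
        if self.effect_class == "null" and (self.beta_crp or self.beta_adip):
            raise ValueError(f"SNP {self.id}: null class requires zero betas")
        if self.effect_class == "mediated":
            nonzero = (self.beta_crp != 0) + (self.beta_adip != 0)
            if nonzero != 1:
                raise ValueError(
                    f"SNP {self.id}: mediated class requires exactly one "
                    "nonzero direct beta"
                )
        if self.effect_class == "single_trait":
            nonzero = (self.beta_crp != 0) + (self.beta_adip != 0)
            if nonzero != 1:
                raise ValueError(
                    f"SNP {self.id}: single_trait class requires exactly one "
                    "nonzero beta"
                )
        if not 0.0 <= self.info <= 1.0:
            raise ValueError(f"SNP {self.id}: info must be in [0,1]")


@dataclass
class CohortConfig:
    """Parameters of one simulated cohort."""

    n_individuals: int
    snp_specs: list[SnpSpec]
    trait_error_corr: np.ndarray = field(
        default_factory=lambda: DEFAULT_TRAIT_CORR.copy()
    )
    trait_error_sd: tuple[float, float, float] = (1.0, 1.0, 1.0)
    mediation_coeff: float = 0.3
    cluster_size_dist: dict[int, float] = field(
        default_factory=lambda: {1: 0.7, 2: 0.2, 3: 0.1}
    )
    cluster_var_frac: float = 0.1
    n_pcs: int = 10
    n_centers: int = 2
    female_frac: float = 0.63
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 30:
            raise ValueError("n_individuals must be >= 30")
        R = np.asarray(self.trait_error_corr, dtype=float)
        if R.shape != (3, 3) or not np.allclose(R, R.T):
            raise ValueError("trait_error_corr must be a symmetric 3x3 matrix")
        if not np.allclose(np.diag(R), 1.0):
            raise ValueError("trait_error_corr must have unit diagonal")
        if np.linalg.eigvalsh(R).min() <= 0:
            raise ValueError("trait_error_corr must be positive-definite")
        self.trait_error_corr = R


@dataclass
class CohortTable:
    """Individual-level data for one cohort.

    ``dosage`` is n x m in [0, 2]; ``covariates`` carries age, sex
    (1 = female), center, PC1..PCk and cluster_id; ``phenotypes`` carries
    crp (> 0, original scale), bmi, waist and hip. ``snp_map`` records per-SNP
    metadata including the generating ground truth.
    """

    dosage: pd.DataFrame
    covariates: pd.DataFrame
    phenotypes: pd.DataFrame
    snp_map: pd.DataFrame

    @property
    def n(self) -> int:
        return len(self.dosage)


def simulate_genotypes(
    n: int, specs: list[SnpSpec], seed: int | np.random.Generator = 0
) -> pd.DataFrame:
    """Draw dosages as Binomial(2, maf) per individual under HWE."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _as_rng(seed)
    out = {s.id: rng.binomial(2, s.maf, size=n).astype(float) for s in specs}
    return pd.DataFrame(out)


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _allele_corr(rho: float, thresh: float, p: float) -> float:
    """Correlation of two threshold-Bernoulli alleles from latent corr rho."""
    cov = np.array([[1.0, rho], [rho, 1.0]])
    joint = stats.multivariate_normal(mean=[0.0, 0.0], cov=cov).cdf(
        [thresh, thresh]
    )
    return (joint - p * p) / (p * (1.0 - p))


def simulate_ld_pair(
    n: int,
    maf: float,
    target_r: float,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Two dosage columns whose Pearson correlation approaches ``target_r``.

    Uses a latent bivariate-Gaussian threshold construction per allele copy;
    the dosage correlation equals the allele-level correlation because the
    two copies are independent draws of the same latent pair.
    """
    if not 0.0 < maf <= 0.5:
        raise ValueError(f"maf must be in (0, 0.5], got {maf}")
    if abs(target_r) > 1.0:
        raise ValueError("|target_r| must be <= 1")
    rng = _as_rng(seed)
    thresh = stats.norm.ppf(maf)
    r_min = -maf / (1.0 - maf)  # countermonotone alleles, p <= 0.5
    if target_r < r_min:
        raise ValueError(
            f"target_r={target_r} unattainable at maf={maf}; "
            f"minimum achievable correlation is {r_min:.4f}"
        )
    if target_r == 1.0:
        a = rng.binomial(2, maf, size=n).astype(float)
        return a, a.copy()
    from scipy.optimize import brentq

    if target_r == 0.0:
        rho = 0.0
    else:
        rho = brentq(
            lambda r: _allele_corr(r, thresh, maf) - target_r,
            -0.9999,
            0.9999,
            xtol=1e-10,
        )
    chol = np.linalg.cholesky(np.array([[1.0, rho], [rho, 1.0]]))
    a = np.zeros(n)
    b = np.zeros(n)
    for _ in range(2):  # two allele copies
        z = rng.standard_normal((n, 2)) @ chol.T
        a += z[:, 0] < thresh
        b += z[:, 1] < thresh
    return a, b


def simulate_null_z(
    m: int, R: np.ndarray, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """i.i.d. rows from MVN(0, R): the null distribution of trait Z-scores."""
    R = np.asarray(R, dtype=float)
    try:
        chol = np.linalg.cholesky(R)
    except np.linalg.LinAlgError as exc:
        raise ValueError("R must be positive-definite") from exc
    rng = _as_rng(seed)
    return rng.standard_normal((m, R.shape[0])) @ chol.T


def _mediation_directions(specs: list[SnpSpec], coeff: float):
    """Which adiposity traits feed CRP and which receive from it.

    Returns (adip_mediators, crp_receivers): sets of adiposity trait names.
    A trait cannot simultaneously feed and receive (that would be a cycle).
    """
    feeds, receives = set(), set()
    if coeff != 0.0:
        for s in specs:
            if s.effect_class != "mediated":
                continue
            if s.beta_crp != 0.0:  # SNP -> CRP -> adiposity
                receives.add(s.target_adiposity)
            else:  # SNP -> adiposity -> CRP
                feeds.add(s.target_adiposity)
    cycle = feeds & receives
    if cycle:
        raise ValueError(
            f"mediation cycle: trait(s) {sorted(cycle)} both feed and "
            "receive CRP mediation"
        )
    return feeds, receives


def simulate_cohort(config: CohortConfig) -> CohortTable:
    """Generate a full cohort table from ``config``.

    log-CRP is a linear model in dosage, covariates and a cluster random
    intercept; CRP is its exponential (left-truncated at ``CRP_FLOOR``).
    BMI and WHR follow the same structure; mediated-class SNPs transmit
    their effect between traits through ``mediation_coeff`` applied to the
    standardized upstream trait. WHR is stored as waist and hip columns
    with WHR = 100 * waist / hip recoverable exactly.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_individuals
    specs = config.snp_specs

    dosage = simulate_genotypes(n, specs, rng)
    G = dosage.to_numpy()

    # covariates
    age = rng.uniform(18.0, 80.0, size=n)
    female = rng.binomial(1, config.female_frac, size=n).astype(float)
    center = rng.integers(0, config.n_centers, size=n)
    pcs = rng.standard_normal((n, config.n_pcs))
    cluster_id = _draw_clusters(n, config.cluster_size_dist, rng)

    sds = np.asarray(config.trait_error_sd, dtype=float)
    chol = np.linalg.cholesky(config.trait_error_corr)
    errors = rng.standard_normal((n, 3)) @ chol.T * sds

    cluster_sd = np.sqrt(config.cluster_var_frac) * sds
    n_clusters = int(cluster_id.max()) + 1
    cluster_eff = rng.standard_normal((n_clusters, 3)) * cluster_sd
    cluster_part = cluster_eff[cluster_id]

    def fixed_mean(trait: str) -> np.ndarray:
        return (
            _INTERCEPTS[trait]
            + _AGE_SLOPES[trait] * (age - 50.0)
            + _FEMALE_SHIFTS[trait] * female
            + _CENTER_SHIFTS[trait] * (center == 1)
        )

    beta_crp = np.array([s.beta_crp for s in specs])
    beta_bmi = np.array(
        [s.beta_adip if s.target_adiposity == "BMI" else 0.0 for s in specs]
    )
    beta_whr = np.array(
        [s.beta_adip if s.target_adiposity == "WHR" else 0.0 for s in specs]
    )

    feeds, receives = _mediation_directions(specs, config.mediation_coeff)

    trait_sd = dict(zip(TRAIT_ORDER, sds))
    adip_idx = {"BMI": "bmi", "WHR": "whr"}
    med = np.array([s.effect_class == "mediated" for s in specs])

    values = {
        "bmi": fixed_mean("bmi") + G @ beta_bmi + cluster_part[:, 1]
        + errors[:, 1],
        "whr": fixed_mean("whr") + G @ beta_whr + cluster_part[:, 2]
        + errors[:, 2],
    }

    # The mediated channel carries the mediated-class SNPs' genetic
    # contribution plus the mediator's own cluster and error variation
    # (standardized by the mediator's residual SD), so mediated SNPs show a
    # genuine indirect path while the other effect classes stay clean.
    logcrp = (
        fixed_mean("logcrp") + G @ beta_crp + cluster_part[:, 0] + errors[:, 0]
    )
    for t in feeds:  # adiposity trait -> CRP
        key = adip_idx[t]
        i = TRAIT_ORDER.index(key)
        b_med = np.where(
            med & (np.array([s.target_adiposity for s in specs]) == t),
            [s.beta_adip for s in specs], 0.0,
        )
        channel = (G @ b_med + cluster_part[:, i] + errors[:, i]) \
            / trait_sd[key]
        logcrp = logcrp + config.mediation_coeff * channel

    for t in receives:  # CRP -> adiposity trait
        key = adip_idx[t]
        b_med = np.where(
            med & (np.array([s.target_adiposity for s in specs]) == t),
            beta_crp, 0.0,
        )
        channel = (G @ b_med + cluster_part[:, 0] + errors[:, 0]) \
            / trait_sd["logcrp"]
        values[key] = values[key] + config.mediation_coeff * channel

    crp = np.maximum(np.exp(logcrp), CRP_FLOOR)
    hip = rng.normal(100.0, 6.0, size=n)
    waist = hip * values["whr"] / 100.0

    covariates = pd.DataFrame(
        {
            "age": age,
            "sex": female,
            "center": center,
            **{f"PC{i + 1}": pcs[:, i] for i in range(config.n_pcs)},
            "cluster_id": cluster_id,
        }
    )
    phenotypes = pd.DataFrame(
        {"crp": crp, "bmi": values["bmi"], "waist": waist, "hip": hip}
    )
    snp_map = pd.DataFrame(
        {
            "snp": [s.id for s in specs],
            "chrom": [s.chrom for s in specs],
            "pos": [s.pos for s in specs],
            "maf": [s.maf for s in specs],
            "info": [s.info for s in specs],
            "effect_class": [s.effect_class for s in specs],
            "beta_crp": beta_crp,
            "beta_adip": [s.beta_adip for s in specs],
            "target_adiposity": [s.target_adiposity for s in specs],
        }
    )
    return CohortTable(
        dosage=dosage,
        covariates=covariates,
        phenotypes=phenotypes,
        snp_map=snp_map,
    )


def _draw_clusters(
    n: int, size_dist: dict[int, float], rng: np.random.Generator
) -> np.ndarray:
    sizes = np.array(sorted(size_dist), dtype=int)
    probs = np.array([size_dist[s] for s in sizes], dtype=float)
    probs = probs / probs.sum()
    out = np.empty(n, dtype=int)
    filled = 0
    cid = 0
    while filled < n:
        k = int(rng.choice(sizes, p=probs))
        k = min(k, n - filled)
        out[filled : filled + k] = cid
        filled += k
        cid += 1
    return out


def write_cohort(table: CohortTable, out_dir: str | Path, config=None) -> None:
    """Write the cohort as TSVs plus a JSON sidecar with the config."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table.dosage.to_csv(out / "dosage.tsv", sep="\t", index=False)
    table.snp_map.to_csv(out / "snp_map.tsv", sep="\t", index=False)
    table.covariates.to_csv(out / "covariates.tsv", sep="\t", index=False)
    table.phenotypes.to_csv(out / "phenotypes.tsv", sep="\t", index=False)
    if config is not None:
        side = {
            "n_individuals": config.n_individuals,
            "seed": config.seed,
            "mediation_coeff": config.mediation_coeff,
            "trait_error_corr": np.asarray(config.trait_error_corr).tolist(),
            "trait_error_sd": list(config.trait_error_sd),
            "n_pcs": config.n_pcs,
        }
        (out / "config.json").write_text(json.dumps(side, indent=2))


def read_cohort(in_dir: str | Path) -> CohortTable:
    src = Path(in_dir)
    return CohortTable(
        dosage=pd.read_csv(src / "dosage.tsv", sep="\t"),
        snp_map=pd.read_csv(src / "snp_map.tsv", sep="\t"),
        covariates=pd.read_csv(src / "covariates.tsv", sep="\t"),
        phenotypes=pd.read_csv(src / "phenotypes.tsv", sep="\t"),
    )
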