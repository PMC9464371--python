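"""Univariate association testing, SNP QC, and fixed-effect meta-analysis.

``run_gwas`` fits, per SNP, a linear model of the INT-transformed trait on
dosage plus genetic PCs, with an independence working correlation and a
cluster-robust (sandwich) variance grouped by family id -- the GEE-with-
independent-errors estimator. ``ivw_meta`` pools per-study estimates with
fixed-effect inverse-variance weights. ``genomic_lambda`` is the usual
median-chi-square inflation diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: Canonical summary-statistic column order (TSV schema).
SUMSTAT_COLUMNS = [
    "SNP", "CHR", "POS", "EA", "OA", "EAF", "BETA", "SE", "Z", "P",
    "N", "INFO", "NEFF", "TRAIT", "STUDY",
]

CHI2_MEDIAN_1DF = stats.chi2.ppf(0.5, 1)  # 0.454936...


def effective_n(n, eaf, info):
    """Effective sample size 2*eaf*(1-eaf)*n*info for an imputed SNP."""
    return 2.0 * np.asarray(eaf) * (1.0 - np.asarray(eaf)) * np.asarray(n) \
        * np.asarray(info)


def qc_filter(
    records: pd.DataFrame,
    *,
    info_min: float = 0.4,
    neff_min: float = 30.0,
    maf_min: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop SNPs failing imputation, effective-N or MAF rules (strict <).

    Returns (retained, audit); the audit counts failures per reason (a SNP
    can fail several rules at once).
    """
    info = records["INFO"].to_numpy(dtype=float)
    neff = records["NEFF"].to_numpy(dtype=float)
    eaf = records["EAF"].to_numpy(dtype=float)
    maf = np.minimum(eaf, 1.0 - eaf)
    fail_info = info < info_min
    fail_neff = neff < neff_min
    fail_maf = maf < maf_min
    fail = fail_info | fail_neff | fail_maf
    audit = pd.DataFrame(
        {
            "reason": ["info", "neff", "maf", "any"],
            "n_failed": [
                int(fail_info.sum()),
                int(fail_neff.sum()),
                int(fail_maf.sum()),
                int(fail.sum()),
            ],
        }
    )
    return records.loc[~fail].reset_index(drop=True), audit


def run_gwas(
    trait: pd.Series,
    dosage: pd.DataFrame,
    pcs: pd.DataFrame | np.ndarray,
    cluster_id: pd.Series | np.ndarray,
    *,
    snp_map: pd.DataFrame | None = None,
    trait_name: str = "trait",
    study: str = "study1",
) -> pd.DataFrame:
    """Per-SNP linear association with cluster-robust sandwich SEs.

    ``trait`` is indexed by retained individuals; dosage/pcs/cluster rows are
    subset to that index. The per-SNP coefficient is obtained by
    Frisch-Waugh partialling of both outcome and dosage on the covariates
    (intercept + PCs), which reproduces the full-model OLS coordinate and
    its cluster sandwich exactly. Monomorphic SNPs are emitted with
    beta = 0 and EAF at the boundary so that QC removes them.
    """
    idx = trait.index
    y = trait.to_numpy(dtype=float)
    X = dosage.loc[idx].to_numpy(dtype=float)
    pcs = pd.DataFrame(pcs).loc[idx].to_numpy(dtype=float)
    clusters = pd.Series(np.asarray(cluster_id), index=dosage.index).loc[idx]
    n = y.size
    if pd.unique(clusters).size < 2:
        raise ValueError("need at least 2 clusters")

    C = np.column_stack([np.ones(n), pcs])
    # partial covariates out of y and every dosage column
    Q, _ = np.linalg.qr(C)
    y_t = y - Q @ (Q.T @ y)
    X_t = X - Q @ (Q.T @ X)

    xx = np.einsum("ij,ij->j", X_t, X_t)
    mono = xx <= 1e-12
    xx_safe = np.where(mono, 1.0, xx)
    beta = np.einsum("ij,i->j", X_t, y_t) / xx_safe
    resid = y_t[:, None] - X_t * beta[None, :]

    # cluster sums of the per-SNP score x_t * resid
    codes = pd.factorize(clusters.to_numpy())[0]
    scores = X_t * resid
    g = np.zeros((codes.max() + 1, X.shape[1]))
    np.add.at(g, codes, scores)
    meat = np.einsum("cj,cj->j", g, g)
    se = np.sqrt(meat) / xx_safe

    beta = np.where(mono, 0.0, beta)
    se = np.where(mono, np.nan, se)
    z = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    p = 2.0 * stats.norm.sf(np.abs(z))

    eaf = X.mean(axis=0) / 2.0
    snps = list(dosage.columns)
    if snp_map is not None:
        meta = snp_map.set_index("snp").loc[snps]
        chrom = meta["chrom"].to_numpy()
        pos = meta["pos"].to_numpy()
        info = meta["info"].to_numpy(dtype=float)
    else:
        chrom = np.repeat("1", len(snps))
        pos = np.arange(len(snps))
        info = np.ones(len(snps))

    out = pd.DataFrame(
        {
            "SNP": snps,
            "CHR": chrom,
            "POS": pos,
            "EA": "A",
            "OA": "G",
            "EAF": eaf,
            "BETA": beta,
            "SE": se,
            "Z": z,
            "P": p,
            "N": n,
            "INFO": info,
            "TRAIT": trait_name,
            "STUDY": study,
        }
    )
    out["NEFF"] = effective_n(out["N"], out["EAF"], out["INFO"])
    return out[SUMSTAT_COLUMNS]


@dataclass
class MetaRecord:
    """Fixed-effect inverse-variance pooled estimate for one SNP/trait."""

    beta_meta: float
    se_meta: float
    z_meta: float
    p_meta: float
    k_studies: int
    direction: str


def ivw_meta(per_study: list[tuple[float, float]]) -> MetaRecord:
    """Fixed-effect inverse-variance meta-analysis of (beta, se) pairs."""
    if not per_study:
        raise ValueError("ivw_meta requires at least one study")
    betas = np.array([b for b, _ in per_study], dtype=float)
    ses = np.array([s for _, s in per_study], dtype=float)
    if np.any(ses <= 0):
        raise ValueError("all standard errors must be > 0")
    import math

    w = 1.0 / ses**2
    # exactly-rounded sums make pooling order-invariant to the last bit
    beta = math.fsum(w * betas) / math.fsum(w)
    se = 1.0 / math.sqrt(math.fsum(w))
    z = beta / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    direction = "".join("+" if b > 0 else "-" if b < 0 else "0" for b in betas)
    return MetaRecord(beta, se, z, p, len(per_study), direction)


def _complement(allele: str) -> str:
    return {"A": "T", "T": "A", "C": "G", "G": "C"}.get(allele, allele)


def harmonize_to_reference(
    ref_ea: str, ref_oa: str, row: pd.Series, eaf_tol: float = 0.2
) -> pd.Series | None:
    """Align one summary record to reference effect/other alleles.

    Swapped alleles flip the sign; strand flips are resolved by
    complementing; ambiguous A/T and C/G SNPs are kept only when the EAFs
    agree within ``eaf_tol`` (orientation by EAF proximity), else dropped.
    Returns the aligned record or None when the SNP must be dropped.
    """
    ea, oa = row["EA"], row["OA"]
    ambiguous = {ea, oa} in ({"A", "T"}, {"C", "G"})
    if ambiguous:
        if {ea, oa} != {ref_ea, ref_oa}:
            raise ValueError(
                f"incompatible allele sets ({ea}/{oa} vs {ref_ea}/{ref_oa})"
            )
        # strand cannot be resolved from the alleles; orient by EAF
        # proximity when a reference EAF is supplied, else by labels
        keep = row.copy()
        keep["EA"], keep["OA"] = ref_ea, ref_oa
        flipped = row.copy()
        flipped["EA"], flipped["OA"] = ref_ea, ref_oa
        flipped["BETA"] = -row["BETA"]
        flipped["Z"] = -row["Z"]
        flipped["EAF"] = 1.0 - row["EAF"]
        ref_eaf = row.get("REF_EAF", None)
        if ref_eaf is None or pd.isna(ref_eaf):
            return keep if ea == ref_ea else flipped
        d_keep = abs(keep["EAF"] - ref_eaf)
        d_flip = abs(flipped["EAF"] - ref_eaf)
        if min(d_keep, d_flip) > eaf_tol:
            return None
        return keep if d_keep <= d_flip else flipped
    if (ea, oa) == (ref_ea, ref_oa) or (
        _complement(ea), _complement(oa)) == (ref_ea, ref_oa):
        return row.copy()
    if (oa, ea) == (ref_ea, ref_oa) or (
        _complement(oa), _complement(ea)) == (ref_ea, ref_oa):
        out = row.copy()
        out["BETA"] = -row["BETA"]
        out["Z"] = -row["Z"]
        out["EAF"] = 1.0 - row["EAF"]
        out["EA"], out["OA"] = ref_ea, ref_oa
        return out
    raise ValueError(
        f"incompatible allele sets ({ea}/{oa} vs {ref_ea}/{ref_oa})"
    )


def meta_analyze(studies: list[pd.DataFrame]) -> pd.DataFrame:
    """IVW meta-analysis of per-study summary tables for one trait.

    Records are joined on SNP id; alleles are aligned to the first study
    carrying each SNP before pooling.
    """
    if not studies:
        raise ValueError("no studies supplied")
    pooled = []
    frames = pd.concat(studies, ignore_index=True)
    for snp, grp in frames.groupby("SNP", sort=False):
        ref = grp.iloc[0]
        rows = [ref]
        for _, row in grp.iloc[1:].iterrows():
            aligned = harmonize_to_reference(ref["EA"], ref["OA"], row)
            if aligned is not None:
                rows.append(aligned)
        rec = ivw_meta([(r["BETA"], r["SE"]) for r in rows])
        pooled.append(
            {
                "SNP": snp,
                "CHR": ref["CHR"],
                "POS": ref["POS"],
                "EA": ref["EA"],
                "OA": ref["OA"],
                "EAF": float(np.mean([r["EAF"] for r in rows])),
                "BETA": rec.beta_meta,
                "SE": rec.se_meta,
                "Z": rec.z_meta,
                "P": rec.p_meta,
                "N": int(sum(r["N"] for r in rows)),
                "INFO": float(np.mean([r["INFO"] for r in rows])),
                "NEFF": float(sum(r["NEFF"] for r in rows)),
                "TRAIT": ref["TRAIT"],
                "STUDY": "meta",
                "K_STUDIES": rec.k_studies,
                "DIRECTION": rec.direction,
            }
        )
    return pd.DataFrame(pooled)


def genomic_lambda(pvalues: np.ndarray | pd.Series) -> float:
    """Genomic inflation factor: median observed 1-df chi2 over 0.4549."""
    p = np.asarray(pvalues, dtype=float)
    p = p[~np.isnan(p)]
    if p.size < 100:
        raise ValueError("need at least 100 p-values")
    chi2 = stats.norm.isf(p / 2.0) ** 2
    return float(np.median(chi2) / CHI2_MEDIAN_1DF)
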