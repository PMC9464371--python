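"""Locus definition and decision rules.

Greedy LD clumping groups multi-trait results into independent loci
(lead variants pairwise r^2 below a threshold, 0.1 by default), and pure
decision functions encode the candidate and replication criteria: a
conservative multi-trait significance threshold, nominal univariate support
for inflammation plus at least one adiposity trait, presence in the pooled
genotyping panel, and direction-of-effect consistency between discovery and
replication.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ADIPOSITY = ("BMI", "WHR_men", "WHR_women")

GENOMEWIDE_ALPHA = 5e-8


def multitrait_threshold(n_traits: int = 4,
                         genomewide: float = GENOMEWIDE_ALPHA) -> float:
    """Conservative multi-trait threshold: genome-wide alpha / #traits."""
    if n_traits < 1:
        raise ValueError("n_traits must be >= 1")
    return genomewide / n_traits


@dataclass
class ClumpedLocus:
    lead_snp: str
    members: list[str]
    lead_p_aspu: float
    chrom: str
    pos_range: tuple[int, int]


@dataclass
class Decision:
    """Outcome of a candidate or replication rule for one SNP."""

    snp_id: str
    passed: bool
    reasons: dict[str, bool] = field(default_factory=dict)


def ld_r2(dos_a: np.ndarray, dos_b: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage columns."""
    a = np.asarray(dos_a, dtype=float)
    b = np.asarray(dos_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("dosage columns must have equal length")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("monomorphic dosage column")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def clump(
    results: pd.DataFrame,
    dosages: pd.DataFrame,
    *,
    r2_threshold: float = 0.1,
    window_kb: float = 1000.0,
    snp_map: pd.DataFrame | None = None,
) -> list[ClumpedLocus]:
    """Greedy clumping of aSPU results into independent loci.

    Repeatedly takes the best remaining SNP (smallest P_ASPU) as a lead and
    absorbs all unassigned SNPs on the same chromosome within the window
    whose r^2 with the lead is at or above the threshold.
    """
    req = {"SNP", "P_ASPU"}
    if not req <= set(results.columns):
        raise ValueError(f"results must have columns {sorted(req)}")
    df = results.copy()
    if "CHR" not in df.columns or "POS" not in df.columns:
        if snp_map is None:
            raise ValueError("need CHR/POS columns or a snp_map")
        pos = snp_map.set_index("snp")
        df["CHR"] = pos.loc[df["SNP"], "chrom"].to_numpy()
        df["POS"] = pos.loc[df["SNP"], "pos"].to_numpy()
    df = df.sort_values(["P_ASPU", "SNP"], kind="mergesort").reset_index(
        drop=True
    )
    unassigned = dict(zip(df["SNP"], df.index))
    loci: list[ClumpedLocus] = []
    window = window_kb * 1000.0
    for _, row in df.iterrows():
        snp = row["SNP"]
        if snp not in unassigned:
            continue
        del unassigned[snp]
        members = [snp]
        lead_dos = dosages[snp].to_numpy(dtype=float)
        positions = [int(row["POS"])]
        for other in list(unassigned):
            orow = df.iloc[unassigned[other]]
            if orow["CHR"] != row["CHR"]:
                continue
            if abs(orow["POS"] - row["POS"]) > window:
                continue
            other_dos = dosages[other].to_numpy(dtype=float)
            if other_dos.std() == 0 or lead_dos.std() == 0:
                continue
            if ld_r2(lead_dos, other_dos) >= r2_threshold:
                members.append(other)
                positions.append(int(orow["POS"]))
                del unassigned[other]
        loci.append(
            ClumpedLocus(
                lead_snp=snp,
                members=members,
                lead_p_aspu=float(row["P_ASPU"]),
                chrom=str(row["CHR"]),
                pos_range=(min(positions), max(positions)),
            )
        )
    return loci


def harmonize_alleles(
    disc: pd.Series, rep: pd.Series, eaf_tol: float = 0.2
) -> tuple[pd.Series, pd.Series | None]:
    """Align a replication record to the discovery allele orientation.

    Swapped alleles flip the replication beta sign; strand flips resolve by
    complement; ambiguous A/T and C/G SNPs orient by EAF proximity and are
    dropped (None) when the frequencies disagree by more than ``eaf_tol``.
    """
    from .assoc import harmonize_to_reference

    rep = rep.copy()
    rep["REF_EAF"] = disc["EAF"]
    aligned = harmonize_to_reference(disc["EA"], disc["OA"], rep,
                                     eaf_tol=eaf_tol)
    if aligned is not None:
        aligned = aligned.drop(labels=["REF_EAF"])
    return disc, aligned


def candidate_filter(
    snp_id: str,
    p_aspu: float,
    univariate_p: dict[str, float],
    present_in_pool: bool,
    *,
    aspu_threshold: float = 1.25e-8,
    nominal: float = 0.05,
) -> Decision:
    """Discovery-stage candidacy decision.

    Pass requires multi-trait p below the conservative threshold, nominal
    univariate inflammation (CRP) support AND nominal support for at least
    one adiposity trait, and presence in the pooled genotyping results.
    All comparisons are strict.
    """
    if "CRP" not in univariate_p:
        raise ValueError("univariate_p must include CRP")
    adip_ps = [univariate_p[t] for t in ADIPOSITY if t in univariate_p]
    reasons = {
        "aspu_significant": bool(p_aspu < aspu_threshold),
        "crp_nominal": bool(univariate_p["CRP"] < nominal),
        "adiposity_nominal": bool(adip_ps and min(adip_ps) < nominal),
        "present_in_pool": bool(present_in_pool),
    }
    return Decision(snp_id, all(reasons.values()), reasons)


def replication_filter(
    snp_id: str,
    rep_p_aspu: float,
    rep_univariate_p: dict[str, float],
    sign_consistent: dict[str, bool],
    *,
    nominal: float = 0.05,
) -> Decision:
    """Replication decision for one discovery SNP.

    Pass requires nominal replication multi-trait p, nominal CRP and at
    least one nominal adiposity trait, and discovery/replication effect
    signs agreeing on every trait that contributed to the nominal-support
    criterion (CRP plus each nominal adiposity trait).
    """
    if "CRP" not in rep_univariate_p:
        raise ValueError("rep_univariate_p must include CRP")
    nominal_adip = [
        t for t in ADIPOSITY
        if t in rep_univariate_p and rep_univariate_p[t] < nominal
    ]
    counted = (["CRP"] if rep_univariate_p["CRP"] < nominal else []) \
        + nominal_adip
    reasons = {
        "aspu_nominal": bool(rep_p_aspu < nominal),
        "crp_nominal": bool(rep_univariate_p["CRP"] < nominal),
        "adiposity_nominal": bool(nominal_adip),
        "signs_consistent": all(
            bool(sign_consistent.get(t, False)) for t in counted
        ) if counted else False,
    }
    return Decision(snp_id, all(reasons.values()), reasons)
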