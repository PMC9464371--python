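"""Tab-delimited summary-statistic and dosage I/O.

The summary-statistic schema is a single header row with columns
SNP CHR POS EA OA EAF BETA SE Z P N INFO NEFF TRAIT STUDY, '.' coding
missing values. The writer is column-order stable and the write->read
round trip is the identity on all fields.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .assoc import SUMSTAT_COLUMNS

_NUMERIC = ["POS", "EAF", "BETA", "SE", "Z", "P", "N", "INFO", "NEFF"]


def write_sumstats(records: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in SUMSTAT_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"records lack mandatory column(s): {missing}")
    out = records[SUMSTAT_COLUMNS].copy()
    out.to_csv(path, sep="\t", index=False, na_rep=".")


def read_sumstats(path: str | Path) -> pd.DataFrame:
    """Read and validate a summary-statistic TSV.

    Malformed rows (non-numeric fields, non-positive SE) are reported with
    their 1-based line numbers.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=["."],
                     keep_default_na=False)
    missing = [c for c in SUMSTAT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing mandatory column(s) {missing}; expected "
            f"schema {SUMSTAT_COLUMNS}"
        )
    for col in _NUMERIC:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header is line 1
            raise ValueError(
                f"{path}: line {line}: non-numeric value "
                f"{df[col][bad.idxmax()]!r} in column {col}"
            )
        df[col] = converted
    bad_se = df["SE"].notna() & (df["SE"] <= 0)
    if bad_se.any():
        line = int(bad_se.idxmax()) + 2
        raise ValueError(f"{path}: line {line}: SE must be > 0")
    return df[SUMSTAT_COLUMNS]


def read_dosage_tsv(path: str | Path) -> pd.DataFrame:
    """Plain dosage matrix: one column per SNP, one row per individual."""
    df = pd.read_csv(path, sep="\t")
    arr = df.to_numpy(dtype=float)
    if np.nanmin(arr) < 0 or np.nanmax(arr) > 2:
        raise ValueError(f"{path}: dosage entries must lie in [0, 2]")
    return df


def read_vcf_dosage(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Dosages from a VCF with a DS FORMAT field.

    Returns (dosage matrix with sample rows, snp map with chrom/pos).
    Requires cyvcf2.
    """
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading VCF dosages requires cyvcf2") from exc
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols: dict[str, np.ndarray] = {}
    meta = []
    for var in vcf:
        ds = var.format("DS")
        if ds is None:
            raise ValueError(
                f"{path}: variant {var.ID or var.POS} lacks a DS field"
            )
        snp_id = var.ID or f"{var.CHROM}:{var.POS}"
        cols[snp_id] = np.asarray(ds, dtype=float).ravel()
        meta.append(
            {
                "snp": snp_id,
                "chrom": var.CHROM,
                "pos": var.POS,
                "ea": var.ALT[0] if var.ALT else ".",
                "oa": var.REF,
            }
        )
    dosage = pd.DataFrame(cols, index=samples)
    return dosage, pd.DataFrame(meta)
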