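"""End-to-end pipeline: simulate -> prep -> GWAS -> meta -> aSPU ->
clump/select -> replicate -> mediate.

Each stage reads its inputs from and writes its outputs to ``out_dir`` as
TSV (plus a JSON manifest with config, seeds and output checksums), so
stages can be re-run individually and a completed run is reproducible
byte-for-byte from its seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .aspu import (DEFAULT_GAMMAS, NullCorr, aspu_scan, estimate_null_corr)
from .assoc import genomic_lambda, meta_analyze, qc_filter, run_gwas
from .io import read_sumstats, write_sumstats
from .loci import (candidate_filter, clump, multitrait_threshold,
                   replication_filter)
from .mediation import (choose_direction, fit_models, mediate,
                        mediation_table, sensitivity)
from .phenotype_prep import ANALYSIS_TRAITS, prepare_traits
from .synthetic_data import (CohortConfig, CohortTable, SnpSpec,
                             read_cohort, simulate_cohort, write_cohort)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "prep", "gwas", "meta", "aspu", "select",
          "replicate", "mediate")


@dataclass
class PipelineConfig:
    """Scale, thresholds and seeds for one pipeline run."""

    out_dir: str = "pleioscan_run"
    seed: int = 0
    # synthetic-cohort scale (demo defaults)
    n_discovery: int = 2000
    n_replication: int = 1000
    m_snps: int = 5000
    n_studies: int = 2
    n_pleiotropic: int = 4
    n_single_trait: int = 3
    n_mediated: int = 2
    effect_size: float = 0.35
    mediation_coeff: float = 0.3
    # QC / decision thresholds
    n_traits: int = 4
    nominal: float = 0.05
    r2_clump: float = 0.1
    clump_window_kb: float = 1000.0
    maf_min: float = 0.05
    info_min: float = 0.4
    neff_min: float = 30.0
    # aSPU
    gammas: tuple[int, ...] = DEFAULT_GAMMAS
    schedule: tuple[int, ...] = (10_000, 1_000_000, 100_000_000)
    # replication decisions only need nominal-p resolution
    replication_schedule: tuple[int, ...] = (10_000, 1_000_000)
    escalation_c: float = 100.0
    null_corr_thin: int = 1
    null_corr_min_snps: int = 1000
    # mediation
    mediation_sims: int = 1000
    aspu_threshold: float | None = None  # default: 5e-8 / n_traits

    def __post_init__(self) -> None:
        if self.aspu_threshold is None:
            self.aspu_threshold = multitrait_threshold(self.n_traits)
        self.schedule = tuple(int(b) for b in self.schedule)
        self.replication_schedule = tuple(
            int(b) for b in self.replication_schedule
        )
        self.gammas = tuple(int(g) for g in self.gammas)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)


def default_snp_specs(cfg: PipelineConfig) -> list[SnpSpec]:
    """Planted SNP roster: pleiotropic, single-trait, mediated, null.

    SNPs are spread 2 Mb apart over 22 chromosomes so the synthetic panel
    is effectively LD-free; LD behaviour is exercised separately.
    """
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed,
                                                       spawn_key=(99,)))
    m = cfg.m_snps
    mafs = rng.uniform(0.1, 0.5, size=m)
    e = cfg.effect_size
    specs: list[SnpSpec] = []
    classes: list[tuple[str, dict]] = []
    for i in range(cfg.n_pleiotropic):
        classes.append(("pleiotropic",
                        {"beta_crp": e, "beta_adip": e,
                         "target_adiposity": "BMI" if i % 2 == 0 else "WHR"}))
    single_cycle = [{"beta_crp": e}, {"beta_adip": e,
                                      "target_adiposity": "BMI"},
                    {"beta_adip": e, "target_adiposity": "WHR"}]
    for i in range(cfg.n_single_trait):
        classes.append(("single_trait", single_cycle[i % 3]))
    med_cycle = [{"beta_crp": e, "target_adiposity": "BMI"},
                 {"beta_adip": e, "target_adiposity": "WHR"}]
    for i in range(cfg.n_mediated):
        classes.append(("mediated", med_cycle[i % 2]))
    while len(classes) < m:
        classes.append(("null", {}))
    for i, (klass, kw) in enumerate(classes):
        specs.append(
            SnpSpec(
                id=f"snp{i:05d}",
                maf=float(mafs[i]),
                effect_class=klass,
                chrom=str(i % 22 + 1),
                pos=2_000_000 * (i // 22 + 1),
                **kw,
            )
        )
    return specs


@dataclass
class RunManifest:
    config: dict
    seed: int
    versions: dict[str, str]
    config_hash: str = ""
    stages: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.config_hash:
            payload = json.dumps(self.config, sort_keys=True).encode()
            self.config_hash = hashlib.sha256(payload).hexdigest()

    def record(self, stage: str, outputs: list[Path]) -> None:
        self.stages[stage] = {
            "outputs": {
                str(p.name): _sha256(p) for p in outputs if p.exists()
            },
            "completed_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class Pipeline:
    """Stage runner bound to one output directory."""

    def __init__(self, config: PipelineConfig):
        self.cfg = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest = RunManifest(
            config={k: (list(v) if isinstance(v, tuple) else v)
                    for k, v in dataclasses.asdict(config).items()},
            seed=config.seed,
            versions={
                "pleioscan": __version__,
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
        )

    # -- helpers --------------------------------------------------------

    def _require(self, *paths: Path) -> None:
        missing = [str(p) for p in paths if not p.exists()]
        if missing:
            raise FileNotFoundError(
                "missing stage input(s): " + ", ".join(missing)
                + "; run the upstream stage first"
            )

    def _cohort_dir(self, which: str) -> Path:
        return self.out / f"cohort_{which}"

    # -- stages ---------------------------------------------------------

    def simulate(self) -> None:
        cfg = self.cfg
        specs = default_snp_specs(cfg)
        for which, n, seed in (
            ("discovery", cfg.n_discovery, cfg.seed),
            ("replication", cfg.n_replication, cfg.seed + 1),
        ):
            cc = CohortConfig(
                n_individuals=n,
                snp_specs=specs,
                mediation_coeff=cfg.mediation_coeff,
                seed=seed,
            )
            table = simulate_cohort(cc)
            write_cohort(table, self._cohort_dir(which), cc)
        self.manifest.record(
            "simulate",
            [self._cohort_dir(w) / "dosage.tsv"
             for w in ("discovery", "replication")],
        )

    def _split_studies(self, cohort: CohortTable) -> list[pd.Index]:
        """Partition individuals into studies along cluster boundaries."""
        k = self.cfg.n_studies
        cid = cohort.covariates["cluster_id"].to_numpy()
        assign = cid % k
        return [cohort.covariates.index[assign == s] for s in range(k)]

    def prep_and_gwas(self, which: str) -> None:
        cfg = self.cfg
        self._require(self._cohort_dir(which) / "dosage.tsv")
        cohort = read_cohort(self._cohort_dir(which))
        splits = (
            self._split_studies(cohort) if which == "discovery"
            else [cohort.covariates.index]
        )
        pc_cols = [c for c in cohort.covariates.columns
                   if c.startswith("PC")]
        outputs = []
        audits = []
        exclusions = []
        for s, rows in enumerate(splits):
            sub = CohortTable(
                dosage=cohort.dosage.loc[rows],
                covariates=cohort.covariates.loc[rows],
                phenotypes=cohort.phenotypes.loc[rows],
                snp_map=cohort.snp_map,
            )
            traits = prepare_traits(sub)
            for trait in traits.values():
                if len(trait.audit):
                    exclusions.append(
                        trait.audit.assign(study=f"{which}_s{s}")
                    )
            for name, trait in traits.items():
                stats_df = run_gwas(
                    trait.int_residuals,
                    sub.dosage,
                    sub.covariates[pc_cols],
                    sub.covariates["cluster_id"],
                    snp_map=cohort.snp_map,
                    trait_name=name,
                    study=f"{which}_s{s}",
                )
                stats_df, audit = qc_filter(
                    stats_df, info_min=cfg.info_min,
                    neff_min=cfg.neff_min, maf_min=cfg.maf_min,
                )
                audit["trait"] = name
                audit["study"] = f"{which}_s{s}"
                audits.append(audit)
                path = self.out / f"gwas_{which}_s{s}_{name}.tsv"
                write_sumstats(stats_df, path)
                outputs.append(path)
        pd.concat(audits, ignore_index=True).to_csv(
            self.out / f"qc_audit_{which}.tsv", sep="\t", index=False
        )
        excl = (pd.concat(exclusions, ignore_index=True) if exclusions
                else pd.DataFrame(columns=["individual", "trait", "reason",
                                           "value", "threshold_sd",
                                           "study"]))
        excl.to_csv(self.out / f"exclusions_{which}.tsv", sep="\t",
                    index=False)
        self.manifest.record(f"gwas_{which}", outputs)

    def meta(self, which: str) -> None:
        cfg = self.cfg
        outputs = []
        for name in ANALYSIS_TRAITS:
            paths = sorted(self.out.glob(f"gwas_{which}_s*_{name}.tsv"))
            self._require(*(paths or [self.out / f"gwas_{which}_s0_{name}.tsv"]))
            studies = [read_sumstats(p) for p in paths]
            meta_df = meta_analyze(studies)
            path = self.out / f"meta_{which}_{name}.tsv"
            meta_df.to_csv(path, sep="\t", index=False, na_rep=".")
            outputs.append(path)
        lam = {}
        for name in ANALYSIS_TRAITS:
            pvals = pd.read_csv(self.out / f"meta_{which}_{name}.tsv",
                                sep="\t")["P"]
            # inflation estimate is meaningless on a handful of SNPs
            lam[name] = (genomic_lambda(pvals) if pvals.notna().sum() >= 100
                         else None)
        (self.out / f"lambda_{which}.json").write_text(json.dumps(lam))
        self.manifest.record(f"meta_{which}", outputs)

    def _z_matrix(self, which: str) -> pd.DataFrame:
        frames = {}
        for name in ANALYSIS_TRAITS:
            path = self.out / f"meta_{which}_{name}.tsv"
            self._require(path)
            df = pd.read_csv(path, sep="\t")
            frames[name] = df.set_index("SNP")[["CHR", "POS", "Z"]]
        base = pd.concat(
            [f[["CHR", "POS"]] for f in frames.values()]
        )
        base = base[~base.index.duplicated()]
        z = pd.DataFrame(index=base.index)
        z["CHR"] = base["CHR"]
        z["POS"] = base["POS"]
        for name, f in frames.items():
            z[name] = f["Z"].reindex(z.index)
        return z.reset_index().rename(columns={"index": "SNP"})

    def aspu(self, which: str) -> None:
        cfg = self.cfg
        z = self._z_matrix(which)
        R = estimate_null_corr(
            z, list(ANALYSIS_TRAITS),
            thin=cfg.null_corr_thin, min_snps=cfg.null_corr_min_snps,
        )
        np.savetxt(self.out / f"null_corr_{which}.tsv", R.R, delimiter="\t")
        schedule = (cfg.schedule if which == "discovery"
                    else cfg.replication_schedule)
        res = aspu_scan(
            z, R, gammas=cfg.gammas, schedule=schedule,
            escalation_c=cfg.escalation_c,
            seed=cfg.seed + (10 if which == "discovery" else 11),
        )
        res = res.merge(z[["SNP", "CHR", "POS"]], on="SNP")
        path = self.out / f"aspu_{which}.tsv"
        res.to_csv(path, sep="\t", index=False)
        self.manifest.record(f"aspu_{which}", [path])

    def select(self) -> None:
        cfg = self.cfg
        aspu_path = self.out / "aspu_discovery.tsv"
        self._require(aspu_path, self._cohort_dir("discovery") / "dosage.tsv")
        res = pd.read_csv(aspu_path, sep="\t")
        cohort = read_cohort(self._cohort_dir("discovery"))
        loci_list = clump(
            res, cohort.dosage, r2_threshold=cfg.r2_clump,
            window_kb=cfg.clump_window_kb,
        )
        uni = {
            name: pd.read_csv(self.out / f"meta_discovery_{name}.tsv",
                              sep="\t").set_index("SNP")["P"]
            for name in ANALYSIS_TRAITS
        }
        pool = set(uni["CRP"].index)
        rows = []
        for locus in loci_list:
            pvals = {t: float(uni[t].get(locus.lead_snp, np.nan))
                     for t in ANALYSIS_TRAITS}
            pvals = {t: p for t, p in pvals.items() if not np.isnan(p)}
            if "CRP" not in pvals:
                continue
            dec = candidate_filter(
                locus.lead_snp, locus.lead_p_aspu, pvals,
                locus.lead_snp in pool,
                aspu_threshold=cfg.aspu_threshold, nominal=cfg.nominal,
            )
            rows.append(
                {
                    "LEAD": locus.lead_snp,
                    "CHR": locus.chrom,
                    "MEMBERS": ",".join(locus.members),
                    "P_ASPU": locus.lead_p_aspu,
                    "DECISION": dec.passed,
                    "REASONS": ";".join(
                        f"{k}={int(v)}" for k, v in dec.reasons.items()
                    ),
                }
            )
        path = self.out / "loci_discovery.tsv"
        pd.DataFrame(
            rows, columns=["LEAD", "CHR", "MEMBERS", "P_ASPU", "DECISION",
                           "REASONS"],
        ).to_csv(path, sep="\t", index=False)
        self.manifest.record("select", [path])

    def replicate(self) -> None:
        cfg = self.cfg
        loci_path = self.out / "loci_discovery.tsv"
        rep_aspu = self.out / "aspu_replication.tsv"
        self._require(loci_path, rep_aspu)
        loci_df = pd.read_csv(loci_path, sep="\t")
        candidates = loci_df.loc[loci_df["DECISION"], "LEAD"]
        rep = pd.read_csv(rep_aspu, sep="\t").set_index("SNP")
        disc_uni = {
            t: pd.read_csv(self.out / f"meta_discovery_{t}.tsv",
                           sep="\t").set_index("SNP")
            for t in ANALYSIS_TRAITS
        }
        rep_uni = {
            t: pd.read_csv(self.out / f"meta_replication_{t}.tsv",
                           sep="\t").set_index("SNP")
            for t in ANALYSIS_TRAITS
        }
        rows = []
        for snp in candidates:
            if snp not in rep.index:
                continue
            pvals = {}
            signs = {}
            for t in ANALYSIS_TRAITS:
                if snp in rep_uni[t].index and snp in disc_uni[t].index:
                    pvals[t] = float(rep_uni[t].loc[snp, "P"])
                    signs[t] = bool(
                        np.sign(rep_uni[t].loc[snp, "BETA"])
                        == np.sign(disc_uni[t].loc[snp, "BETA"])
                    )
            dec = replication_filter(
                snp, float(rep.loc[snp, "P_ASPU"]), pvals, signs,
                nominal=cfg.nominal,
            )
            rows.append(
                {
                    "SNP": snp,
                    "REP_P_ASPU": float(rep.loc[snp, "P_ASPU"]),
                    "DECISION": dec.passed,
                    "REASONS": ";".join(
                        f"{k}={int(v)}" for k, v in dec.reasons.items()
                    ),
                }
            )
        path = self.out / "replication.tsv"
        pd.DataFrame(
            rows, columns=["SNP", "REP_P_ASPU", "DECISION", "REASONS"],
        ).to_csv(path, sep="\t", index=False)
        self.manifest.record("replicate", [path])

    def mediate(self) -> None:
        cfg = self.cfg
        rep_path = self.out / "replication.tsv"
        self._require(rep_path, self._cohort_dir("discovery") / "dosage.tsv")
        rep = pd.read_csv(rep_path, sep="\t")
        passed = rep.loc[rep["DECISION"], "SNP"]
        cohort = read_cohort(self._cohort_dir("discovery"))
        snp_map = cohort.snp_map.set_index("snp")
        pc_cols = [c for c in cohort.covariates.columns
                   if c.startswith("PC")]
        covs = cohort.covariates[["age", "sex"] + pc_cols]
        logcrp = np.log(cohort.phenotypes["crp"].to_numpy())
        whr = 100.0 * cohort.phenotypes["waist"] / cohort.phenotypes["hip"]
        trait_values = {
            "CRP": logcrp,
            "BMI": cohort.phenotypes["bmi"].to_numpy(),
            "WHR": whr.to_numpy(),
        }
        results = {}
        curves = []
        for snp in passed:
            meta_row = snp_map.loc[snp]
            prior = ("inflammation"
                     if abs(meta_row["beta_crp"]) >= abs(meta_row["beta_adip"])
                     else "adiposity")
            mediator, outcome = choose_direction(
                prior, adiposity_trait=str(meta_row["target_adiposity"])
            )
            med_fit, out_fit = fit_models(
                cohort.dosage[snp], trait_values[mediator],
                trait_values[outcome], covs,
            )
            res = mediate(
                med_fit, out_fit, n_sims=cfg.mediation_sims,
                seed=cfg.seed + 20, mediator_name=mediator,
                outcome_name=outcome,
            )
            results[snp] = res
            grid = np.linspace(-0.9, 0.9, 37)
            curve = sensitivity(med_fit, out_fit, res, grid)
            curves.append(
                pd.DataFrame(
                    {"SNP": snp, "RHO": curve.rho_grid,
                     "ACME": curve.acme_at_rho}
                )
            )
        path = self.out / "mediation.tsv"
        mediation_table(results).to_csv(path, sep="\t", index=False)
        if curves:
            pd.concat(curves, ignore_index=True).to_csv(
                self.out / "mediation_sensitivity.tsv", sep="\t", index=False
            )
        self.manifest.record("mediate", [path])

    # -- driver ---------------------------------------------------------

    def run(self, stages: tuple[str, ...] = STAGES) -> RunManifest:
        for stage in stages:
            if stage not in STAGES:
                raise ValueError(f"unknown stage {stage!r}")
        try:
            if "simulate" in stages:
                self.simulate()
            for which in ("discovery", "replication"):
                if "gwas" in stages or "prep" in stages:
                    self.prep_and_gwas(which)
                if "meta" in stages:
                    self.meta(which)
                if "aspu" in stages:
                    self.aspu(which)
            if "select" in stages:
                self.select()
            if "replicate" in stages:
                self.replicate()
            if "mediate" in stages:
                self.mediate()
        finally:
            self.manifest.write(self.out / "manifest.json")
        return self.manifest


def run_pipeline(config: PipelineConfig,
                 stages: tuple[str, ...] = STAGES) -> RunManifest:
    return Pipeline(config).run(stages)
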