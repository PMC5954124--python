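"""End-to-end orchestration: simulate (or load) -> QC -> cluster -> score ->
associate -> mediate, with a run report mirroring the study's summary tables
(demographics block, association block, mediation block)."""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as eio
from .assoc import (
    AssociationResult,
    GroupComparison,
    association_frame,
    ols_fit,
    pearson_chi2,
    prs_association,
    two_sample_t,
)
from .cluster import assignments_frame, fit_kmeans, label_globally_impaired, select_k_vfold
from .containers import ERP_MEASURES, ConfigurationError
from .mediation import MediationResult, bootstrap_bcci, dichotomize_exposure
from .prs import ClumpConfig, score_pipeline
from .qc import QCThresholds, run_qc
from .simulate import SimulationConfig, simulate_cohort

log = logging.getLogger("erpmed")


@dataclass
class MediationSpec:
    """One exposure -> mediator -> outcome triple to analyze."""

    trait: str
    p_threshold: float
    mediator: str = "gi_flag"
    outcome: str = "panss_positive"
    cases_only: bool = True
    interaction: bool = False


@dataclass
class PipelineConfig:
    simulation: SimulationConfig | None = None
    genotypes_path: str | None = None
    sumstats_paths: dict = field(default_factory=dict)
    phenotypes_path: str | None = None
    qc: QCThresholds = field(default_factory=QCThresholds)
    clump: ClumpConfig = field(default_factory=ClumpConfig)
    k: int | str = "auto"
    k_range: tuple[int, ...] = (2, 3, 4, 5)
    folds: int = 10
    mediation_specs: list[MediationSpec] = field(default_factory=list)
    n_boot: int = 200
    out_dir: str = "erpmed_out"
    seed: int = 0

    def __post_init__(self) -> None:
        has_real = self.genotypes_path is not None
        if has_real == (self.simulation is not None):
            raise ConfigurationError(
                "provide exactly one of a SimulationConfig or real input paths")


@dataclass
class StageRecord:
    stage: str
    params: dict
    counts: dict
    outputs: list[str]
    seconds: float


@dataclass
class RunReport:
    stages: list[StageRecord] = field(default_factory=list)
    table1: list[GroupComparison] = field(default_factory=list)
    table1_counts: dict = field(default_factory=dict)
    associations: list[AssociationResult] = field(default_factory=list)
    mediations: list[tuple[MediationSpec, MediationResult]] = field(default_factory=list)
    seed: int = 0
    chosen_k: int | None = None
    gi_size: int | None = None


def _record(report: RunReport, stage: str, t0: float, params: dict,
            counts: dict, outputs: list[str]) -> None:
    rec = StageRecord(stage=stage, params=params, counts=counts,
                      outputs=[str(o) for o in outputs],
                      seconds=round(time.time() - t0, 3))
    for o in rec.outputs:
        p = Path(o)
        if not (p.exists() and p.stat().st_size > 0):
            raise RuntimeError(f"stage {stage}: output {o} missing or empty")
    report.stages.append(rec)
    log.info("stage %s done in %.2fs: %s", stage, rec.seconds, counts)


def table_one(pheno: pd.DataFrame, gi: pd.Series) -> tuple[list[GroupComparison], dict]:
    """Demographic/clinical comparisons of GI vs non-GI, mirroring the
    study's descriptive table: diagnosis and sex chi-squares, age t-test,
    smoking chi-square, and (cases) PANSS-positive t-test plus a
    covariate-adjusted linear regression coefficient for GI."""
    gi = gi.reindex(pheno.index)
    comps: list[GroupComparison] = []
    counts: dict = {}

    diag_tab = pd.crosstab(gi, pheno["diagnosis"])[["SCZ", "BPD", "control"]]
    diag_tab = diag_tab.reindex([1, 0]).to_numpy()
    comps.append(pearson_chi2(diag_tab, "diagnosis"))
    counts["diagnosis_2x3"] = diag_tab.tolist()
    counts["gi_case_fraction"] = float(diag_tab[0, :2].sum() / diag_tab[0].sum())

    sex_tab = pd.crosstab(gi, pheno["sex"]).reindex([1, 0]).to_numpy()
    comps.append(pearson_chi2(sex_tab, "sex"))

    a1 = pheno.loc[gi == 1, "age"]
    a0 = pheno.loc[gi == 0, "age"]
    comps.append(two_sample_t(a1.mean(), a1.std(), len(a1),
                              a0.mean(), a0.std(), len(a0), "age"))

    smoke_tab = pd.crosstab(gi, pheno["smoker"]).reindex([1, 0])
    comps.append(pearson_chi2(smoke_tab[["yes", "no"]].to_numpy(), "smoker"))

    cases = pheno["diagnosis"].isin(["SCZ", "BPD"])
    panss = pheno.loc[cases, "panss_positive"].dropna()
    g1 = panss[gi.reindex(panss.index) == 1]
    g0 = panss[gi.reindex(panss.index) == 0]
    if len(g1) >= 2 and len(g0) >= 2:
        comps.append(two_sample_t(g1.mean(), g1.std(), len(g1),
                                  g0.mean(), g0.std(), len(g0),
                                  "panss_positive"))
        sub = pheno.loc[panss.index].copy()
        X = np.column_stack([
            np.ones(len(sub)),
            gi.reindex(sub.index).to_numpy(dtype=float),
            sub["age"].to_numpy(dtype=float),
            (sub["sex"] == "F").to_numpy(dtype=float),
            sub["cpz_dose"].fillna(sub["cpz_dose"].median()).to_numpy(dtype=float),
            (sub["smoker"] == "yes").to_numpy(dtype=float),
        ])
        fit = ols_fit(panss.to_numpy(dtype=float), X,
                      names=["intercept", "gi", "age", "sex", "cpz", "smoker"])
        comps.append(GroupComparison(
            "panss_positive_adj", "ols_beta", float(fit.coef[1]), fit.df_resid,
            float(fit.pvalues[1]), ("age", "sex", "cpz", "smoker")))
    return comps, counts


def run_pipeline(cfg: PipelineConfig) -> RunReport:
    """Execute every stage; outputs land in ``cfg.out_dir``."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(seed=cfg.seed)

    # --- inputs -----------------------------------------------------------
    t0 = time.time()
    if cfg.simulation is not None:
        sim = cfg.simulation
        g, sumstats, pheno = simulate_cohort(sim)
        pheno_path = out / "phenotypes.tsv"
        eio.write_phenotypes(pheno, pheno_path)
        _record(report, "simulate", t0,
                {"seed": sim.seed, "n_samples": sim.n_samples,
                 "n_variants": sim.n_variants},
                {"samples": g.n_samples, "variants": g.n_variants},
                [pheno_path])
    else:
        g = _load_genotypes(cfg.genotypes_path)
        sumstats = {t: eio.read_sumstats(p) for t, p in cfg.sumstats_paths.items()}
        pheno = eio.read_phenotypes(cfg.phenotypes_path)
        _record(report, "load", t0, {"genotypes": cfg.genotypes_path},
                {"samples": g.n_samples, "variants": g.n_variants}, [])

    # --- QC ---------------------------------------------------------------
    t0 = time.time()
    g_qc, pcs, qc_report = run_qc(g, cfg.qc)
    pcs_path = out / "pcs.tsv"
    pcs.to_frame().to_csv(pcs_path, sep="\t")
    qc_path = out / "qc_report.tsv"
    pd.DataFrame(qc_report.removed_variants + qc_report.removed_samples,
                 columns=["id", "reason"]).to_csv(qc_path, sep="\t", index=False)
    if qc_path.stat().st_size == 0:  # header-only is still non-empty
        pass
    _record(report, "qc", t0, vars(cfg.qc).copy(),
            {"samples": g_qc.n_samples, "variants": g_qc.n_variants,
             "removed_samples": len(qc_report.removed_samples),
             "removed_variants": len(qc_report.removed_variants)},
            [pcs_path, qc_path])

    pheno = pheno.loc[[s for s in g_qc.sample_ids if s in pheno.index]]

    # --- clustering -------------------------------------------------------
    t0 = time.time()
    profiles = pheno[list(ERP_MEASURES)]
    if cfg.k == "auto":
        sel = select_k_vfold(profiles, cfg.k_range, v=cfg.folds, seed=cfg.seed)
        k = sel.chosen_k
        report.chosen_k = k
    else:
        k = int(cfg.k)
        report.chosen_k = k
    model = label_globally_impaired(fit_kmeans(profiles, k, seed=cfg.seed))
    assign = assignments_frame(model, pheno.index)
    assign_path = out / "clusters.tsv"
    assign.to_csv(assign_path, sep="\t")
    report.gi_size = int(assign["gi_flag"].sum())
    _record(report, "cluster", t0, {"k": k, "folds": cfg.folds},
            {"gi_size": report.gi_size, "n": len(assign)}, [assign_path])

    gi = assign["gi_flag"]
    report.table1, report.table1_counts = table_one(pheno, gi)

    # --- scoring ----------------------------------------------------------
    t0 = time.time()
    scores = score_pipeline(g_qc, sumstats, cfg.clump)
    scores_path = out / "prs.tsv"
    scores.to_csv(scores_path, sep="\t", index=False)
    _record(report, "score", t0,
            {"window_kb": cfg.clump.window_kb, "r2_max": cfg.clump.r2_max,
             "thresholds": list(cfg.clump.thresholds)},
            {"rows": len(scores)}, [scores_path])

    # --- association ------------------------------------------------------
    t0 = time.time()
    cases_mask = pheno["diagnosis"].isin(["SCZ", "BPD"])
    assoc_all = prs_association(scores, gi, pcs.to_frame(), subset="all")
    try:
        assoc_cases = prs_association(scores, gi, pcs.to_frame(),
                                      subset="cases", subset_mask=cases_mask)
    except ConfigurationError:
        assoc_cases = []
    report.associations = assoc_all + assoc_cases
    assoc_path = out / "associations.tsv"
    association_frame(report.associations).to_csv(assoc_path, sep="\t", index=False)
    _record(report, "assoc", t0, {"subsets": ["all", "cases"]},
            {"tests": len(report.associations)}, [assoc_path])

    # --- mediation --------------------------------------------------------
    t0 = time.time()
    med_rows = []
    for spec in cfg.mediation_specs:
        res = _run_mediation(spec, scores, pheno, gi, pcs.to_frame(),
                             n_boot=cfg.n_boot, seed=cfg.seed)
        report.mediations.append((spec, res))
        med_rows.append({
            "exposure": f"{spec.trait}:{spec.p_threshold:g}",
            "mediator": spec.mediator, "outcome": spec.outcome,
            "nde": res.nde, "nie": res.nie, "total": res.total,
            "proportion_mediated": res.proportion_mediated,
            "nde_lo": res.ci_nde[0], "nde_hi": res.ci_nde[1],
            "nie_lo": res.ci_nie[0], "nie_hi": res.ci_nie[1],
            "n": res.n, "n_boot": res.n_boot, "seed": res.seed,
        })
    if cfg.mediation_specs:
        med_path = out / "mediation.tsv"
        pd.DataFrame(med_rows).to_csv(med_path, sep="\t", index=False)
        _record(report, "mediate", t0, {"n_boot": cfg.n_boot},
                {"analyses": len(med_rows)}, [med_path])

    (out / "report.md").write_text(render_report(report))
    return report


def _run_mediation(spec: MediationSpec, scores: pd.DataFrame,
                   pheno: pd.DataFrame, gi: pd.Series, pcs: pd.DataFrame,
                   n_boot: int, seed: int) -> MediationResult:
    s = scores[(scores["trait"] == spec.trait)
               & (scores["p_threshold"] == spec.p_threshold)]
    if s.empty:
        raise ConfigurationError(
            f"no scores for {spec.trait} at P_T={spec.p_threshold}")
    score = s.set_index("sample_id")["score"].reindex(pheno.index)
    if spec.cases_only:
        score = score[pheno["diagnosis"].isin(["SCZ", "BPD"])]
    a = dichotomize_exposure(score)

    d = pheno.copy()
    d["exposure"] = a.reindex(d.index)
    d["gi_flag"] = gi.reindex(d.index)
    d["sex_f"] = (d["sex"] == "F").astype(float)
    d["smoker_yes"] = (d["smoker"] == "yes").astype(float)
    d = d.join(pcs)
    covars = [c for c in pcs.columns] + ["age", "sex_f", "smoker_yes"]
    if spec.cases_only:
        covars.append("cpz_dose")
    return bootstrap_bcci(d, spec.outcome, spec.mediator, "exposure", covars,
                          interaction=spec.interaction, n_boot=n_boot, seed=seed)


def _load_genotypes(path: str):
    p = Path(path)
    if p.suffix == ".vcf" or str(p).endswith(".vcf.gz"):
        return eio.read_vcf(p)
    if p.suffix == ".bed" or p.with_suffix(".bed").exists():
        return eio.read_plink(p.with_suffix(""))
    return eio.read_dosage_tsv(p)


# ---------------------------------------------------------------------------
# reporting

def _fmt_p(p: float) -> str:
    if p != p:
        return "NA"
    return f"{p:.2e}" if p < 0.005 else f"{p:.3f}"


def render_report(report: RunReport) -> str:
    """Plain-markdown run report: demographics, associations, mediation."""
    lines = [f"# Run report (seed {report.seed})", ""]
    lines.append("## Stages")
    for s in report.stages:
        lines.append(f"- {s.stage}: {s.counts} ({s.seconds:.2f} s); "
                     f"params {s.params}; outputs {s.outputs}")
    lines.append("")

    lines.append("## Demographic and clinical comparisons "
                 "(globally impaired vs non-globally impaired)")
    if report.table1:
        if report.gi_size is not None:
            lines.append(f"- globally impaired cluster size: {report.gi_size}")
        if "gi_case_fraction" in report.table1_counts:
            lines.append(f"- case fraction in GI cluster: "
                         f"{100 * report.table1_counts['gi_case_fraction']:.1f}%")
        for c in report.table1:
            stat = (f"X2 = {c.statistic:.2f}" if c.statistic_kind == "chi2"
                    else f"{c.statistic_kind} = {c.statistic:.2f}")
            adj = f" (adjusted for {', '.join(c.adjusted_for)})" if c.adjusted_for else ""
            lines.append(f"- {c.variable}: {stat}, P = {_fmt_p(c.p)}{adj}")
    else:
        lines.append("not run")
    lines.append("")

    lines.append("## PRS associations with globally impaired ERP")
    if report.associations:
        lines.append("| subset | trait | P_T | beta | P | q | dR2 (%) | flags |")
        lines.append("|---|---|---|---|---|---|---|---|")
        for r in report.associations:
            flags = "**" if r.q_value < 0.05 else ("*" if r.wald_p < 0.05 else "")
            lines.append(
                f"| {r.subset} | {r.trait} | {r.p_threshold:g} | {r.beta:.2f} "
                f"| {_fmt_p(r.wald_p)} | {_fmt_p(r.q_value)} "
                f"| {100 * r.nagelkerke_r2:.2f} | {flags} |")
        lines.append("")
        lines.append("\\* unadjusted P < 0.05; ** FDR-corrected P < 0.05")
    else:
        lines.append("not run")
    lines.append("")

    lines.append("## Mediation (exposure -> globally impaired ERP -> outcome)")
    if report.mediations:
        for spec, r in report.mediations:
            pm = (f"{100 * r.proportion_mediated:.1f}%" if r.pm_defined
                  else "undefined (total effect 0)")
            lines.append(
                f"- {spec.trait}:{spec.p_threshold:g} -> {spec.mediator} -> "
                f"{spec.outcome}: NDE = {r.nde:.2f} "
                f"(95% BCCI {r.ci_nde[0]:.2f}, {r.ci_nde[1]:.2f}); "
                f"NIE = {r.nie:.2f} "
                f"(95% BCCI {r.ci_nie[0]:.2f}, {r.ci_nie[1]:.2f}); "
                f"total = {r.total:.2f}; proportion mediated = {pm}; "
                f"n = {r.n}, {r.n_boot} bootstrap replicates")
    else:
        lines.append("not run")
    lines.append("")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# config file support

def load_config(path) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file (all keys optional)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    sim = None
    if "simulation" in raw:
        sim = SimulationConfig(**(raw["simulation"] or {}))
    qc = QCThresholds(**raw.get("qc", {}))
    clump = ClumpConfig(**raw.get("clump", {}))
    specs = [MediationSpec(**s) for s in raw.get("mediation_specs", [])]
    return PipelineConfig(
        simulation=sim,
        genotypes_path=raw.get("genotypes_path"),
        sumstats_paths=raw.get("sumstats_paths", {}),
        phenotypes_path=raw.get("phenotypes_path"),
        qc=qc, clump=clump,
        k=raw.get("k", "auto"),
        k_range=tuple(raw.get("k_range", (2, 3, 4, 5))),
        folds=raw.get("folds", 10),
        mediation_specs=specs,
        n_boot=raw.get("n_boot", 200),
        out_dir=raw.get("out_dir", "erpmed_out"),
        seed=raw.get("seed", 0),
    )
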