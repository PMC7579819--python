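"""End-to-end orchestration: simulate-or-load through replication.

A single YAML config drives eleven stages; one top-level seed is fanned out
deterministically per stage, every output carries the config hash and seed
in the run manifest, and a completed stage's outputs can be reused
(``resume=True``). Stage failure halts with the stage name; outputs written
so far are left in place.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as tio
from .compare import (
    conditional_novel_genes,
    detect_lost_mediators,
    evaluate_module_prediction,
    fit_sem,
    replicate_edges,
)
from .iv import build_instruments, validate_instruments
from .network import (
    DEFAULT_TUNING_GRID,
    learn_network,
    permutation_stability,
    tune_by_hamming,
)
from .properties import (
    annotation_degree_odds_ratio,
    degrees_and_roles,
    find_modules,
)
from .stats import hypergeom_enrichment
from .synthetic import simulate_study, simulate_term_sets, simulate_cohorts

log = logging.getLogger("transnet")

STAGES = [
    "simulate", "residualize", "build_iv", "tune", "learn", "stability",
    "properties", "compare", "predict", "enrich", "replicate",
]


@dataclass
class RunConfig:
    """Validated pipeline configuration (synthetic mode by default)."""

    out_dir: str = "transnet_run"
    seed: int = 1
    # synthetic-study conditions
    n_genes: int = 30
    n_cases: int = 300
    n_controls: int = 300
    window: int = 40_000
    deleted_edges: list[list[str]] = field(default_factory=lambda: [["G13", "G14"]])
    # learning
    structure_cohort: str = "control"  # 'control' | 'case' | 'pooled'
    tuning_grid: list[float] = field(default_factory=lambda: list(DEFAULT_TUNING_GRID))
    n_subsamples: int = 6
    subsample_frac: float = 0.75
    f_threshold: float = 10.0
    alpha_validity: float = 0.05
    # stability
    stability_degrees: list[int] = field(default_factory=lambda: [1, 2, 3, 4, 5])
    stability_n_perm: int = 5
    stability_n_genes: int = 10
    # downstream thresholds
    core_min_outdegree: int = 4
    degree_threshold: int = 3
    corr_threshold: float = 0.6
    mspe_threshold: float = 0.3
    fdr_level: float = 0.05
    cv_repeats: int = 50
    known_genes: list[str] = field(default_factory=lambda: ["G01", "G03", "G09"])
    n_replication_samples: int = 25
    resume: bool = False

    @staticmethod
    def from_yaml(path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in RunConfig.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return RunConfig(**raw)

    def config_hash(self) -> str:
        blob = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def validate(self) -> None:
        if self.structure_cohort not in ("control", "case", "pooled"):
            raise ValueError("structure_cohort must be control, case or pooled")
        if not (0 < self.subsample_frac <= 1):
            raise ValueError("subsample_frac must be in (0, 1]")
        if not (0 < self.fdr_level < 1):
            raise ValueError("fdr_level must be in (0, 1)")
        if self.corr_threshold <= 0 or self.mspe_threshold <= 0:
            raise ValueError("prediction thresholds must be positive")


def _stage_seed(seed: int, stage_index: int) -> int:
    return (seed * 1_000_003 + stage_index) % (2**31)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the run manifest (also written to disk)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "config": asdict(config),
        "stages": {},
    }
    state: dict = {}
    for idx, stage in enumerate(STAGES):
        seed = _stage_seed(config.seed, idx)
        log.info("stage %s (seed %d)", stage, seed)
        try:
            outputs = _STAGE_FUNCS[stage](config, out, seed, state)
        except Exception as exc:  # halt with the stage name
            manifest["failed_stage"] = stage
            manifest["error"] = str(exc)
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
            raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc
        manifest["stages"][stage] = {"seed": seed, "outputs": outputs}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _rows(path: Path) -> int:
    return sum(1 for _ in open(path)) - 1


def _stage_simulate(config: RunConfig, out: Path, seed: int, state: dict):
    study = simulate_study(
        seed=seed, n_genes=config.n_genes, n_cases=config.n_cases,
        n_controls=config.n_controls, window=config.window,
        deleted_edges={tuple(e) for e in config.deleted_edges},
    )
    state["study"] = study
    tio.write_genotypes_tsv(study.genotypes, out / "genotypes.tsv")
    tio.write_genotypes_vcf(study.genotypes, study.panel, out / "genotypes.vcf")
    tio.write_snp_panel_tsv(study.panel, out / "snps.tsv")
    tio.write_genes_bed(study.genes, out / "genes.bed")
    tio.write_hic_bedpe(study.hic, out / "hic.bedpe")
    tio.write_expression_tsv(study.expression, out / "expression_raw.tsv")
    tio.write_covariates_tsv(study.expression.covariates, out / "covariates.tsv")
    tio.write_true_system(study.system, out / "truth_edges.tsv",
                          out / "truth_manifest.json",
                          params={"seed": seed, "n_genes": config.n_genes})
    return {"expression_raw.tsv": _rows(out / "expression_raw.tsv"),
            "genotypes.tsv": _rows(out / "genotypes.tsv")}


def _stage_residualize(config: RunConfig, out: Path, seed: int, state: dict):
    study = state["study"]
    state["expr"] = study.residualized
    tio.write_expression_tsv(study.residualized, out / "expression_residualized.tsv")
    return {"expression_residualized.tsv": _rows(out / "expression_residualized.tsv")}


def _stage_build_iv(config: RunConfig, out: Path, seed: int, state: dict):
    study = state["study"]
    expr = state["expr"]
    ivs = build_instruments(study.genotypes, study.genes, study.panel, study.hic,
                            expr, window=config.window,
                            f_threshold=config.f_threshold)
    ivs = validate_instruments(ivs, expr, alpha_validity=config.alpha_validity)
    state["ivs"] = ivs
    tio.write_instruments(ivs, out / "instruments.tsv", out / "instruments_meta.tsv")
    return {"instruments.tsv": ivs.scores.shape[1],
            "instruments_meta.tsv": len(ivs.meta)}


def _structure_inputs(config: RunConfig, state: dict):
    """Expression/instruments used for structure learning (the reference
    cohort for lost-mediator detection is the controls by default)."""
    expr = state["expr"]
    if config.structure_cohort != "pooled":
        expr = expr.subset(config.structure_cohort)
    ivs = state["ivs"].subset(expr.samples) if len(state["ivs"]) else state["ivs"]
    return expr, ivs


def _stage_tune(config: RunConfig, out: Path, seed: int, state: dict):
    expr_s, ivs_s = _structure_inputs(config, state)
    report = tune_by_hamming(
        expr_s, ivs_s, grid=tuple(config.tuning_grid),
        n_subsamples=config.n_subsamples, subsample_frac=config.subsample_frac,
        seed=seed,
    )
    state["alpha"] = report.selected
    pd.DataFrame(report.as_rows()).to_csv(out / "tuning.tsv", sep="\t", index=False)
    return {"tuning.tsv": len(report.grid), "selected_alpha": report.selected}


def _stage_learn(config: RunConfig, out: Path, seed: int, state: dict):
    expr_s, ivs_s = _structure_inputs(config, state)
    graph = learn_network(expr_s, ivs_s, alpha=state["alpha"])
    state["graph"] = graph
    tio.write_graph_tsv(graph, out / "network_edges.tsv")
    tio.write_graph_graphml(graph, out / "network.graphml")
    return {"network_edges.tsv": len(graph.edge_table()),
            "gene_edges": len(graph.gene_edges())}


def _stage_stability(config: RunConfig, out: Path, seed: int, state: dict):
    rows = []
    roles_df = degrees_and_roles(state["graph"])
    for role in ("broadcaster", "receptor"):
        col = "out_degree" if role == "broadcaster" else "in_degree"
        for degree in config.stability_degrees:
            avail = ((roles_df["role"] == role) & (roles_df[col] == degree)).sum()
            if avail == 0:
                continue
            expr_s, ivs_s = _structure_inputs(config, state)
            res = permutation_stability(
                expr_s, ivs_s, state["graph"], role=role,
                degree=degree, n_genes=config.stability_n_genes,
                n_perm=config.stability_n_perm, seed=seed + degree,
            )
            rows.append({"role": role, "degree": degree,
                         "n_genes_used": res.n_genes_used,
                         "n_perm": res.n_perm,
                         "mean_stability": res.mean_stability})
    pd.DataFrame(rows).to_csv(out / "stability.tsv", sep="\t", index=False)
    return {"stability.tsv": len(rows)}


def _stage_properties(config: RunConfig, out: Path, seed: int, state: dict):
    graph = state["graph"]
    roles = degrees_and_roles(graph)
    state["roles"] = roles
    roles.to_csv(out / "roles.tsv", sep="\t")
    modules = find_modules(graph, core_min_outdegree=config.core_min_outdegree)
    state["modules"] = modules
    idx_rows = [
        {"core": m.core, "n_members": len(m.members),
         "n_boundary_receptors": len(m.boundary_receptors),
         "max_path_length": m.max_path_length,
         "members": ",".join(sorted(m.members))}
        for m in modules
    ]
    pd.DataFrame(idx_rows, columns=["core", "n_members", "n_boundary_receptors",
                                    "max_path_length", "members"]).to_csv(
        out / "modules.tsv", sep="\t", index=False)
    flag = roles["has_iv"]
    orr = annotation_degree_odds_ratio(roles, flag,
                                       degree_threshold=config.degree_threshold)
    pd.DataFrame([vars(orr)]).to_csv(out / "odds_ratio.tsv", sep="\t", index=False)
    return {"roles.tsv": len(roles), "modules.tsv": len(modules)}


def _stage_compare(config: RunConfig, out: Path, seed: int, state: dict):
    expr = state["expr"]
    cases, controls = expr.subset("case"), expr.subset("control")
    state["cases"], state["controls"] = cases, controls
    for label, cohort_expr in (("controls", controls), ("cases", cases)):
        fit = fit_sem(cohort_expr, state["graph"])
        fit.edges.to_csv(out / f"sem_{label}.tsv", sep="\t", index=False)
    table, lost = detect_lost_mediators(cases, controls, state["graph"])
    state["lost"] = lost
    table.to_csv(out / "exclusive_effects.tsv", sep="\t", index=False)
    pd.DataFrame(lost, columns=["mediator", "downstream"]).to_csv(
        out / "lost_mediators.tsv", sep="\t", index=False)
    return {"exclusive_effects.tsv": len(table), "lost_mediators.tsv": len(lost)}


def _stage_predict(config: RunConfig, out: Path, seed: int, state: dict):
    frames = []
    cands = []
    known = set(config.known_genes)
    for m in state["modules"]:
        pred = evaluate_module_prediction(
            state["cases"], state["controls"], m, state["graph"],
            corr_threshold=config.corr_threshold,
            mspe_threshold=config.mspe_threshold,
            repeats=config.cv_repeats, seed=seed,
        )
        frames.append(pred)
        if pred["good_predictor"].any():
            cands.append(conditional_novel_genes(
                state["cases"], state["controls"], m, known,
                q_threshold=config.fdr_level))
    pred_all = (pd.concat(frames, ignore_index=True) if frames
                else pd.DataFrame(columns=["core", "target"]))
    cand_all = (pd.concat(cands, ignore_index=True) if cands
                else pd.DataFrame(columns=["core", "target", "candidate"]))
    state["candidates"] = cand_all
    pred_all.to_csv(out / "prediction.tsv", sep="\t", index=False)
    cand_all.to_csv(out / "candidates.tsv", sep="\t", index=False)
    return {"prediction.tsv": len(pred_all), "candidates.tsv": len(cand_all)}


def _stage_enrich(config: RunConfig, out: Path, seed: int, state: dict):
    genes = state["expr"].gene_ids
    term_sets = simulate_term_sets(genes, seed=seed)
    query = set(m for m, _ in state.get("lost", []))
    cand = state.get("candidates")
    if cand is not None and len(cand) and "candidate" in cand:
        query |= set(cand.loc[cand["candidate"], "target"])
    if not query:  # fall back to high-degree genes for the smoke report
        roles = state["roles"]
        query = set(roles.sort_values("degree").tail(3).index)
    enr = hypergeom_enrichment(query, term_sets, set(genes))
    enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    return {"enrichment.tsv": len(enr)}


def _stage_replicate(config: RunConfig, out: Path, seed: int, state: dict):
    study = state["study"]
    from .synthetic import simulate_genotypes

    geno = simulate_genotypes(study.panel, config.n_replication_samples,
                              seed=seed, sample_prefix="R")
    repl = simulate_cohorts(study.system, geno,
                            n_cases=0, n_controls=config.n_replication_samples,
                            seed=seed + 1)
    table, fraction, excluded = replicate_edges(state["graph"], repl,
                                                q_threshold=config.fdr_level)
    table.to_csv(out / "replication.tsv", sep="\t", index=False)
    return {"replication.tsv": len(table), "replicated_fraction": fraction,
            "excluded_edges": excluded}


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "residualize": _stage_residualize,
    "build_iv": _stage_build_iv,
    "tune": _stage_tune,
    "learn": _stage_learn,
    "stability": _stage_stability,
    "properties": _stage_properties,
    "compare": _stage_compare,
    "predict": _stage_predict,
    "enrich": _stage_enrich,
    "replicate": _stage_replicate,
}
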