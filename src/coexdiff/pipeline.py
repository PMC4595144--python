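"""End-to-end orchestration of the case-control transcriptome analysis.

Stage order: quality control -> discovery/replication split -> covariate
adjustment -> differential expression (two-stage) -> co-expression + CDC
-> differential co-expression (permutation test, preservation) -> hub
genes (on modules passing both the permutation and preservation gates)
-> nearest-shrunken-centroid classification. One global seed derives a
deterministic per-stage seed so any stage can be rerun in isolation; the
structured report contains no timestamps and is byte-identical across
reruns with the same config.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from . import adjust, dcx, dge, hubs, network, nsc, qc
from .simulate import SimulationConfig, config_from_dict, generate_dataset

logger = logging.getLogger("coexdiff")

__all__ = ["PipelineConfig", "validate_config", "run_pipeline"]


class InputBlock(BaseModel):
    expression: str
    metadata: str
    annotation: str


class QcBlock(BaseModel):
    rin_min: float = Field(6.0, gt=0)
    purity_min: float = Field(1.8, gt=0)
    k_mad: float = Field(5.0, gt=0)
    min_discordant: int = Field(2, ge=1)
    r_duplicate: float = Field(0.99, gt=0, lt=1)


class AdjustBlock(BaseModel):
    n_sv: int | Literal["auto"] = "auto"
    known_covariates: list[str] = Field(default_factory=lambda: [
        "age", "sex", "hypertension", "smoking_ever", "familial_ia"])


class DeBlock(BaseModel):
    alpha_fdr: float = Field(0.05, gt=0, lt=1)
    candidate_genes: Optional[str] = None


class NetworkBlock(BaseModel):
    beta: float = Field(6.0, ge=1)
    cut_height: float = Field(0.96, gt=0, le=1)
    min_module_size: int = Field(30, ge=2)
    cdc_permutations: int = Field(10000, ge=1000)


class DcBlock(BaseModel):
    beta: float = Field(6.0, ge=1)
    cut_height: float = Field(0.96, gt=0, le=1)
    min_module_size: int = Field(30, ge=2)
    n_permutations: int = Field(10000, ge=100)
    preservation_permutations: int = Field(200, ge=50)
    p_bonf_threshold: float = Field(0.05, gt=0, lt=1)
    z_summary_threshold: float = 10.0
    export_heatmaps: bool = False


class HubBlock(BaseModel):
    edge_quantile: float = Field(0.9, gt=0, lt=1)
    top_frac: float = Field(0.2, gt=0, lt=1)


class ClassifierBlock(BaseModel):
    n_folds: int = Field(10, ge=2)
    n_delta: int = Field(30, ge=2)
    error_ceiling: float = Field(0.4, gt=0, le=1)


class PipelineConfig(BaseModel):
    """Validated configuration for a full pipeline run."""

    seed: int = 0
    out_dir: str = "coexdiff_run"
    input: Optional[InputBlock] = None
    simulate: Optional[dict] = None
    qc: QcBlock = QcBlock()
    adjust: AdjustBlock = AdjustBlock()
    de: DeBlock = DeBlock()
    network: NetworkBlock = NetworkBlock()
    dc: DcBlock = DcBlock()
    hubs: HubBlock = HubBlock()
    classifier: ClassifierBlock = ClassifierBlock()

    @field_validator("simulate")
    @classmethod
    def _simulate_parses(cls, v):
        if v is not None:
            config_from_dict(v).validate()
        return v

    def model_post_init(self, _ctx) -> None:
        if self.input is None and self.simulate is None:
            raise ValueError("config needs either an 'input' or a 'simulate' block")
        if self.input is not None:
            missing = [p for p in (self.input.expression, self.input.metadata,
                                   self.input.annotation) if not Path(p).exists()]
            if missing:
                raise ValueError(f"input file(s) not found: {missing}")


def validate_config(raw: dict) -> PipelineConfig:
    """Normalize a raw config dict, filling defaults; pydantic aggregates
    every range violation into a single error."""
    return PipelineConfig(**raw)


def _stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    h = np.random.SeedSequence([seed, zlib.crc32(stage.encode()) % (2**31)])
    return int(h.generate_state(1)[0] % (2**31))


def _covariate_design(metadata: pd.DataFrame, names: list[str]) -> pd.DataFrame:
    cols = {}
    for name in names:
        if name == "sex":
            cols["sex"] = (metadata["reported_sex"] == "F").astype(float)
        else:
            cols[name] = metadata[name].astype(float)
    return pd.DataFrame(cols, index=metadata.index)


def _drop_constant_covariates(design: pd.DataFrame, context: str) -> pd.DataFrame:
    """Covariates constant within a stratum carry no information and would
    make the design rank-deficient; drop them with a warning."""
    const = [c for c in design.columns if design[c].nunique() <= 1]
    if const:
        logger.warning("dropping constant covariate(s) in %s: %s", context, const)
        design = design.drop(columns=const)
    return design


def run_pipeline(config: PipelineConfig | dict) -> dict:
    """Execute every stage and write stage outputs plus a report.

    Returns the report dict; writes report.json, report.txt and per-stage
    tables under ``config.out_dir``. A stage failure raises with the stage
    name; outputs of completed stages remain on disk.
    """
    if isinstance(config, dict):
        config = validate_config(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed}
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    def stage(name):
        logger.info("stage %s started", name)
        return time.time()

    def done(name, t0):
        logger.info("stage %s finished in %.1fs", name, time.time() - t0)

    try:
        # ---- input ------------------------------------------------------
        t0 = stage("input")
        if config.simulate is not None:
            sim_cfg = config_from_dict(config.simulate)
            sim_cfg.seed = _stage_seed(config.seed, "simulate") \
                if "seed" not in config.simulate else sim_cfg.seed
            ds = generate_dataset(sim_cfg)
            expr_raw, metadata, annotation = ds.expression, ds.metadata, ds.annotation
            report["simulated"] = True
        else:
            from .io import read_annotation, read_expression, read_metadata
            expr_raw = read_expression(config.input.expression)
            metadata = read_metadata(config.input.metadata)
            annotation = read_annotation(config.input.annotation)
            report["simulated"] = False
        done("input", t0)

        # ---- QC ---------------------------------------------------------
        t0 = stage("qc")
        expr, meta, qcrep = qc.run_qc(
            expr_raw, metadata, annotation,
            rin_min=config.qc.rin_min, purity_min=config.qc.purity_min,
            k_mad=config.qc.k_mad, min_discordant=config.qc.min_discordant,
            r_dup=config.qc.r_duplicate,
        )
        report["qc"] = qcrep.to_dict()
        (out / "qc_report.json").write_text(json.dumps(qcrep.to_dict(), indent=1))
        leuko = qc.compare_leukocyte_counts(meta)
        leuko.to_csv(out / "leukocyte_tests.tsv", sep="\t")
        report["leukocytes"] = {
            "any_significant": bool((leuko["p"] < 0.05).any()),
            "p_values": {k: round(v, 4) for k, v in leuko["p"].items()},
        }
        done("qc", t0)

        # ---- split ------------------------------------------------------
        t0 = stage("split")
        split = qc.split_discovery_replication(meta, _stage_seed(config.seed, "split"))
        split.to_csv(out / "split.tsv", sep="\t")
        disc = split.index[split == "discovery"]
        repl = split.index[split == "replication"]
        report["split"] = {
            "discovery": {"cases": int(meta.loc[disc, "is_case"].sum()),
                          "controls": int((~meta.loc[disc, "is_case"]).sum())},
            "replication": {"cases": int(meta.loc[repl, "is_case"].sum()),
                            "controls": int((~meta.loc[repl, "is_case"]).sum())},
        }
        done("split", t0)

        # ---- adjustment -------------------------------------------------
        t0 = stage("adjust")
        y_disc = meta.loc[disc, "is_case"].astype(int).to_numpy()
        y_repl = meta.loc[repl, "is_case"].astype(int).to_numpy()
        sv_disc = adjust.estimate_surrogate_variables(
            expr[disc], y_disc, n_sv=config.adjust.n_sv,
            random_state=_stage_seed(config.seed, "sva"))
        sv_repl = adjust.estimate_surrogate_variables(
            expr[repl], y_repl, n_sv=config.adjust.n_sv,
            random_state=_stage_seed(config.seed, "sva_repl"))
        sv_disc.to_csv(out / "surrogate_variables_discovery.tsv", sep="\t")
        report["adjust"] = {"n_sv_discovery": sv_disc.shape[1],
                            "n_sv_replication": sv_repl.shape[1]}
        risk_disc = _drop_constant_covariates(
            _covariate_design(meta.loc[disc], config.adjust.known_covariates),
            "discovery")
        risk_repl = _drop_constant_covariates(
            _covariate_design(meta.loc[repl], config.adjust.known_covariates),
            "replication")
        resid_disc = adjust.residualize(expr[disc], risk_disc)
        resid_repl = adjust.residualize(expr[repl], risk_repl)
        done("adjust", t0)

        # ---- differential expression ------------------------------------
        t0 = stage("de")
        de_res = dge.logistic_de(expr[disc], y_disc, sv_disc)
        de_res.to_csv(out / "de_discovery.tsv", sep="\t")
        replicated = dge.two_stage_replication(
            de_res, expr[repl], y_repl, sv_repl, alpha_fdr=config.de.alpha_fdr)
        report["de"] = {
            "n_discovery_fdr_significant": int((de_res["p_fdr"] < config.de.alpha_fdr).sum()),
            "n_replicated": int(len(replicated)),
            "n_nonconverged": int((~de_res["converged"]).sum()),
        }
        probe_to_gene = annotation["gene_symbol"]
        candidates = None
        if config.de.candidate_genes:
            candidates = [line.strip() for line in
                          Path(config.de.candidate_genes).read_text().splitlines()
                          if line.strip()]
            cand = dge.candidate_gene_lookup(de_res, candidates, probe_to_gene)
            cand.to_csv(out / "candidate_genes.tsv", sep="\t")
            report["de"]["candidate_probes_tested"] = int(len(cand))
            report["de"]["candidate_probes_significant"] = int(cand["significant"].sum()) \
                if len(cand) else 0
        done("de", t0)

        # ---- co-expression + CDC ----------------------------------------
        t0 = stage("network")
        adjacency = network.build_adjacency(resid_disc, beta=config.network.beta)
        modules = network.extract_modules(
            adjacency, config.network.cut_height, config.network.min_module_size)
        modules.labels.to_csv(out / "coexpression_modules.tsv", sep="\t")
        report["coexpression"] = {"n_modules": modules.n_modules()}
        if modules.n_modules():
            cdc = network.cdc_test(modules, de_res["p"],
                                   n_perm=config.network.cdc_permutations,
                                   seed=_stage_seed(config.seed, "cdc"))
            cdc.to_csv(out / "cdc_results.tsv", sep="\t")
            report["coexpression"]["cdc"] = {
                m: {"n_genes": int(r["n_genes"]), "p_perm": round(r["p_perm"], 4)}
                for m, r in cdc.iterrows()}
        done("network", t0)

        # ---- differential co-expression ---------------------------------
        t0 = stage("dc")
        disc_cases = disc[meta.loc[disc, "is_case"]]
        disc_ctrls = disc[~meta.loc[disc, "is_case"]]
        repl_cases = repl[meta.loc[repl, "is_case"]]
        repl_ctrls = repl[~meta.loc[repl, "is_case"]]
        d_disc = dcx.dc_difference(resid_disc[disc_cases], resid_disc[disc_ctrls],
                                   beta=config.dc.beta)
        dc_modules = dcx.extract_dc_modules(
            d_disc, config.dc.cut_height, config.dc.min_module_size,
            palette_seed=_stage_seed(config.seed, "palette"))
        dc_modules.labels.to_csv(out / "dc_modules.tsv", sep="\t")
        report["dc"] = {"n_modules": dc_modules.n_modules()}
        significant: list[str] = []
        if dc_modules.n_modules():
            perm = dcx.permutation_test(
                resid_disc[disc_cases], resid_disc[disc_ctrls], dc_modules,
                n_perm=config.dc.n_permutations, beta=config.dc.beta,
                seed=_stage_seed(config.seed, "dc_perm"))
            perm.to_csv(out / "dc_permutation.tsv", sep="\t")
            report["dc"]["permutation"] = {
                m: {"n_genes": int(r["n_genes"]), "d_s": round(r["d_s"], 4),
                    "perm_index": int(r["perm_index"]), "p_bonf": round(r["p_bonf"], 4)}
                for m, r in perm.iterrows()}
            significant = [str(m) for m in
                           perm.index[perm["p_bonf"] < config.dc.p_bonf_threshold]]

            preserved: list[str] = []
            if significant:
                d_repl = dcx.dc_difference(resid_repl[repl_cases],
                                           resid_repl[repl_ctrls], beta=config.dc.beta)
                pres_rows = {}
                for m in significant:
                    genes = dc_modules.modules()[m]
                    pres = dcx.preservation_zsummary(
                        d_disc, d_repl, genes,
                        n_perm=config.dc.preservation_permutations,
                        seed=_stage_seed(config.seed, f"pres_{m}"))
                    pres_rows[m] = pres
                    if pres["z_summary"] > config.dc.z_summary_threshold:
                        preserved.append(m)
                pd.DataFrame(pres_rows).T.to_csv(out / "dc_preservation.tsv", sep="\t")
                report["dc"]["preservation"] = {
                    m: {k: (round(v, 3) if isinstance(v, float) else v)
                        for k, v in r.items()} for m, r in pres_rows.items()}
            report["dc"]["significant_modules"] = significant
            report["dc"]["preserved_significant_modules"] = preserved

            if config.dc.export_heatmaps:
                dcx.dc_heatmap_export(resid_disc[disc_cases], resid_disc[disc_ctrls],
                                      dc_modules, out / "heatmaps")
        done("dc", t0)

        # ---- hub genes (gated on permutation AND preservation) ----------
        t0 = stage("hubs")
        report["hubs"] = {}
        for m in report["dc"].get("preserved_significant_modules", []):
            genes = dc_modules.modules()[m]
            graph, dropped = hubs.build_module_graph(d_disc, genes,
                                                     config.hubs.edge_quantile)
            metrics = hubs.graph_metrics(graph)
            scored = hubs.hub_scores(metrics, config.hubs.top_frac)
            scored.to_csv(out / f"hubs_{m}.tsv", sep="\t")
            entry = {"n_hubs": int(scored["is_hub"].sum()),
                     "n_dropped_isolated": len(dropped),
                     "top10": [str(g) for g in scored.index[:10]]}
            if candidates is not None:
                entry["candidate_overlap"] = hubs.overlap_with_candidates(
                    scored, candidates, probe_to_gene)
            report["hubs"][m] = entry
        done("hubs", t0)

        # ---- classifier --------------------------------------------------
        t0 = stage("classify")
        sva_fit = adjust.SurrogateVariableAnalysis(
            n_sv=config.adjust.n_sv,
            random_state=_stage_seed(config.seed, "sva")).fit(
                expr[disc].to_numpy(float).T, y_disc)
        X_disc = pd.DataFrame(sva_fit.transform(expr[disc].to_numpy(float).T).T,
                              index=expr.index, columns=disc)
        sva_rep = adjust.SurrogateVariableAnalysis(
            n_sv=config.adjust.n_sv,
            random_state=_stage_seed(config.seed, "sva_repl")).fit(
                expr[repl].to_numpy(float).T, y_repl)
        X_repl = pd.DataFrame(sva_rep.transform(expr[repl].to_numpy(float).T).T,
                              index=expr.index, columns=repl)
        model = nsc.fit_nsc(X_disc, y_disc,
                            delta_grid=None, n_folds=config.classifier.n_folds,
                            seed=_stage_seed(config.seed, "cv"))
        model.to_json(out / "classifier.json")
        pred = nsc.predict_nsc(model, X_repl, y_repl)
        pred["probabilities"].to_csv(out / "replication_probabilities.tsv", sep="\t")
        small = nsc.smallest_gene_set_report(model, X_repl, y_repl,
                                             config.classifier.error_ceiling)
        report["classifier"] = {
            "chosen_delta": round(model.chosen_delta, 4),
            "n_active_genes": len(model.active_genes),
            "cv_error_at_chosen": round(float(model.cv_errors.min()), 4),
            "replication_misclassification": round(pred["misclassification"], 4),
            "replication_sensitivity": round(pred["sensitivity"], 4),
            "replication_specificity": round(pred["specificity"], 4),
            "smallest_gene_set": {
                "qualified": small["qualified"],
                "n_genes": len(small["genes"]),
                "misclassification": round(small.get("misclassification",
                                                     float("nan")), 4)
                if small["qualified"] else None,
            },
        }
        done("classify", t0)
    except Exception as exc:
        logger.exception("pipeline failed")
        raise RuntimeError(f"pipeline stage failed: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()

    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    (out / "report.txt").write_text(_render_report(report))
    return report


def _render_report(report: dict) -> str:
    lines = ["coexdiff pipeline report", "=" * 24, ""]
    q = report.get("qc", {})
    lines.append(f"samples retained: {q.get('n_samples_retained')} "
                 f"(excluded {len(q.get('excluded_samples', []))})")
    lines.append(f"probes retained: {q.get('n_probes_retained')} "
                 f"(excluded {len(q.get('excluded_probes', []))})")
    s = report.get("split", {})
    if s:
        lines.append(f"discovery: {s['discovery']['cases']} cases / "
                     f"{s['discovery']['controls']} controls; replication: "
                     f"{s['replication']['cases']} / {s['replication']['controls']}")
    de = report.get("de", {})
    lines.append(f"DE probes FDR<0.05 in discovery: "
                 f"{de.get('n_discovery_fdr_significant')}; replicated: "
                 f"{de.get('n_replicated')}")
    lines.append(f"co-expression modules: {report.get('coexpression', {}).get('n_modules')}")
    dc = report.get("dc", {})
    lines.append(f"DC modules: {dc.get('n_modules')}; significant: "
                 f"{dc.get('significant_modules', [])}; preserved: "
                 f"{dc.get('preserved_significant_modules', [])}")
    for m, h in report.get("hubs", {}).items():
        lines.append(f"hubs[{m}]: {h['n_hubs']} hub genes; top10 {h['top10']}")
    c = report.get("classifier", {})
    if c:
        lines.append(
            f"classifier: delta {c['chosen_delta']}, {c['n_active_genes']} active "
            f"genes; replication misclassification {c['replication_misclassification']}"
            f" (sens {c['replication_sensitivity']}, spec {c['replication_specificity']})")
    return "\n".join(lines) + "\n"
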