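"""End-to-end orchestration: simulate -> filter -> model comparison ->
signature -> network -> enrichment -> cell-line validation.

A single YAML config drives every stage; one global seed deterministically
derives per-stage seeds (stage-name hashing) so stages are independently
reproducible. Every stage writes its artifacts under the output directory
and registers them in a JSON run manifest; a rerun with the same config
and seed is byte-identical for the deterministic summary tables.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synthdata
from .cohort import FilterConfig, filter_drugs, modality_correlation
from .enrichment import enrich_kinases, enrich_sets
from .io_formats import (
    read_drug_response,
    read_edgelist,
    read_gmt,
    read_ks,
    read_matrix,
    write_drug_response,
    write_edgelist,
    write_gmt,
    write_ks,
    write_matrix,
    MODALITIES,
    MultiOmicCohort,
)
from .models import (
    ALLOWED_COMBOS,
    CVConfig,
    ModelSpec,
    assemble_features,
    compare_models,
    extract_signature,
    summarize_comparison,
)
from .network import (
    PCSFConfig,
    assign_prizes,
    build_augmented_graph,
    export_consensus,
    randomized_pcsf,
)
from .validation import (
    cluster_signature,
    resistance_stage_proximity,
    separation_score,
    to_newick,
)

log = logging.getLogger("amlsig")

STAGES = ("simulate", "filter", "compare", "signature", "network", "enrich", "validate")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r}: {message}")


def stage_seed(global_seed: int, stage: str) -> int:
    """Per-stage seed derived from the global seed by stage-name hashing."""
    return (int(global_seed) ^ zlib.crc32(stage.encode())) % (2**31)


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (see ``default_config``)."""

    seed: int
    outdir: str
    cohort: dict | None = None
    cohort_paths: dict | None = None
    response_path: str | None = None
    network_gen: dict = field(default_factory=dict)
    ppi_path: str | None = None
    ks_path: str | None = None
    gmt_path: str | None = None
    annotations: dict = field(default_factory=dict)
    filter: dict = field(default_factory=dict)
    models: dict = field(default_factory=dict)
    pcsf: dict = field(default_factory=dict)
    enrichment: dict = field(default_factory=dict)
    validation: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("config must set a seed")
        if self.cohort is None and self.cohort_paths is None:
            raise ValueError("config needs either a synthetic 'cohort' block or 'cohort_paths'")
        if self.cohort_paths is not None and self.response_path is None:
            raise ValueError("cohort_paths requires response_path (drug table)")
        for key in ("cohort_paths", "response_path", "ppi_path", "ks_path", "gmt_path"):
            val = getattr(self, key)
            paths = val.values() if isinstance(val, dict) else [val] if val else []
            for p in paths:
                if p and not Path(p).exists():
                    raise ValueError(f"{key}: path {p!r} does not exist")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "seed" not in raw or "outdir" not in raw:
            raise ValueError("config must set 'seed' and 'outdir'")
        return cls(**raw)


def default_config(outdir: str, seed: int = 0) -> PipelineConfig:
    """The default synthetic study: a 38-sample cohort with planted
    protein-level drug signatures, a modest interaction network, and
    parental/early/late cell lines.

    Cohort statistics follow the generator defaults (AUC range, weak
    cross-modality correlations); gene and drug counts are sized for a
    desk-scale run.
    """
    return PipelineConfig(
        seed=seed,
        outdir=outdir,
        cohort={"n_samples": 38, "n_genes": 30, "n_drugs": 3, "signature_size": 5},
        network_gen={"edge_density": 0.08, "kinase_fraction": 0.15,
                     "site_annotation_fraction": 0.2},
        annotations={"n_sets": 25, "set_size": [5, 15]},
        models={"families": ["lasso", "elasticnet", "logistic"],
                "combos": "all",
                "logistic_combos": [["protein"], ["protein", "phosphosite"]],
                "outer_k": 5, "n_lambda": 20},
        pcsf={"beta": 2.0, "n_randomizations": 25, "noise_delta": 0.05,
              "consensus_fraction": 0.5},
        enrichment={"q_threshold": 0.01},
        validation={"n_per_group": 4, "shift_late": 3.0, "shift_early": 1.5, "k": 2},
    )


def _specs_from_config(mcfg: dict) -> list[ModelSpec]:
    families = mcfg.get("families", ["lasso", "elasticnet", "logistic"])
    combos = mcfg.get("combos", "all")
    if combos == "all":
        combos = [list(c) for c in ALLOWED_COMBOS]
    specs = []
    for f in families:
        fam_combos = combos
        if f == "logistic" and "logistic_combos" in mcfg:
            fam_combos = mcfg["logistic_combos"]
        specs.extend(ModelSpec(family=f, modalities=tuple(c)) for c in fam_combos)
    return specs


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in order; returns (and writes) the run manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": [], "artifacts": {}}

    def record(stage: str, artifacts: dict, summary: dict | None = None) -> None:
        manifest["stages"].append(stage)
        manifest["artifacts"][stage] = {k: str(v) for k, v in artifacts.items()}
        if summary:
            manifest["artifacts"][stage]["summary"] = summary
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)

    def fail(stage: str, exc: Exception):
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)
        raise PipelineError(stage, str(exc)) from exc

    # -- simulate / load ---------------------------------------------------
    stage = "simulate"
    try:
        if config.cohort_paths is not None:
            matrices = {
                m: read_matrix(p, m) for m, p in config.cohort_paths.items()
            }
            cohort = MultiOmicCohort(matrices=matrices)
            response = read_drug_response(config.response_path)
            truth = None
        else:
            ccfg = synthdata.CohortConfig(
                seed=stage_seed(config.seed, "simulate"), **(config.cohort or {})
            )
            cohort, response, truth = synthdata.generate_cohort(ccfg)
        arts = {}
        for m in cohort.modalities:
            p = out / f"{m}.tsv"
            write_matrix(cohort[m], p)
            arts[m] = p
        write_drug_response(response, out / "auc.tsv")
        arts["auc"] = out / "auc.tsv"
        if truth is not None:
            truth.to_json(out / "ground_truth.json")
            arts["ground_truth"] = out / "ground_truth.json"
        if config.ppi_path:
            ppi, ks = read_edgelist(config.ppi_path), read_ks(config.ks_path)
        else:
            genes = cohort["protein"].features
            ppi, ks = synthdata.generate_network(
                n_proteins=len(genes),
                genes=genes,
                sites=cohort["phosphosite"].features if "phosphosite" in cohort else None,
                seed=stage_seed(config.seed, "network_gen"),
                **config.network_gen,
            )
        write_edgelist(ppi, out / "ppi.tsv")
        write_ks(ks, out / "kinase_substrate.tsv")
        arts["ppi"], arts["ks"] = out / "ppi.tsv", out / "kinase_substrate.tsv"
        if config.gmt_path:
            gene_sets = read_gmt(config.gmt_path)
        else:
            acfg = dict(config.annotations)
            if "set_size" in acfg:
                acfg["set_size"] = tuple(acfg["set_size"])
            gene_sets = synthdata.generate_annotations(
                genes=cohort["protein"].features,
                seed=stage_seed(config.seed, "annotations"),
                **acfg,
            )
        write_gmt(gene_sets, out / "gene_sets.gmt")
        arts["gene_sets"] = out / "gene_sets.gmt"
        # cohort-level correlation summary
        corr = {}
        if "transcript" in cohort and "protein" in cohort:
            corr["mrna_protein_pooled"] = modality_correlation(
                cohort["transcript"], cohort["protein"], level="pooled"
            ).pooled
        if "phosphosite" in cohort and "protein" in cohort:
            corr["site_protein_pooled"] = modality_correlation(
                cohort["phosphosite"], cohort["protein"], level="pooled"
            ).pooled
        record(stage, arts, summary=corr)
        log.info("simulate: %d samples, %d drugs", len(cohort.samples), len(response.drugs))
    except Exception as exc:  # noqa: BLE001
        fail(stage, exc)

    # -- filter ------------------------------------------------------------
    stage = "filter"
    try:
        fcfg = FilterConfig(**config.filter)
        drugs = filter_drugs(response, fcfg)
        if not drugs:
            raise ValueError("no drugs pass the sensitivity filter")
        (out / "retained_drugs.txt").write_text("\n".join(drugs) + "\n")
        record(stage, {"retained_drugs": out / "retained_drugs.txt"},
               summary={"n_retained": len(drugs)})
        log.info("filter: retained %d/%d drugs", len(drugs), len(response.drugs))
    except Exception as exc:  # noqa: BLE001
        fail(stage, exc)

    # -- compare -----------------------------------------------------------
    stage = "compare"
    try:
        mcfg = config.models
        specs = _specs_from_config(mcfg)
        cv = CVConfig(
            outer_k=mcfg.get("outer_k", 5),
            seed=stage_seed(config.seed, "compare"),
            n_lambda=mcfg.get("n_lambda", 50),
        )
        table = compare_models(cohort, response, drugs, specs, cv,
                               auc_threshold=config.filter.get("auc_threshold", 100.0))
        table.to_csv(out / "model_comparison.tsv", sep="\t", index=False)
        med = summarize_comparison(table)
        med["by_family"].to_csv(out / "median_by_family.tsv", sep="\t")
        med["by_modalities"].to_csv(out / "median_by_modalities.tsv", sep="\t")
        record(stage, {"comparison": out / "model_comparison.tsv",
                       "by_family": out / "median_by_family.tsv",
                       "by_modalities": out / "median_by_modalities.tsv"},
               summary={"n_models": int(len(table)),
                        "n_excluded": int(table["excluded"].sum())})
        log.info("compare: %d model rows, %d excluded", len(table), table["excluded"].sum())
    except Exception as exc:  # noqa: BLE001
        fail(stage, exc)

    # -- signature ---------------------------------------------------------
    stage = "signature"
    try:
        ok = table.loc[~table["excluded"]].sort_values("mean_score", ascending=False)
        if ok.empty:
            raise ValueError("every model was excluded; no signature to extract")
        top = ok.iloc[0]
        spec = ModelSpec(family=top["family"], modalities=tuple(top["modalities"].split("+")))
        yrow = response.auc.loc[top["drug"]]
        samples = [s for s in cohort.samples if s in yrow.index and not np.isnan(yrow[s])]
        X = assemble_features(cohort, spec.modalities, samples=samples)
        y = yrow[samples].to_numpy(dtype=float)
        if spec.family == "logistic":
            from .cohort import binarize_response

            y = binarize_response(y, threshold=config.filter.get("auc_threshold", 100.0))
        signature = extract_signature(X, y, spec, drug=top["drug"], cv=cv)
        signature.to_json(out / "signature.json")
        record(stage, {"signature": out / "signature.json"},
               summary={"drug": top["drug"], "model": spec.label,
                        "n_features": len(signature.features),
                        "mean_score": float(top["mean_score"])})
        log.info("signature: %s via %s, %d features", top["drug"], spec.label,
                 len(signature.features))
    except Exception as exc:  # noqa: BLE001
        fail(stage, exc)

    # -- network -----------------------------------------------------------
    stage = "network"
    try:
        sites = cohort["phosphosite"].features if "phosphosite" in cohort else []
        graph = build_augmented_graph(ppi, ks, sites)
        prizes = assign_prizes(signature, graph)
        pcfg = PCSFConfig(seed=stage_seed(config.seed, "network"), **config.pcsf)
        forest = randomized_pcsf(graph, prizes, pcfg)
        export_consensus(forest, graph, prizes,
                         out / "consensus_edges.tsv", out / "consensus_nodes.tsv")
        record(stage, {"edges": out / "consensus_edges.tsv",
                       "nodes": out / "consensus_nodes.tsv"},
               summary={"n_consensus_nodes": forest.consensus.number_of_nodes(),
                        "objective": forest.objective})
        log.info("network: consensus of %d nodes", forest.consensus.number_of_nodes())
    except Exception as exc:  # noqa: BLE001
        fail(stage, exc)

    # -- enrich ------------------------------------------------------------
    stage = "enrich"
    try:
        qthr = config.enrichment.get("q_threshold", 0.01)
        sig_genes = sorted(
            {f for f, m, _c in signature.features if m in ("protein", "transcript", "mutation")}
            | {v for v in forest.consensus.nodes()
               if graph.graph.nodes[v]["kind"] == "protein"}
        )
        universe = cohort["protein"].features
        sets_res = enrich_sets(sig_genes, gene_sets, universe, q_threshold=qthr)
        sets_res.table.to_csv(out / "gene_set_enrichment.tsv", sep="\t", index=False)
        sel_sites = [f for f, m, _c in signature.features if m == "phosphosite"]
        site_universe = cohort["phosphosite"].features if "phosphosite" in cohort else []
        kin_res = enrich_kinases(sel_sites, ks, site_universe, q_threshold=qthr)
        kin_res.table.to_csv(out / "kinase_enrichment.tsv", sep="\t", index=False)
        record(stage, {"gene_sets": out / "gene_set_enrichment.tsv",
                       "kinases": out / "kinase_enrichment.tsv"},
               summary={"n_significant_sets": int(sets_res.table["significant"].sum())
                        if len(sets_res.table) else 0,
                        "unannotated_fraction": None
                        if kin_res.unannotated_fraction is None
                        or np.isnan(kin_res.unannotated_fraction)
                        else kin_res.unannotated_fraction})
        log.info("enrich: %d sets tested", len(sets_res.table))
    except Exception as exc:  # noqa: BLE001
        fail(stage, exc)

    # -- validate ----------------------------------------------------------
    stage = "validate"
    try:
        if truth is None:
            raise ValueError("cell-line validation requires generated ground truth")
        vcfg = dict(config.validation)
        k = vcfg.pop("k", 2)
        cells = synthdata.generate_cell_lines(
            truth, seed=stage_seed(config.seed, "validate"),
            drug=signature.drug if signature.drug in truth.signatures else None,
            **vcfg,
        )
        res = cluster_signature(cells, truth.signatures[signature.drug]
                                if signature.drug in truth.signatures
                                else signature, k=k)
        pl = cells.subset_groups(["parental", "late"])
        res_pl = cluster_signature(pl, truth.signatures.get(signature.drug, signature), k=2)
        ari = separation_score(res_pl.labels[pl.values.columns.sort_values()],
                               pl.groups[pl.values.columns.sort_values()])
        prox = resistance_stage_proximity(cells, truth.signatures.get(signature.drug, signature))
        res.labels.to_csv(out / "cluster_labels.tsv", sep="\t", header=True)
        (out / "dendrogram.nwk").write_text(to_newick(res) + "\n")
        pd.DataFrame([prox.distances]).to_csv(out / "proximity.tsv", sep="\t", index=False)
        record(stage, {"labels": out / "cluster_labels.tsv",
                       "dendrogram": out / "dendrogram.nwk",
                       "proximity": out / "proximity.tsv"},
               summary={"parental_vs_late_ari": ari,
                        "early_closer_to_parental": prox.early_closer})
        log.info("validate: parental-vs-late ARI %.2f", ari)
    except Exception as exc:  # noqa: BLE001
        fail(stage, exc)

    return manifest
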