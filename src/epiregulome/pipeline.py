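"""Pipeline orchestration: stage order, config validation, manifest.

Stage order: simulate (optional) / preprocess -> modules -> differential
coexpression + conservation -> enrichment -> regulator prediction ->
regulomes -> sample structure -> report.  Every stochastic step derives its
stream from the config seed (permutation streams are additionally namespaced
per module), so rerunning the same config reproduces all outputs
bit-identically, independent of thread count.
"""

from __future__ import annotations

import concurrent.futures
import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import coex, craft, discovery, enrich, io, preprocess, regulome, simulate, structure
from .exceptions import CohortSizeError, ConfigError

logger = logging.getLogger("epiregulome.pipeline")

STAGE_DEFAULTS: dict[str, dict] = {
    "preprocess": {"min_count": 6, "min_fraction": 0.20, "per_cohort": "all"},
    "modules": {
        "beta": 6.0,
        "k_max": 200,
        "junk_fraction": 0.50,
        "mad_min": 0.25,
        "k_policy": "per_iteration",
        "min_samples": discovery.MIN_COHORT_SAMPLES,
    },
    "dcx": {"n_perm": 1000, "alpha": 0.05},
    "enrich": {},
    "craft": {"min_targets": 3},
    "regulome": {"alpha": 0.05, "cross_cohort_ii_min": 0.3, "k_cap": 40},
    "structure": {"n_pcs": 5, "a_score": False},
}


def validate_config(config: dict) -> dict:
    """Fill stage defaults and check referenced files before any stage runs."""
    cfg = dict(config)
    cfg.setdefault("seed", 0)
    if not isinstance(cfg["seed"], int):
        raise ConfigError("seed must be an integer")
    for stage, defaults in STAGE_DEFAULTS.items():
        block = dict(defaults)
        block.update(cfg.get(stage) or {})
        cfg[stage] = block
    inputs = cfg.get("inputs") or {}
    if "simulate" not in cfg:
        for key in ("counts", "metadata"):
            if key not in inputs:
                raise ConfigError(f"inputs.{key} required when no simulate block is given")
        for key, path in inputs.items():
            if not Path(path).exists():
                raise ConfigError(f"inputs.{key}: file not found: {path}")
        if cfg.get("run_craft", True) and "kb" not in inputs:
            raise ConfigError("regulator prediction enabled but inputs.kb missing")
    cfg["inputs"] = inputs
    return cfg


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict, outdir, threads: int = 1) -> dict:
    """Run all stages; returns the manifest (also written to manifest.json).

    On stage failure, partial outputs are kept and a FAILED marker names the
    failing stage.
    """
    cfg = validate_config(config)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "pipeline.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    logging.getLogger("epiregulome").addHandler(fh)
    seed = cfg["seed"]
    manifest: dict = {"config_hash": _config_hash(cfg), "seed": seed, "outputs": {}}

    def record(name: str, path: Path, n_rows: int) -> None:
        manifest["outputs"][name] = {
            "path": path.name,
            "sha256": _sha256(path),
            "n_rows": int(n_rows),
        }

    current_stage = "setup"
    try:
        # ---- simulate / load inputs ----------------------------------
        truth = None
        genesets = None
        kb_edges = None
        if "simulate" in cfg:
            current_stage = "simulate"
            sim = dict(cfg["simulate"])
            n_decoy_tfs = sim.pop("n_decoy_tfs", 0)
            n_decoy_cmps = sim.pop("n_decoy_cmps", 0)
            n_decoy_sets = sim.pop("n_decoy_sets", 0)
            sim_cfg = simulate.make_config(seed=seed, **sim)
            counts, meta, truth = simulate.generate_cohorts(sim_cfg)
            io.write_counts(counts, out / "counts.tsv")
            io.write_metadata(meta, out / "metadata.tsv")
            (out / "ground_truth.json").write_text(truth.to_json())
            record("counts", out / "counts.tsv", counts.shape[0])
            record("metadata", out / "metadata.tsv", meta.shape[0])
            record("ground_truth", out / "ground_truth.json", len(truth.gene_ids))
            if truth.regulator_map or n_decoy_tfs:
                kb_edges = simulate.generate_knowledge_base(
                    truth, n_decoy_tfs=n_decoy_tfs, n_decoy_cmps=n_decoy_cmps, seed=seed
                )
                io.write_kb(kb_edges, out / "knowledge_base.tsv")
                record("knowledge_base", out / "knowledge_base.tsv", kb_edges.shape[0])
            if truth.pathway_map or n_decoy_sets:
                genesets = simulate.generate_genesets(
                    truth, n_decoy_sets=n_decoy_sets, seed=seed
                )
                io.write_gmt(genesets, out / "genesets.gmt")
                record("genesets", out / "genesets.gmt", len(genesets))
        else:
            counts = io.read_counts(cfg["inputs"]["counts"])
            meta = io.read_metadata(cfg["inputs"]["metadata"], counts=counts)
            if "genesets" in cfg["inputs"]:
                genesets = io.read_gmt(cfg["inputs"]["genesets"])
            if "kb" in cfg["inputs"]:
                kb_edges = io.read_kb(cfg["inputs"]["kb"])

        # ---- preprocess ----------------------------------------------
        current_stage = "preprocess"
        study = preprocess.preprocess_study(counts, meta, **cfg["preprocess"])
        expr_path = out / "expression.tsv"
        study.expr.to_csv(expr_path, sep="\t", index_label="gene_id", float_format="%.6f")
        record("expression", expr_path, study.expr.shape[0])

        # ---- modules -------------------------------------------------
        current_stage = "modules"
        module_sets: dict[str, discovery.ModuleSet] = {}
        for cohort in study.cohorts:
            d_samples = study.cohort_samples(cohort, "disease")
            c_samples = study.cohort_samples(cohort, "control")
            if not d_samples or not c_samples:
                continue
            try:
                ms = discovery.discover_modules(
                    study.expr[d_samples],
                    study.expr[c_samples],
                    cohort,
                    **cfg["modules"],
                )
            except CohortSizeError as exc:
                logger.warning("skipping cohort %s: %s", cohort, exc)
                continue
            module_sets[cohort] = ms
        mod_rows = [
            {"module_id": m.module_id, "gene_id": g, "stability": s}
            for ms in module_sets.values()
            for m in ms.modules
            for g, s in zip(m.genes, m.stability or [float("nan")] * len(m.genes))
        ]
        mod_df = pd.DataFrame(mod_rows, columns=["module_id", "gene_id", "stability"])
        io.write_table(mod_df, out / "modules.tsv")
        record("modules", out / "modules.tsv", mod_df.shape[0])
        summary = pd.DataFrame(
            [
                {
                    "module_id": m.module_id,
                    "cohort": ms.cohort,
                    "n_genes": len(m.genes),
                    "suffix": m.suffix,
                    "k_selected": ms.k_selected,
                }
                for ms in module_sets.values()
                for m in ms.modules
            ]
        )
        io.write_table(summary, out / "module_summary.tsv")
        record("module_summary", out / "module_summary.tsv", summary.shape[0])

        # ---- differential coexpression + conservation ----------------
        current_stage = "dcx"
        dcx_cfg = cfg["dcx"]
        all_modules = [
            m for ms in module_sets.values() for m in ms.modules if len(m.genes) >= 2
        ]

        def _dc(m: discovery.GeneModule) -> coex.CoexStat:
            return coex.diff_coexpression_test(
                m,
                study.expr[study.cohort_samples(m.cohort, "disease")],
                study.expr[study.cohort_samples(m.cohort, "control")],
                n_perm=dcx_cfg["n_perm"],
                seed=seed,
            )

        if threads > 1:
            with concurrent.futures.ThreadPoolExecutor(max_workers=threads) as pool:
                stats = list(pool.map(_dc, all_modules))
        else:
            stats = [_dc(m) for m in all_modules]
        coex_stats = {s.module_id: s for s in stats}
        dc_df = pd.DataFrame([asdict(s) for s in stats])
        if not dc_df.empty:
            dc_df["fdr_bh"] = enrich.bh_fdr(dc_df["p_empirical"].to_numpy())
        io.write_table(dc_df, out / "coex_stats.tsv")
        record("coex_stats", out / "coex_stats.tsv", dc_df.shape[0])

        cons_calls: dict[str, list[coex.ConservationCall]] = {}
        cons_rows = []
        for m in all_modules:
            for cohort in study.cohorts:
                c_samples = study.cohort_samples(cohort, "control")
                if len(c_samples) < 4:
                    continue
                try:
                    call = coex.conservation_test(
                        m,
                        study.expr[c_samples],
                        target_cohort=f"{cohort}_control",
                        n_perm=dcx_cfg["n_perm"],
                        seed=seed,
                        alpha=dcx_cfg["alpha"],
                    )
                except Exception as exc:  # unmappable module: report, don't abort
                    logger.warning("conservation %s vs %s: %s", m.module_id, cohort, exc)
                    continue
                cons_calls.setdefault(m.module_id, []).append(call)
                cons_rows.append(asdict(call))
        cons_df = pd.DataFrame(cons_rows)
        io.write_table(cons_df, out / "conservation.tsv")
        record("conservation", out / "conservation.tsv", cons_df.shape[0])

        # ---- enrichment ----------------------------------------------
        current_stage = "enrich"
        universe = set(study.gene_ids)
        enr_df = pd.DataFrame()
        if genesets:
            queries = {m.module_id: m.gene_set for m in all_modules}
            if queries:
                enr_df = enrich.annotate(queries, {"pathways": genesets}, universe)
        io.write_table(enr_df, out / "enrichment.tsv")
        record("enrichment", out / "enrichment.tsv", enr_df.shape[0])

        # ---- regulator prediction ------------------------------------
        current_stage = "craft"
        pred_df = pd.DataFrame()
        if kb_edges is not None and all_modules:
            kb = craft.KnowledgeBase.from_edges(kb_edges)
            kb = craft.restrict_to_expressed(kb, universe)
            pred_df = craft.predict_regulators(
                all_modules, kb, universe, min_targets=cfg["craft"]["min_targets"]
            )
        io.write_table(pred_df, out / "predictions.tsv")
        record("predictions", out / "predictions.tsv", pred_df.shape[0])

        # ---- regulomes -----------------------------------------------
        current_stage = "regulome"
        reg_rows = []
        if len(all_modules) >= 3:
            module_genes = {m.module_id: m.gene_set for m in all_modules}
            module_cohorts = {m.module_id: m.cohort for m in all_modules}
            regulomes = regulome.build_regulomes(
                module_genes,
                module_cohorts,
                coex_stats,
                cons_calls,
                predictions=pred_df if not pred_df.empty else None,
                **cfg["regulome"],
            )
            for r in regulomes:
                for mid in r.member_modules:
                    reg_rows.append(
                        {
                            "regulome_id": r.regulome_id,
                            "module_id": mid,
                            "cohort": r.member_cohorts[mid],
                            "class": r.label,
                            "n_intersect_genes": len(r.intersect_genes),
                            "shared_regulators": ";".join(r.shared_regulators),
                        }
                    )
        reg_df = pd.DataFrame(
            reg_rows,
            columns=[
                "regulome_id", "module_id", "cohort", "class",
                "n_intersect_genes", "shared_regulators",
            ],
        )
        io.write_table(reg_df, out / "regulomes.tsv")
        record("regulomes", out / "regulomes.tsv", reg_df.shape[0])

        # ---- sample structure ----------------------------------------
        current_stage = "structure"
        st_cfg = cfg["structure"]
        labels = study.sample_meta.loc[list(study.expr.columns), "cohort"]
        if labels.nunique() >= 2:
            n_pcs = min(
                st_cfg["n_pcs"], study.expr.shape[1] - labels.nunique() - 1
            )
            dres = structure.dapc(study.expr, labels, max(1, n_pcs))
            dres.reassignment.to_csv(out / "reassignment.tsv", sep="\t")
            dres.posterior.to_csv(
                out / "posterior.tsv", sep="\t", index_label="sample_id",
                float_format="%.6f",
            )
            record("reassignment", out / "reassignment.tsv", dres.reassignment.shape[0])
            record("posterior", out / "posterior.tsv", dres.posterior.shape[0])
        else:
            logger.info("single cohort: skipping DAPC stage")

        # ---- report --------------------------------------------------
        current_stage = "report"
        rep_rows = []
        for cohort, ms in module_sets.items():
            mids = [m.module_id for m in ms.modules]
            n_dc = sum(
                1 for mid in mids
                if mid in coex_stats and coex_stats[mid].p_empirical < dcx_cfg["alpha"]
            )
            n_annot = (
                enr_df[(enr_df["query_id"].isin(mids)) & (enr_df["fdr"] < 0.05)][
                    "query_id"
                ].nunique()
                if not enr_df.empty
                else 0
            )
            n_reg = (
                pred_df[(pred_df["module_id"].isin(mids)) & (pred_df["fdr"] < 0.05)][
                    "regulator_id"
                ].nunique()
                if not pred_df.empty
                else 0
            )
            rep_rows.append(
                {
                    "cohort": cohort,
                    "n_modules": len(mids),
                    "n_dc_modules": n_dc,
                    "n_annotated_modules": int(n_annot),
                    "n_regulators": int(n_reg),
                }
            )
        rep_df = pd.DataFrame(
            rep_rows,
            columns=["cohort", "n_modules", "n_dc_modules", "n_annotated_modules", "n_regulators"],
        )
        io.write_table(rep_df, out / "report.tsv")
        record("report", out / "report.tsv", rep_df.shape[0])

    except Exception:
        (out / "FAILED").write_text(f"stage: {current_stage}\n")
        logger.exception("pipeline failed at stage %s", current_stage)
        raise
    finally:
        logging.getLogger("epiregulome").removeHandler(fh)
        fh.close()

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
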