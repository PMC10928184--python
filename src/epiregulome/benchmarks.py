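"""Planted-structure validation experiments.

Each function generates synthetic data with known ground truth, runs the
relevant pipeline stage(s), and measures recovery or calibration.  They back
both the test suite and the reproduction script, so the study conditions
(sample sizes, module sizes, planted effect sizes) are defined in exactly
one place.
"""

from __future__ import annotations

import hashlib
import json
from fractions import Fraction
from itertools import combinations
from math import comb
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import coex, craft, discovery, enrich, preprocess, regulome, simulate

__all__ = [
    "module_recovery",
    "recovery_ari",
    "dc_null_calibration",
    "dc_power",
    "craft_recovery",
    "regulome_class_recovery",
    "hypergeom_oracle_error",
    "inclusion_index_oracle_error",
    "pipeline_determinism",
]


def recovery_ari(module_set: discovery.ModuleSet, truth: simulate.GroundTruth) -> float:
    """Adjusted Rand index between discovered and planted module labels,
    evaluated over the planted module genes (genes lost to junk or left
    unassigned count as one extra label)."""
    pred = {g: m.module_id for m in module_set.modules for g in m.genes}
    planted = sorted(truth.module_assignments)
    a = [truth.module_assignments[g] for g in planted]
    b = [pred.get(g, "__unassigned__") for g in planted]
    return float(adjusted_rand_score(a, b))


def module_recovery(
    n_runs: int = 20,
    seed: int = 0,
    module_sizes=(25, 33, 41, 50),
    n_background: int = 200,
    r2_disease: float = 0.7,
    r2_control: float = 0.1,
    n_samples: int = 30,
    ari_min: float = 0.8,
) -> dict:
    """Full discovery pipeline on planted cohorts; fraction of runs with
    ARI >= ``ari_min`` against the planted partition."""
    aris = []
    for rep in range(n_runs):
        cfg = simulate.make_config(
            n_genes=sum(module_sizes) + n_background,
            cohorts=[("A", n_samples, n_samples)],
            module_sizes=list(module_sizes),
            r2_disease=r2_disease,
            r2_control=r2_control,
            seed=simulate.stable_seed(seed, f"recovery{rep}"),
        )
        counts, meta, truth = simulate.generate_cohorts(cfg)
        study = preprocess.preprocess_study(counts, meta)
        d = study.cohort_samples("A", "disease")
        c = study.cohort_samples("A", "control")
        ms = discovery.discover_modules(study.expr[d], study.expr[c], "A")
        aris.append(recovery_ari(ms, truth))
    aris_arr = np.array(aris)
    return {
        "rate": float((aris_arr >= ari_min).mean()),
        "median_ari": float(np.median(aris_arr)),
        "aris": aris,
        "n": n_runs,
    }


def dc_null_calibration(
    n_modules: int = 200,
    module_size: int = 10,
    n_per_arm: int = 20,
    n_perm: int = 500,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Type-I error of the differential-coexpression test: both arms drawn
    from the same (structureless) distribution; rejection rate at ``alpha``."""
    cfg = simulate.make_config(
        n_genes=n_modules * module_size,
        cohorts=[("A", n_per_arm, n_per_arm)],
        module_sizes=[],
        seed=simulate.stable_seed(seed, "dc_null"),
    )
    counts, meta, truth = simulate.generate_cohorts(cfg)
    study = preprocess.preprocess_study(counts, meta, min_count=0)
    d = study.cohort_samples("A", "disease")
    c = study.cohort_samples("A", "control")
    genes = list(study.expr.index)
    rejections = 0
    for i in range(n_modules):
        block = genes[i * module_size:(i + 1) * module_size]
        stat = coex.diff_coexpression_test(
            block, study.expr[d], study.expr[c], n_perm=n_perm, seed=seed,
            module_id=f"null.{i}",
        )
        rejections += stat.p_empirical < alpha
    return {"rate": rejections / n_modules, "n": n_modules}


def dc_power(
    n_replicates: int = 100,
    module_size: int = 30,
    n_per_arm: int = 30,
    delta: float = 0.5,
    r2_control: float = 0.1,
    n_perm: int = 500,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Power of the DC test under a planted difference in median R^2."""
    hits = 0
    for rep in range(n_replicates):
        # module must be a small fraction of the universe, else library-size
        # normalization itself dampens the planted coexpression
        cfg = simulate.make_config(
            n_genes=module_size + 470,
            cohorts=[("A", n_per_arm, n_per_arm)],
            module_sizes=[module_size],
            r2_disease=r2_control + delta,
            r2_control=r2_control,
            seed=simulate.stable_seed(seed, f"dc_power{rep}"),
        )
        counts, meta, truth = simulate.generate_cohorts(cfg)
        study = preprocess.preprocess_study(counts, meta, min_count=0)
        d = study.cohort_samples("A", "disease")
        c = study.cohort_samples("A", "control")
        stat = coex.diff_coexpression_test(
            list(truth.module_genes["M1"]), study.expr[d], study.expr[c],
            n_perm=n_perm, seed=seed, module_id=f"power.{rep}",
        )
        hits += stat.p_empirical < alpha
    return {"rate": hits / n_replicates, "n": n_replicates}


def craft_recovery(
    n_replicates: int = 100,
    n_decoys: int = 50,
    module_size: int = 30,
    n_genes: int = 2000,
    seed: int = 0,
) -> dict:
    """Planted-regulator recovery: fraction of replicates in which the
    planted TF attains the best FDR for its module among 50 decoy TFs."""
    hits = 0
    for rep in range(n_replicates):
        rep_seed = simulate.stable_seed(seed, f"craft{rep}")
        cfg = simulate.make_config(
            n_genes=n_genes,
            cohorts=[("A", 3, 3)],
            module_sizes=[module_size],
            with_regulators=True,
            seed=rep_seed,
        )
        # only the planted layout is needed: build truth without count simulation
        modules = cfg.modules
        truth = simulate.GroundTruth(
            gene_ids=tuple(
                [g for m in modules for g in m.genes]
                + [f"bg_g{j:05d}" for j in range(n_genes - module_size)]
            ),
            module_assignments={g: m.module_id for m in modules for g in m.genes},
            module_targets={m.module_id: (m.r2_disease, m.r2_control) for m in modules},
            module_genes={m.module_id: m.genes for m in modules},
            module_directions={
                m.module_id: dict(zip(m.genes, m.gene_directions)) for m in modules
            },
            module_cohorts={m.module_id: ("A",) for m in modules},
            regulator_map={"TF_M1": ("M1", "activation")},
        )
        kb_edges = simulate.generate_knowledge_base(
            truth, n_decoy_tfs=n_decoys, seed=rep_seed
        )
        kb = craft.KnowledgeBase.from_edges(kb_edges)
        module = discovery.GeneModule("A.1.o", "A", truth.module_genes["M1"])
        pred = craft.predict_regulators(module, kb, truth.gene_ids)
        tf_rows = pred[pred["regulator_class"].isin(["TF", "miRNA"])]
        best = tf_rows["fdr"].min()
        planted_fdr = tf_rows.loc[tf_rows["regulator_id"] == "TF_M1", "fdr"]
        hits += (not planted_fdr.empty) and float(planted_fdr.iloc[0]) <= best + 1e-300
    return {"rate": hits / n_replicates, "n": n_replicates}


# -- regulome classification -------------------------------------------------

_ARCHETYPES = {
    # class -> (r2_disease, r2_control, cohorts)
    "constitutive": (0.60, 0.60, None),
    "enhanced": (0.75, 0.35, None),
    "activated": (0.70, 0.00, None),
    "pathology_specific": (0.70, 0.00, ("A",)),
}


def _archetype_config(seed: int, module_size: int, n_per_arm: int) -> simulate.SimConfig:
    modules = []
    for i, (label, (r2d, r2c, cohorts)) in enumerate(_ARCHETYPES.items(), start=1):
        mid = f"M{i}_{label}"
        modules.append(
            simulate.PlantedModule(
                module_id=mid,
                genes=tuple(f"{mid}_g{j:03d}" for j in range(module_size)),
                r2_disease=r2d,
                r2_control=r2c,
                cohorts=cohorts,
            )
        )
    return simulate.SimConfig(
        n_genes=600,
        cohorts=(("A", n_per_arm, n_per_arm), ("B", n_per_arm, n_per_arm)),
        modules=tuple(modules),
        seed=seed,
    )


def regulome_class_recovery(
    n_replicates: int = 50,
    module_size: int = 25,
    n_per_arm: int = 25,
    n_perm_dc: int = 199,
    n_perm_cons: int = 299,
    alpha: float = 0.05,
    alpha_cons: float = 0.01,
    seed: int = 0,
) -> dict:
    """Plant one regulome archetype per activity class across two cohorts and
    check that clustering + classification recovers all four labels.

    Archetypes: constitutive (R^2 0.6 both arms), enhanced (0.75 vs 0.35,
    conserved in controls), activated (0.7 vs background), and a single-cohort
    pathology-specific module.  Conservation is judged against the pooled
    control samples at a stricter alpha (0.01): classification hinges on an
    any-member-conserved rule, so the per-test level must control the
    family-wise false-conservation rate.
    """
    hits = 0
    per_class = {c: 0 for c in _ARCHETYPES}
    for rep in range(n_replicates):
        rep_seed = simulate.stable_seed(seed, f"regulome{rep}")
        cfg = _archetype_config(rep_seed, module_size, n_per_arm)
        counts, meta, truth = simulate.generate_cohorts(cfg)
        study = preprocess.preprocess_study(counts, meta, min_count=0)
        control_pool = [
            s for s in study.expr.columns
            if study.sample_meta.loc[s, "condition"] == "control"
        ]
        module_genes: dict[str, set[str]] = {}
        module_cohorts: dict[str, str] = {}
        stats: dict[str, coex.CoexStat] = {}
        cons: dict[str, list[coex.ConservationCall]] = {}
        instance_truth: dict[str, str] = {}
        for mid, genes in truth.module_genes.items():
            for cohort in truth.module_cohorts[mid]:
                inst = f"{cohort}.{mid}.o"
                module_genes[inst] = set(genes)
                module_cohorts[inst] = cohort
                instance_truth[inst] = mid.split("_", 1)[1]
                d = study.cohort_samples(cohort, "disease")
                c = study.cohort_samples(cohort, "control")
                stats[inst] = coex.diff_coexpression_test(
                    list(genes), study.expr[d], study.expr[c],
                    n_perm=n_perm_dc, seed=rep_seed, module_id=inst,
                )
                cons[inst] = [
                    coex.conservation_test(
                        list(genes), study.expr[control_pool], "control",
                        n_perm=n_perm_cons, seed=rep_seed, alpha=alpha_cons,
                        module_id=inst,
                    )
                ]
        labels = regulome.cluster_modules(module_genes)
        ok = True
        found_classes = set()
        for lab in set(labels.values()):
            members = sorted(m for m, l in labels.items() if l == lab)
            true_classes = {instance_truth[m] for m in members}
            if len(true_classes) != 1:  # clustering mixed archetypes
                ok = False
                break
            predicted = regulome.classify_regulome(
                members,
                {m: module_cohorts[m] for m in members},
                stats,
                cons,
                all_module_genes=module_genes,
                module_cohorts_all=module_cohorts,
                alpha=alpha,
            )
            true_class = next(iter(true_classes))
            found_classes.add(true_class)
            if predicted != true_class:
                ok = False
                break
            per_class[true_class] += 1
        ok = ok and found_classes == set(_ARCHETYPES)
        hits += ok
    return {"rate": hits / n_replicates, "per_class": per_class, "n": n_replicates}


# -- exact oracles -----------------------------------------------------------


def hypergeom_oracle_error(max_universe: int = 12) -> dict:
    """Max |p - exact| over every hypergeometric instance with N <= 12,
    exact tail computed with rational arithmetic."""
    worst = 0.0
    count = 0
    for N in range(1, max_universe + 1):
        for K in range(N + 1):
            for n in range(N + 1):
                for k in range(min(n, K) + 1):
                    exact = Fraction(0)
                    for i in range(k, min(n, K) + 1):
                        exact += Fraction(comb(K, i) * comb(N - K, n - i), comb(N, n))
                    err = abs(enrich.hypergeom_p(k, n, K, N) - float(exact))
                    worst = max(worst, err)
                    count += 1
    return {"max_abs_error": worst, "n": count}


def inclusion_index_oracle_error(universe_size: int = 6) -> dict:
    """Max |inclusion index - brute force| over all non-empty subset pairs of
    a small universe."""
    universe = [f"g{i}" for i in range(universe_size)]
    subsets = [
        frozenset(c) for r in range(1, universe_size + 1)
        for c in combinations(universe, r)
    ]
    worst = 0.0
    count = 0
    for x in subsets:
        for y in subsets:
            brute = len([g for g in x if g in y]) / min(len(x), len(y))
            worst = max(worst, abs(regulome.inclusion_index(x, y) - brute))
            count += 1
    return {"max_abs_error": worst, "n": count}


def pipeline_determinism(workdir, seed: int = 0) -> dict:
    """Run the pipeline twice sequentially plus once with two threads on the
    same config; 1.0 iff all output hashes agree."""
    from .pipeline import run_pipeline

    cfg = {
        "seed": int(seed),
        "simulate": {
            "n_genes": 180,
            "cohorts": [["A", 22, 22]],
            "module_sizes": [20, 25],
            "r2_disease": 0.7,
            "r2_control": 0.1,
            "with_regulators": True,
            "with_pathways": True,
            "n_decoy_tfs": 10,
            "n_decoy_sets": 5,
        },
        "dcx": {"n_perm": 200},
    }
    workdir = Path(workdir)
    hashes = []
    for name, threads in (("a", 1), ("b", 1), ("c", 2)):
        manifest = run_pipeline(cfg, workdir / name, threads=threads)
        digest = hashlib.sha256(
            json.dumps(
                {k: v["sha256"] for k, v in manifest["outputs"].items()}, sort_keys=True
            ).encode()
        ).hexdigest()
        hashes.append(digest)
    return {"identical": float(len(set(hashes)) == 1), "n": len(hashes)}
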