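"""Causal-reasoning prediction of upstream regulators (CRAFT-style).

Transcription factors and miRNAs act on modules through their direct signed
target sets; cell-membrane receptor proteins (CMPs) act indirectly through
CMP -> TF -> gene canonical paths whose sign is the product of the two edge
signs.  Significance of a regulator for a module is the hypergeometric
upper-tail of the overlap between the regulator's (expressed) target set and
the module, over the expressed-gene universe, with Benjamini-Hochberg FDR
across all regulator x module tests.  Direction is the majority sign over
overlapping genes (>= 60% dominance, else ambiguous).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enrich import bh_fdr, hypergeom_p
from .exceptions import DegenerateDataError, SchemaError

logger = logging.getLogger(__name__)

__all__ = [
    "KnowledgeBase",
    "RegulatorPrediction",
    "restrict_to_expressed",
    "compose_cmp_effects",
    "predict_regulators",
]

_SIGN = {"activation": 1, "inhibition": -1}
_EFFECT = {1: "activation", -1: "inhibition"}
DIRECTION_DOMINANCE = 0.60


@dataclass
class KnowledgeBase:
    """Signed regulatory edges: TF/miRNA -> gene and CMP -> TF.

    Duplicate (regulator, target) rows with conflicting signs collapse to
    "unspecified" (curation conflicts must not silently pick a side).
    """

    tf_edges: pd.DataFrame  # regulator_id, regulator_class in {TF, miRNA}, target_id, effect
    cmp_edges: pd.DataFrame  # cmp_id, tf_id, effect
    expressed_filtered: bool = False

    @classmethod
    def from_edges(cls, edges: pd.DataFrame) -> "KnowledgeBase":
        """Build from a flat edge table (regulator_id, regulator_class,
        target_id, effect) where CMP rows target TFs."""
        required = {"regulator_id", "regulator_class", "target_id", "effect"}
        missing = required - set(edges.columns)
        if missing:
            raise SchemaError(f"knowledge base missing columns: {sorted(missing)}")
        bad_eff = set(edges["effect"]) - {"activation", "inhibition", "unspecified"}
        if bad_eff:
            raise SchemaError(f"unknown effect values: {sorted(bad_eff)}")
        bad_cls = set(edges["regulator_class"]) - {"TF", "miRNA", "CMP"}
        if bad_cls:
            raise SchemaError(f"unknown regulator classes: {sorted(bad_cls)}")
        if (edges["regulator_id"].astype(str).str.len() == 0).any() or (
            edges["target_id"].astype(str).str.len() == 0
        ).any():
            raise SchemaError("empty edge endpoint id")
        edges = _collapse_conflicts(edges)
        is_cmp = edges["regulator_class"] == "CMP"
        tf_edges = edges.loc[~is_cmp].reset_index(drop=True)
        cmp_edges = (
            edges.loc[is_cmp, ["regulator_id", "target_id", "effect"]]
            .rename(columns={"regulator_id": "cmp_id", "target_id": "tf_id"})
            .reset_index(drop=True)
        )
        return cls(tf_edges=tf_edges, cmp_edges=cmp_edges)

    def target_sets(self) -> dict[str, dict[str, str]]:
        """regulator -> {gene -> effect} for TFs/miRNAs."""
        out: dict[str, dict[str, str]] = {}
        for reg, grp in self.tf_edges.groupby("regulator_id"):
            out[str(reg)] = dict(zip(grp["target_id"], grp["effect"]))
        return out

    def regulator_classes(self) -> dict[str, str]:
        return dict(
            zip(self.tf_edges["regulator_id"], self.tf_edges["regulator_class"])
        )


def _collapse_conflicts(edges: pd.DataFrame) -> pd.DataFrame:
    dup = edges.duplicated(subset=["regulator_id", "target_id"], keep=False)
    if not dup.any():
        return edges.reset_index(drop=True)
    resolved = []
    for (reg, tgt), grp in edges.groupby(["regulator_id", "target_id"], sort=False):
        effects = set(grp["effect"])
        if len(effects) == 1:
            resolved.append(grp.iloc[0])
        else:
            logger.warning(
                "conflicting signs for edge %s -> %s collapsed to 'unspecified'", reg, tgt
            )
            row = grp.iloc[0].copy()
            row["effect"] = "unspecified"
            resolved.append(row)
    return pd.DataFrame(resolved).reset_index(drop=True)


@dataclass(frozen=True)
class RegulatorPrediction:
    regulator_id: str
    regulator_class: str
    module_id: str
    overlap: int
    target_set_size: int
    p: float
    fdr: float
    direction: str  # activates / inhibits / ambiguous


def restrict_to_expressed(kb: KnowledgeBase, expressed) -> KnowledgeBase:
    """Drop edges with any unexpressed endpoint; drop regulators left empty.

    CMP -> TF edges survive if the TF is expressed and still has targets."""
    exp = set(expressed)
    if not exp:
        raise DegenerateDataError("empty expressed gene list")
    tf = kb.tf_edges[kb.tf_edges["target_id"].isin(exp)].reset_index(drop=True)
    live_tfs = set(tf["regulator_id"])
    cmp_e = kb.cmp_edges[kb.cmp_edges["tf_id"].isin(live_tfs)].reset_index(drop=True)
    return KnowledgeBase(tf_edges=tf, cmp_edges=cmp_e, expressed_filtered=True)


def combine_signs(upstream: str, downstream: str) -> str:
    """Sign algebra for a two-edge path: product of +/- with 'unspecified'
    absorbing."""
    if "unspecified" in (upstream, downstream):
        return "unspecified"
    return _EFFECT[_SIGN[upstream] * _SIGN[downstream]]


def compose_cmp_effects(kb: KnowledgeBase) -> dict[str, dict[str, str]]:
    """Per-CMP signed gene effect sets via CMP -> TF -> gene paths.

    Per (CMP, gene): all defined path signs agree -> that sign; conflicting
    signs -> "ambiguous"; only unspecified paths -> "unspecified".
    """
    tf_targets = kb.target_sets()
    out: dict[str, dict[str, str]] = {}
    for cmp_id, grp in kb.cmp_edges.groupby("cmp_id"):
        gene_signs: dict[str, set[str]] = {}
        for _, row in grp.iterrows():
            targets = tf_targets.get(row["tf_id"], {})
            for gene, tf_eff in targets.items():
                gene_signs.setdefault(gene, set()).add(combine_signs(row["effect"], tf_eff))
        effects: dict[str, str] = {}
        for gene, signs in gene_signs.items():
            defined = signs - {"unspecified"}
            if not defined:
                effects[gene] = "unspecified"
            elif len(defined) == 1:
                effects[gene] = next(iter(defined))
            else:
                effects[gene] = "ambiguous"
        if effects:
            out[str(cmp_id)] = effects
    return out


def _direction(signs: list[str]) -> str:
    # majority sign must exceed 60% of the signed overlap (a 40% minority,
    # ties included, is a conflicted call)
    defined = [s for s in signs if s in ("activation", "inhibition")]
    if not defined:
        return "ambiguous"
    n_act = sum(1 for s in defined if s == "activation")
    frac = n_act / len(defined)
    if frac > DIRECTION_DOMINANCE:
        return "activates"
    if 1.0 - frac > DIRECTION_DOMINANCE:
        return "inhibits"
    return "ambiguous"


def predict_regulators(
    modules,
    kb: KnowledgeBase,
    universe,
    min_targets: int = 3,
) -> pd.DataFrame:
    """Regulator predictions for one module or a collection of modules.

    BH FDR is applied across all regulator x module tests of the call (the
    cohort's family of tests).  Returns a DataFrame sorted by (module, p).
    """
    uni = set(universe)
    if not uni:
        raise DegenerateDataError("empty universe")
    if hasattr(modules, "module_id"):
        modules = [modules]
    elif hasattr(modules, "modules"):
        modules = list(modules.modules)
    module_sets = {m.module_id: set(m.genes) & uni for m in modules}

    classes = kb.regulator_classes()
    reg_targets: dict[str, tuple[str, dict[str, str]]] = {}
    for reg, targets in kb.target_sets().items():
        expressed_targets = {g: e for g, e in targets.items() if g in uni}
        if len(expressed_targets) >= min_targets:
            reg_targets[reg] = (classes.get(reg, "TF"), expressed_targets)
    for cmp_id, effects in compose_cmp_effects(kb).items():
        expressed = {g: e for g, e in effects.items() if g in uni}
        if len(expressed) >= min_targets:
            reg_targets[cmp_id] = ("CMP", expressed)

    rows = []
    N = len(uni)
    for module_id, mod_genes in module_sets.items():
        n = len(mod_genes)
        for reg, (cls, targets) in sorted(reg_targets.items()):
            tset = set(targets)
            overlap = mod_genes & tset
            k = len(overlap)
            p = hypergeom_p(k, n, len(tset), N)
            direction = _direction([targets[g] for g in overlap]) if k else "ambiguous"
            rows.append(
                {
                    "regulator_id": reg,
                    "regulator_class": cls,
                    "module_id": module_id,
                    "overlap": k,
                    "target_set_size": len(tset),
                    "p": p,
                    "direction": direction,
                }
            )
    out = pd.DataFrame(rows)
    if out.empty:
        return out.assign(fdr=pd.Series(dtype=float))
    out["fdr"] = bh_fdr(out["p"].to_numpy())
    return out.sort_values(["module_id", "p", "regulator_id"], kind="stable").reset_index(
        drop=True
    )
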