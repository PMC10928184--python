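"""Synthetic multi-cohort RNA-seq studies with planted coexpression structure.

The generator emulates the design of a multi-pathology brain-tissue study:
several disease cohorts with matched controls, gene coexpression modules
driven by per-sample latent factors whose strength differs between disease
and control arms (planted differential coexpression), over-/under-expressed
gene programs, a signed CMP -> TF -> gene regulatory hierarchy, and decoy
pathway / cell-type gene sets.  Every planted feature is recorded in a
:class:`GroundTruth` object so downstream recovery can be scored.

Construction: each module owns a per-sample latent factor ``f ~ N(0,1)``.
A member gene's latent value is ``a*s*f + sqrt(1-a^2)*eps`` with ``s = +1``
for "over" genes and ``-1`` for "under" genes.  The latent layer is mapped
through an exponential mean into negative-binomial counts with lognormal
library sizes.  The loading ``a`` is calibrated in closed form so that the
median pairwise squared Spearman correlation of member genes approaches the
requested target: for a Gaussian copula the Spearman/Pearson map is
``rho_s = (6/pi) * asin(r/2)``, and the counting layer attenuates the latent
Pearson correlation by ``sigma^2 / (sigma^2 + v)`` where ``v`` approximates
the negative-binomial noise variance on the log scale.  Both maps are
invertible, giving ``a`` directly; the calibration is verified by simulation
in the test suite.
"""

from __future__ import annotations

import json
import warnings
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigError

__all__ = [
    "PlantedModule",
    "SimConfig",
    "GroundTruth",
    "generate_cohorts",
    "generate_knowledge_base",
    "generate_genesets",
    "make_config",
]

# Namespace constants offsetting the shared seed stream so that knowledge-base
# and gene-set generation never collide with the cohort stream.
_KB_NAMESPACE = 0x6B62  # "kb"
_GS_NAMESPACE = 0x6773  # "gs"

EFFECTS = ("activation", "inhibition", "unspecified")


@dataclass(frozen=True)
class PlantedModule:
    """A planted coexpression module.

    ``r2_disease`` / ``r2_control`` are the target median pairwise squared
    Spearman correlations among member genes in the two arms.  ``directions``
    marks each gene as part of the over- or under-expressed program ("over"
    genes load positively on the module factor and are shifted up in disease;
    "under" genes load negatively and are shifted down).  ``cohorts`` limits
    the module to a subset of cohorts (None = planted in every cohort).
    """

    module_id: str
    genes: tuple[str, ...]
    r2_disease: float
    r2_control: float
    directions: tuple[str, ...] | None = None
    regulator_tf: str | None = None
    regulator_sign: str = "activation"
    pathway_label: str | None = None
    cohorts: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.genes) < 2:
            raise ConfigError(f"module {self.module_id}: needs >= 2 genes")
        if len(set(self.genes)) != len(self.genes):
            raise ConfigError(f"module {self.module_id}: duplicate gene ids")
        for r2, name in ((self.r2_disease, "r2_disease"), (self.r2_control, "r2_control")):
            if not 0.0 <= r2 <= 1.0:
                raise ConfigError(f"module {self.module_id}: {name}={r2} outside [0, 1]")
        if self.directions is not None:
            if len(self.directions) != len(self.genes):
                raise ConfigError(f"module {self.module_id}: directions length mismatch")
            bad = set(self.directions) - {"over", "under"}
            if bad:
                raise ConfigError(f"module {self.module_id}: bad directions {bad}")
        if self.regulator_sign not in ("activation", "inhibition"):
            raise ConfigError(f"module {self.module_id}: bad regulator_sign")

    @property
    def gene_directions(self) -> tuple[str, ...]:
        return self.directions if self.directions is not None else ("over",) * len(self.genes)


@dataclass(frozen=True)
class SimConfig:
    """Full specification of a synthetic study.

    ``cohorts`` is a list of ``(name, n_disease, n_control)``.  Defaults give
    sequencing-depth and overdispersion values typical of bulk brain RNA-seq
    (library ~1e6 after downscaling to the simulated gene universe, CV 20%,
    NB dispersion 0.05) and a twofold disease expression shift for the
    over/under programs.
    """

    n_genes: int
    cohorts: tuple[tuple[str, int, int], ...]
    modules: tuple[PlantedModule, ...] = ()
    library_size_mean: float = 1e6
    library_size_cv: float = 0.20
    nb_dispersion: float = 0.05
    latent_sd: float = 1.0
    disease_shift: float = 0.7  # natural-log shift of over/under genes in disease
    seed: int = 0

    def __post_init__(self) -> None:
        if not isinstance(self.seed, (int, np.integer)) or isinstance(self.seed, bool):
            raise ConfigError(f"seed must be an integer, got {self.seed!r}")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be > 0")
        if self.latent_sd <= 0:
            raise ConfigError("latent_sd must be > 0")
        if not self.cohorts:
            raise ConfigError("at least one cohort required")
        for name, nd, nc in self.cohorts:
            if nd < 3 or nc < 3:
                raise ConfigError(f"cohort {name}: all sample counts must be >= 3")
        planted = [g for m in self.modules for g in m.genes]
        if len(planted) != len(set(planted)):
            raise ConfigError("planted modules share genes")
        if len(planted) > self.n_genes:
            raise ConfigError(
                f"planted module sizes ({len(planted)}) exceed n_genes ({self.n_genes})"
            )


@dataclass
class GroundTruth:
    """Record of everything the generator planted."""

    gene_ids: tuple[str, ...]
    module_assignments: dict[str, str]            # gene -> module_id
    module_targets: dict[str, tuple[float, float]]  # module_id -> (r2_disease, r2_control)
    module_genes: dict[str, tuple[str, ...]]
    module_directions: dict[str, dict[str, str]]  # module_id -> gene -> over/under
    module_cohorts: dict[str, tuple[str, ...]]    # module_id -> cohorts it is planted in
    regulator_map: dict[str, tuple[str, str]] = field(default_factory=dict)  # tf -> (module, sign)
    pathway_map: dict[str, str] = field(default_factory=dict)  # pathway -> module_id

    def to_json(self) -> str:
        payload = {
            "gene_ids": list(self.gene_ids),
            "module_assignments": self.module_assignments,
            "module_targets": {k: list(v) for k, v in self.module_targets.items()},
            "module_genes": {k: list(v) for k, v in self.module_genes.items()},
            "module_directions": self.module_directions,
            "module_cohorts": {k: list(v) for k, v in self.module_cohorts.items()},
            "regulator_map": {k: list(v) for k, v in self.regulator_map.items()},
            "pathway_map": self.pathway_map,
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            gene_ids=tuple(d["gene_ids"]),
            module_assignments=d["module_assignments"],
            module_targets={k: (v[0], v[1]) for k, v in d["module_targets"].items()},
            module_genes={k: tuple(v) for k, v in d["module_genes"].items()},
            module_directions=d["module_directions"],
            module_cohorts={k: tuple(v) for k, v in d["module_cohorts"].items()},
            regulator_map={k: (v[0], v[1]) for k, v in d["regulator_map"].items()},
            pathway_map=d["pathway_map"],
        )


def make_config(
    n_genes: int,
    cohorts: Sequence[tuple[str, int, int]],
    module_sizes: Sequence[int] = (),
    r2_disease: float | Sequence[float] = 0.7,
    r2_control: float | Sequence[float] = 0.1,
    with_regulators: bool = False,
    with_pathways: bool = False,
    seed: int = 0,
    **kwargs,
) -> SimConfig:
    """Convenience constructor: auto-names modules M1..Mk and their genes."""
    k = len(module_sizes)
    r2d = [r2_disease] * k if np.isscalar(r2_disease) else list(r2_disease)
    r2c = [r2_control] * k if np.isscalar(r2_control) else list(r2_control)
    modules = []
    for i, size in enumerate(module_sizes):
        mid = f"M{i + 1}"
        modules.append(
            PlantedModule(
                module_id=mid,
                genes=tuple(f"{mid}_g{j:03d}" for j in range(size)),
                r2_disease=r2d[i],
                r2_control=r2c[i],
                regulator_tf=f"TF_{mid}" if with_regulators else None,
                pathway_label=f"PW_{mid}" if with_pathways else None,
            )
        )
    return SimConfig(
        n_genes=n_genes, cohorts=tuple(cohorts), modules=tuple(modules), seed=seed, **kwargs
    )


def _calibrate_loading(r2_target: float, latent_sd: float, log_noise_var: float) -> float:
    """Loading magnitude giving a target median pairwise Spearman rho^2.

    Inverts the Gaussian-copula Spearman map and divides out the attenuation
    from counting noise on the log scale.  Unattainable targets (too much
    noise) are clipped to loading 1 with a warning.
    """
    if r2_target <= 0.0:
        return 0.0
    rho_s = np.sqrt(r2_target)
    r_obs = 2.0 * np.sin(np.pi * rho_s / 6.0)  # observed-scale Pearson needed
    atten = latent_sd**2 / (latent_sd**2 + log_noise_var)
    a2 = r_obs / atten
    if a2 > 1.0:
        warnings.warn(
            f"target rho^2={r2_target:.3f} unattainable under current noise; clipping loading",
            stacklevel=3,
        )
        a2 = 1.0
    return float(np.sqrt(a2))


def generate_cohorts(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate counts (genes x samples), sample metadata, and ground truth.

    Deterministic: the same config (including seed) yields byte-identical
    outputs.
    """
    rng = np.random.default_rng(config.seed)
    sigma = config.latent_sd
    phi = config.nb_dispersion

    planted_genes = [g for m in config.modules for g in m.genes]
    n_bg = config.n_genes - len(planted_genes)
    gene_ids = tuple(planted_genes + [f"bg_g{j:05d}" for j in range(n_bg)])
    n_genes = len(gene_ids)

    # Per-gene baseline abundance on the natural-log scale (lognormal across genes).
    baseline = rng.normal(loc=5.0, scale=1.0, size=n_genes)
    rel = np.exp(baseline)
    # Approximate expected count per gene at the nominal library size, used
    # only for the noise-attenuation term of the loading calibration.
    approx_count = config.library_size_mean * rel / rel.sum()

    gene_index = {g: i for i, g in enumerate(gene_ids)}

    samples: list[str] = []
    meta_rows: list[dict] = []
    cols: list[np.ndarray] = []

    # Pre-compute per-module loadings per arm.
    mod_info = []
    for m in config.modules:
        idx = np.array([gene_index[g] for g in m.genes])
        signs = np.where(np.array(m.gene_directions) == "over", 1.0, -1.0)
        mean_count = float(np.mean(approx_count[idx]))
        v = np.log1p(phi + 1.0 / max(mean_count, 1e-9))
        a_d = _calibrate_loading(m.r2_disease, sigma, v)
        a_c = _calibrate_loading(m.r2_control, sigma, v)
        mod_info.append((m, idx, signs, a_d, a_c))

    # Expected relative column total per (cohort, condition): used to scale
    # expression to the library size.  Scaling by the *expected* rather than
    # the realized total keeps the planted factor correlation intact (a
    # realized-total normalization would divide the shared factor back out).
    base_expect = np.exp(baseline + 0.5 * sigma**2)

    def _expected_total(cohort: str, condition: str) -> float:
        expect = base_expect.copy()
        if condition == "disease":
            for m, idx, signs, _a_d, _a_c in mod_info:
                if m.cohorts is not None and cohort not in m.cohorts:
                    continue
                expect[idx] *= np.exp(signs * config.disease_shift)
        return float(expect.sum())

    for cohort, n_d, n_c in config.cohorts:
        for condition, n_arm in (("disease", n_d), ("control", n_c)):
            expected_total = _expected_total(cohort, condition)
            for s in range(n_arm):
                sid = f"{cohort}_{condition[0]}{s + 1:03d}"
                samples.append(sid)
                meta_rows.append(
                    {
                        "sample_id": sid,
                        "cohort": cohort,
                        "condition": condition,
                        "tissue": "brain",
                        "age": round(float(rng.uniform(5.0, 60.0)), 1),
                        "seizure_frequency": round(float(rng.lognormal(2.0, 1.0)), 2),
                    }
                )
                x = rng.normal(size=n_genes)  # independent latent residuals
                logmu = baseline + sigma * x
                for m, idx, signs, a_d, a_c in mod_info:
                    if m.cohorts is not None and cohort not in m.cohorts:
                        continue
                    a = a_d if condition == "disease" else a_c
                    f = rng.normal()
                    logmu[idx] = baseline[idx] + sigma * (
                        a * signs * f + np.sqrt(1.0 - a * a) * x[idx]
                    )
                    if condition == "disease":
                        logmu[idx] += signs * config.disease_shift
                lib = rng.lognormal(
                    mean=np.log(config.library_size_mean)
                    - 0.5 * np.log1p(config.library_size_cv**2),
                    sigma=np.sqrt(np.log1p(config.library_size_cv**2)),
                )
                mu = np.exp(logmu) * (lib / expected_total)
                r = 1.0 / phi
                counts = rng.negative_binomial(r, r / (r + mu))
                cols.append(counts)

    counts = pd.DataFrame(
        np.column_stack(cols).astype(np.int64), index=list(gene_ids), columns=samples
    )
    counts.index.name = "gene_id"
    meta = pd.DataFrame(meta_rows).set_index("sample_id", drop=False)
    meta.index.name = None

    truth = GroundTruth(
        gene_ids=gene_ids,
        module_assignments={g: m.module_id for m in config.modules for g in m.genes},
        module_targets={m.module_id: (m.r2_disease, m.r2_control) for m in config.modules},
        module_genes={m.module_id: m.genes for m in config.modules},
        module_directions={
            m.module_id: dict(zip(m.genes, m.gene_directions)) for m in config.modules
        },
        module_cohorts={
            m.module_id: (m.cohorts if m.cohorts is not None else tuple(c[0] for c in config.cohorts))
            for m in config.modules
        },
        regulator_map={
            m.regulator_tf: (m.module_id, m.regulator_sign)
            for m in config.modules
            if m.regulator_tf is not None
        },
        pathway_map={
            m.pathway_label: m.module_id for m in config.modules if m.pathway_label is not None
        },
    )
    return counts, meta, truth


def _flip(effect: str) -> str:
    return {"activation": "inhibition", "inhibition": "activation"}.get(effect, effect)


def generate_knowledge_base(
    truth: GroundTruth,
    n_decoy_tfs: int = 0,
    n_decoy_cmps: int = 0,
    seed: int = 0,
    target_coverage: float = 0.9,
    extra_target_frac: float = 0.2,
) -> pd.DataFrame:
    """Signed regulatory edge list (regulator_id, regulator_class, target_id, effect).

    Each planted TF receives signed edges to ``target_coverage`` of its
    module's genes (>= 80% by default) plus a sprinkle of off-module targets,
    and one upstream CMP edge.  Decoy TFs/CMPs get random target sets of
    matched size.  Edge sign toward an "over" gene equals the planted
    regulator sign; toward an "under" gene it is flipped (the regulator
    drives the program, suppression included).
    """
    if not truth.gene_ids:
        raise ConfigError("empty ground truth")
    rng = np.random.default_rng([seed, _KB_NAMESPACE])
    universe = np.array(truth.gene_ids)
    rows: list[tuple[str, str, str, str]] = []
    planted_sizes: list[int] = []

    for tf, (module_id, sign) in sorted(truth.regulator_map.items()):
        genes = list(truth.module_genes[module_id])
        dirs = truth.module_directions[module_id]
        n_cov = max(2, int(np.ceil(target_coverage * len(genes))))
        chosen = list(rng.choice(genes, size=n_cov, replace=False))
        n_extra = int(round(extra_target_frac * n_cov))
        off_module = np.setdiff1d(universe, np.array(genes), assume_unique=False)
        extra = list(rng.choice(off_module, size=min(n_extra, off_module.size), replace=False))
        for g in chosen:
            effect = sign if dirs.get(g, "over") == "over" else _flip(sign)
            rows.append((tf, "TF", g, effect))
        for g in extra:
            rows.append((tf, "TF", g, str(rng.choice(EFFECTS))))
        planted_sizes.append(n_cov + len(extra))
        rows.append((f"CMP_{tf}", "CMP", tf, "activation"))

    decoy_size = int(np.median(planted_sizes)) if planted_sizes else max(
        3, len(universe) // 100
    )
    for d in range(n_decoy_tfs):
        tf = f"decoyTF_{d + 1:03d}"
        targets = rng.choice(universe, size=min(decoy_size, universe.size), replace=False)
        for g in targets:
            rows.append((tf, "TF", str(g), str(rng.choice(EFFECTS))))
    all_tfs = sorted({r[0] for r in rows if r[1] == "TF"})
    for d in range(n_decoy_cmps):
        cmp_id = f"decoyCMP_{d + 1:03d}"
        if not all_tfs:
            break
        n_down = int(rng.integers(1, min(4, len(all_tfs)) + 1))
        for tf in rng.choice(all_tfs, size=n_down, replace=False):
            rows.append((cmp_id, "CMP", str(tf), str(rng.choice(EFFECTS))))

    kb = pd.DataFrame(rows, columns=["regulator_id", "regulator_class", "target_id", "effect"])
    return kb.drop_duplicates(subset=["regulator_id", "target_id"], keep="first").reset_index(
        drop=True
    )


def generate_genesets(
    truth: GroundTruth,
    n_decoy_sets: int = 0,
    seed: int = 0,
    noise_frac: float = 0.2,
    decoy_size: int = 50,
) -> dict[str, set[str]]:
    """Gene-set collection: planted pathways (module + noise padding) + decoys."""
    if not truth.gene_ids:
        raise ConfigError("empty ground truth")
    rng = np.random.default_rng([seed, _GS_NAMESPACE])
    universe = np.array(truth.gene_ids)
    sets: dict[str, set[str]] = {}
    for pw, module_id in sorted(truth.pathway_map.items()):
        genes = set(truth.module_genes[module_id])
        n_noise = int(round(noise_frac * len(genes)))
        pool = np.setdiff1d(universe, np.array(sorted(genes)))
        noise = rng.choice(pool, size=min(n_noise, pool.size), replace=False)
        sets[pw] = genes | {str(g) for g in noise}
    for d in range(n_decoy_sets):
        members = rng.choice(universe, size=min(decoy_size, universe.size), replace=False)
        sets[f"decoySET_{d + 1:03d}"] = {str(g) for g in members}
    return sets


def stable_seed(base_seed: int, label: str) -> int:
    """Deterministic per-label seed below 2^31 (crc32 namespace mix)."""
    return int((base_seed + zlib.crc32(label.encode())) % (2**31))
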