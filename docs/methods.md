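# Methods

This note documents the models, estimators and numerical choices behind
`epiregulome`, what the synthetic-data generator does and does not emulate,
and the known limitations of each stage.

## Synthetic cohorts

Each planted module owns a per-sample standard-normal latent factor *f*. A
member gene's latent value is `a·s·f + sqrt(1−a²)·ε` with sign `s = +1` for
"over" genes and `−1` for "under" genes; background genes are pure noise.
The latent layer maps through an exponential mean (gene baselines lognormal,
log-mean 5, log-sd 1) into negative-binomial counts (default dispersion
0.05) with lognormal library sizes (default mean 10⁶, CV 0.20). "Over"
("under") genes additionally gain (lose) a natural-log shift of 0.7
(≈ twofold) in disease samples, coupling the o/u expression labeling to the
factor signs.

**Loading calibration.** The loading *a* is solved in closed form from the
target median pairwise squared Spearman correlation *t*: for a Gaussian
copula, ρ_s = (6/π)·asin(r/2), so the required observed-scale Pearson
correlation is r = 2·sin(π·√t/6); counting noise attenuates the latent
correlation by σ²/(σ²+v) with v ≈ log(1 + φ + 1/μ̄) (φ the NB dispersion,
μ̄ the module's expected mean count), giving a² = r·(σ²+v)/σ², clipped at 1
with a warning when the target is unattainable under the configured noise.
The tests verify the calibration by simulation (realized median ρ² within
±0.1 of target at 100 samples per arm) and its monotonicity in the target.

**Expected-total scaling.** Expression is scaled to the drawn library size
through the *expected* (not realized) column total of the arm. Scaling by
the realized total — like any compositional normalization — divides the
shared factor back out of the module genes and destroys the planted
correlation whenever the module is a sizeable fraction of the universe. The
same effect reappears downstream in CPM normalization, which is why
validation universes keep planted modules well under ~10% of genes, as in
real transcriptomes.

**Not emulated:** batch effects, isoform structure, gene length bias,
sample outliers, and correlated background genes. Passing recovery tests
therefore show that the estimators work when their assumptions hold, not
that real brain tissue satisfies those assumptions.

## Preprocessing

Genes are kept when ≥ 20% of samples **in every cohort** have ≥ 6 counts
(a flag switches to the weaker any-cohort rule). TMM scaling factors follow
the standard weighted trimmed-mean-of-M-values procedure — reference sample
by upper-quartile fraction closest to the mean, two-sided trims of 30% on M
and 5% on A, inverse-variance-weighted mean of the surviving M values,
factors rescaled to product 1 — and are verified in the tests against an
independent R implementation to ~10⁻⁷. Expression is
log2((count+0.5)/(lib·factor+1)·10⁶). The MAD variability filter
(raw MAD ≥ 0.25, no 1.4826 consistency constant, inclusive boundary) is
applied per cohort at discovery time.

## Module discovery

Distance for clustering is 1 − A with the signed adjacency
A = ((1+ρ)/2)^β, β = 6 (an unsigned |ρ|^β variant is available). The signed
form keeps anti-correlated genes apart so the later o/u split can separate
them. Ward clustering uses squared-distance (Ward.D2) semantics via scipy;
merge ties break deterministically by pair index.

**Choosing K.** R²(K) = 1 − WSS/TSS is evaluated on a classical-MDS
embedding of the distance matrix (non-negative eigenvalue dimensions), so
variance explained is well defined and non-decreasing in K for hierarchical
cuts; the K = n column of scipy's `cut_tree` is patched to singletons
(upstream quirk returns one cluster). K is the interior point maximizing
|R²(K+1) − 2R²(K) + R²(K−1)|. The curve is deterministic given the data, so
the default smoothing window is 1 (configurable); wider windows displace
sharp elbows by up to half the window. *Known limitation:* on concave gain
curves with very unbalanced cluster sizes, maximum curvature can sit at
small K and merge the weakest clusters; in recovery simulations this
truncates K in roughly one run in ten, and the affected modules end up in
the junk residue rather than contaminating other modules.

**Stability and junk.** One leave-one-out iteration per sample re-runs the
whole distance → adjacency → Ward → K workflow; the co-clustering fraction
matrix S is the consensus input. Per iteration, the junk cluster is the one
with the lowest mean intramodular adjacency (singletons count as 0), flagged
only if below the matrix-wide mean adjacency (the "cohesion floor",
disablable); a gene is junk when it sits in the junk cluster in ≥ 50% of
iterations (inclusive). Genes constant after a sample drop are excluded from
S with a warning. Consensus modules come from Ward on 1 − S with K
re-selected on that distance; module indices are assigned by descending
size.

**o/u split.** The module eigengene is the first principal component of the
gene-standardized disease submatrix, sign-fixed to correlate non-negatively
with the mean member profile. Genes partition by the sign of their
correlation with the eigengene; each part is suffixed `o` if its mean
disease-minus-control log2 expression is positive, else `u`. If both parts
receive the same suffix they are merged back (ids are
`{cohort}.{index}.{suffix}` and must be unique). Discovery refuses cohorts
with ≤ 20 disease samples.

## Coexpression statistics

The module statistic is the median over unordered gene pairs of the squared
Spearman correlation (Pearson available by flag). The differential test
permutes disease/control labels over the pooled samples preserving arm
sizes; the two-sided empirical p is (1 + #{|Δ*| ≥ |Δ|})/(n_perm + 1), never
zero by construction. Samples are put in a canonical order before
permuting, making p invariant to input column order; the permutation stream
is seeded per module (global seed + CRC32 of the module id, mod 2³¹), so
results do not depend on execution order or thread count.

Conservation of a module in a target cohort cannot permute a two-arm label
(there is only one cohort), so its null redraws random gene sets of the
same size from the target cohort's expressed genes; the one-sided p asks
whether the module out-coexpresses random sets. Modules need ≥ 50% of their
genes present in the target matrix.

Phenotype association is OLS of the eigengene on the covariate with a
two-sided t-test on the slope; epilepsy duration automatically adds age to
the design (the two are confounded), and the call refuses to run if age is
unavailable.

## Enrichment and upstream regulators

One hypergeometric kernel (log-space tail summation) backs both gene-set
enrichment and regulator prediction; it is tested against exact rational
enumeration for every instance with universe ≤ 12. BH FDR is applied within
a collection across all (query, set) tests of a family — the total number
of enrichment tests performed — and across all regulator × module tests for
predictions. Genes absent from the universe are dropped with a warning, not
an error (GMT collections routinely contain unmeasured genes).

Knowledge-base edges with conflicting duplicate signs collapse to
"unspecified" with a warning rather than silently picking a side. CMP
effects compose over CMP→TF→gene paths by sign product, with "unspecified"
absorbing; per (CMP, gene), agreeing defined paths give the sign,
conflicting paths give "ambiguous". CMP significance uses the full composed
gene set regardless of sign. Regulators need ≥ 3 expressed targets
(configurable); direction calls require the majority sign to exceed 60% of
the signed overlap — a 40% minority, including exact ties, is "ambiguous".

## Regulomes

Modules across cohorts are compared with the inclusion index
|x∩y| / min(|x|,|y|) and Ward-clustered on 1 − inclusion; K maximizes the
mean silhouette over K = 2…min(n−1, 40). Mutually disjoint modules have a
degenerate silhouette and fall back to singletons with a warning. Intersect
genes of a regulome are those occurring in at least one member module of
every represented cohort (single-cohort regulomes: the union).

Classification applies, in order of precedence: **pathology-specific**
(all members from one cohort, or maximum inclusion with any other-cohort
module < 0.3, and ≥ 1 member differentially coexpressed at α),
**activated** (≥ 1 member significant and no member conserved in any
control cohort), **enhanced** (≥ 1 member significant with ΔR² > 0 and
≥ 1 member conserved in controls), else **constitutive**. The precedence
order and both thresholds are configurable; the four classes are verbal
descriptions in the underlying analysis tradition and this ordering is one
defensible operationalization of them.

In the class-recovery validation study (two cohorts of 25+25, one planted
archetype per class, 25-gene modules in a 600-gene universe), conservation
for classification is judged on the pooled control samples at α = 0.01
rather than 0.05: the activated/constitutive boundary hinges on an
*any-member-conserved* rule, so the per-test level has to control the
family-wise false-conservation rate across members. Differential
coexpression stays at α = 0.05 with 199 permutations (299 for
conservation).

## Sample structure

The sample dendrogram is Ward linkage in the space of the top principal
components (those explaining ≥ 80% of variance) of gene-standardized
expression. DAPC reduces to n_pcs PCs then fits an LDA with equal priors
per cohort (cohort sizes reflect sampling, not prevalence); the posterior
membership matrix and the prior × assigned reassignment cross-tabulation
are reported. The a-score for choosing n_pcs is observed reassignment
minus the mean reassignment over 10 random relabelings, penalizing the
overfitting that drives reassignment toward 1 as n_pcs approaches the
sample count.

## Determinism and problem sizes

Every stochastic step derives its stream from the configured seed; all
derived seeds stay below 2³¹. Pipeline reruns with the same config are
bit-identical, including under `--threads > 1`, because per-module streams
are independent of execution order. Validation studies use desk-scale
problem sizes chosen to exercise each estimator's operating regime: module
recovery at 4 modules (25–50 genes) over 200 background genes and 30+30
samples; DC calibration over 200 size-10 null modules at 500 permutations
and power over 100 replicates of a size-30 module at planted ΔR² = 0.5;
regulator recovery against 50 decoys in a 2000-gene universe; regulome
class recovery over 50 replicates of the two-cohort archetype study.
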