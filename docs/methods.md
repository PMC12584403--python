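# Methods

This note documents the models, the defaults and the judgment calls behind
`eecfate`, in the order the pipeline runs.

## Quality control and normalization

A cell is removed when (i) its mitochondrial count fraction — mitochondrial
counts over non-spike counts — is strictly above `max_mito_fraction`
(0.20 for mouse, 0.50 for human plate-based data), (ii) its ERCC spike-in
fraction — spike counts over all counts — is at or above
`max_ercc_fraction` (0.50; the boundary is inclusive, matching the "50% or
more" convention), or (iii) it detects fewer than `min_genes` non-spike
genes (strict `<`; 500 for mouse E18.5/P12-like data, 3 000 for the deeper
E15.5-like plates, 1 000 for human organoid data — thresholds are per
dataset/batch, so they are plain config values).  Filtering is idempotent
and order-preserving.

Normalization scales each cell so its **non-spike** total equals a common
target (default: the median of per-cell totals, which is scale-free).
Spike-ins are excluded from the total because they measure capture
efficiency, not biology, but they are scaled by the same per-cell factor so
spike-based diagnostics remain meaningful.  Raw counts are always preserved
in `layers["raw"]`.  The log transform is a separate recorded step
(`log1p_layer`): rank-based marker tests are invariant to it, PCA is not,
so embeddings default to log values while dot-plot summaries report plain
normalized means.

## Embedding, graph, clustering

Highly variable genes are ranked by variance/mean dispersion z-scored
within 20 equal-width mean bins; zero-variance genes are never selected.
PCA (default 15 components) is sign-fixed (largest-magnitude loading
positive) for reproducibility and errors out if more components than the
data rank are requested.

The kNN graph (default k = 15; k = 10 on a 10-dimensional embedding for
the fate chain) uses exact brute-force Euclidean neighbors with ties broken
by cell index.  Edge weights are a Gaussian kernel with per-node adaptive
bandwidth (the distance to the node's farthest selected neighbor),
symmetrized by elementwise maximum, which keeps weights in (0, 1] — the
form the diffusion and fate machinery expects.  Batch-balanced neighbors
take each cell's `k_per_batch` nearest cells *within every batch* and then
symmetrize; with one batch this is exactly the plain kNN graph.

Community detection is a pluggable modularity backend (Leiden,
`RBConfigurationVertexPartition`, seeded); the contract is determinism
given a seed, a resolution parameter, and support for sub-clustering a
subset with label splicing.  `cluster_at_n` targets a known number of
populations by bisecting the resolution and, among partitions with the
requested count, returns the one with the highest plain weighted
modularity — a truth-free model-selection rule used by the recovery
experiments, where the number of planted populations is known.

## Markers and cell cycle

Marker tests are two-sided Wilcoxon rank-sum on (log-)normalized values —
exact when both groups are small and tie-free, tie-corrected normal
approximation otherwise — with Benjamini–Hochberg FDR across genes.  The
fold change is log2 of the ratio of group means with a tiny pseudocount
(1e-9 of the gene's global mean) and a ±10 cap; the estimator is a
reporting convenience, the test itself is rank-based.  A gene passes as a
marker iff FDR <= 0.05, log2FC >= 1, expressed (nonzero) in at least
`min_frac_in` (default 0.15) of the group and at most `max_frac_out`
(default 0.65) outside; the defaults sit at the permissive ends of the
conventional 15–20% / 60–65% ranges and are configurable.  Pairwise
condition contrasts reuse the same machinery within each population.

Cell-cycle scores subtract, from the mean expression of a phase gene set,
the mean of a background set sampled per expression-level bin (`ctrl_size`
genes per member; a bin smaller than the request contributes all its
genes).  Phases: S if the S score is the strict maximum and positive, G2M
if the G2/M score wins (ties go to G2M, a documented and configurable
choice) and is positive, else G1.  Phase gene lists are inputs; the
synthetic generator plants its own.

## Lineage graph and pseudotime

Cluster connectivity is the observed number of inter-cluster edges divided
by its configuration-model expectation deg(a)·deg(b)/(2m); the value
reported as *confidence* is clipped to [0, 1] (the raw ratio is kept
alongside).  Under random labels the ratio calibrates to 1.  No numeric
threshold is imposed on the graph — cut-offs are user configuration.

The diffusion map eigendecomposes the symmetric-normalized kernel
D^(−1/2) W D^(−1/2); right eigenvectors of the walk kernel are normalized
so the trivial component is the constant one, making coordinates invariant
to rescaling all edge weights.  Pseudotime is the Euclidean distance from
the root in coordinates weighted by λ/(1−λ) (slowly mixing components
dominate); cells outside the root's connected component are flagged
infinite.  The default root is the most central progenitor (maximal edge
weight into its own cluster), overridable by explicit cell id.  The number
of components defaults to 15.

## Potential field and fate probabilities

Differentiation is a discrete Markov process on the cell graph, biased by
a potential-energy landscape.  The potential is **harmonic**: V = 1 on
source (progenitor) cells, V = 0 on every sink (terminal-fate) cell, and
each interior value is the weighted mean of its neighbors' — the unique
solution of the graph-Laplace boundary problem, solved sparsely to a
residual below 1e-10.  The maximum principle keeps interior values strictly
inside (0, 1).  This harmonic choice is the package's model: it is smooth,
parameter-free given the boundary sets, and admits an exact absorption
oracle; it is a documented stand-in for unspecified potential
constructions, not a claim about any particular one.

Transitions from a non-absorbing cell go to its closed neighborhood with
Boltzmann weights exp(−β(V(j)−V(i))); sink cells are absorbing.  β (default
10) is the single bias parameter: β = 0 is an unbiased walk, large β a
steepest-descent walk; increasing β strictly increases the mean per-step
potential drop.  "Iterations" of the stochastic simulation are the number
of sampled walks (1 500 for mouse-sized runs, 2 000 for organoid-sized
runs); each walk starts from a uniformly drawn source cell and stops at
absorption or `max_steps` (default 10× the number of cells).  Walks that
hit `max_steps` carry no absorption information and are excluded from fate
estimates (and reported).

Fate probabilities come two ways.  Exact: the absorbing-chain system
B = (I−Q)⁻¹R solved sparsely; rows sum to 1 for every transient cell, and
a transient cell that cannot reach any sink is reported by index.
Empirical: a cell's probability for fate F is the fraction of absorbed
walks visiting it that end in F, with binomial standard errors; unvisited
cells are undefined (NaN), low-visit cells are flagged rather than
zero-filled.  Dynamic profiles rescale each absorbed walk to t ∈ [0, 1] by
step index, pool per-cell values in 50 grid bins, and smooth with a
5-bin centered moving average (both configurable); empty bins are filled by
linear interpolation between populated neighbors before smoothing.

## Motif activities and differential selection

The linear model of gene regulation explains gene-centered (log-)
expression per cell as N·A, with N the gene × motif site-count matrix,
column-standardized so activities share a scale (this makes a single
trajectory-SD threshold meaningful across motifs; the standardization is a
package decision).  The per-cell ridge solution is
A = (NᵀN + λI)⁻¹NᵀẼ with λ defaulting to 0.1× the mean eigenvalue of NᵀN
(λ = 0 demands full column rank and is used for oracle checks).  Standard
errors propagate the per-cell residual variance through the sandwich
(NᵀN+λI)⁻¹(NᵀN)(NᵀN+λI)⁻¹; activities are then centered per motif.  The
per-motif z-score is the RMS over cells of A/δA — activity variation
relative to its estimation error.

Expression–activity correlation over a fate's trajectory is Pearson's ρ at
integer bin shifts within ±25% of the profile length (lags with fewer than
5 overlapping bins are excluded); the peak is the maximum |ρ|, and its sign
calls the motif an activator (ρ >= +0.7) or repressor (ρ <= −0.7) — the
magnitude reading is deliberate, since strong negative correlation is the
repressor signature.  A motif is a differential regulator of fate F iff
z >= 1.4 AND trajectory-profile SD >= 0.004 AND peak |ρ| >= 0.7; the
specificity label is the exact set of passing fates, and within a fate
motifs are ordered by activation onset (first bin above half the profile
range).  Motifs without a mapped TF gene cannot receive a role call and
fail closed with a warning.

## Synthetic data: what it emulates, and what it does not

The generator mimics a plate-based EEC experiment: 800 cells × 2 000
biological genes (plus 20 ERCC spike-ins and ~2% mitochondrial genes),
negative-binomial counts (gamma–Poisson, dispersion 3) with log-normal
library sizes, two batches with small per-gene shifts, a progenitor pool
branching at pseudotime 0.3 into three equal fates, and expression driven
by a planted motif-target matrix (25 motifs, ~40 targets each, 3 drivers
per fate) through log-linear effects at SNR 0.5.  Driver activities are
branch-specific sigmoids with staggered onsets (0.40/0.55/0.70, width
0.04) so onset ordering is testable; each driver's TF mRNA leads its
activity by 0.05 pseudotime, fixing the planted lag sign; null motifs get
low-amplitude white noise.  Identity programs rise as the square root of
branch progress and hormone-like markers switch on just after commitment
(sigmoid center 0.42, amplitude 4 natural-log units): commitment is fast
relative to maturation, as in real EEC data where hormone genes turn on
early in committed cells and span orders of magnitude.  A 2% fraction of
cells gets mitochondrial means inflated to a 60% fraction, giving the QC
filters known positives.

Not emulated: amplification chemistry, UMI saturation, doublets, ambient
RNA, nonlinear or combinatorial regulation, and cluster-concentrated
pseudotime (sampling is uniform, the hardest case for clustering since the
data form a continuum).  Passing the recovery suite therefore shows the
pipeline's inference is correct under a known log-linear branching model
with realistic count noise — not that real tissues satisfy that model.

Cells within ~0.05 pseudotime of the branch point are genuinely ambiguous
under this design (their fate programs have barely risen); they bound the
achievable clustering agreement and fate accuracy, which is why the
recovery thresholds (ARI 0.8, fate accuracy 0.9) sit below 1.

## Problem sizes and numerical choices

The test and acceptance runs use the default 800-cell study (seconds per
stage on one CPU), 1 500-walk ensembles, 20 random ≤50-node chains with
10⁵ walks each for the Monte-Carlo-versus-exact absorption check, and
exact Wilcoxon enumeration up to group size 8.  Determinism: every random
step takes an explicit seed (kNN ties by index, PCA and diffusion
components sign-fixed, Leiden seeded, walk ensembles bit-reproducible);
the pipeline derives each stage's seed from the global seed by hashing.
Linear solves are sparse direct; the potential solve reports its residual;
the absorption solver rejects (by index) transient cells that cannot reach
a sink, and NaN rows from singular systems are caught the same way.

## Known limitations

Lagged correlations between two smooth profiles can be spuriously high, so
the correlation criterion is only meaningful jointly with the z-score and
variability criteria; the 0.004 SD threshold is tied to the column-
standardization of N (a different scaling would rescale it); the harmonic
potential ignores expression velocity and density effects; and empirical
fate probabilities are biased for rarely visited cells — prefer the exact
solver whenever the chain fits in memory.
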