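# eecfate

Trajectory, fate-probability and transcription-factor-activity analysis for
single-cell RNA-seq of differentiating enteroendocrine cells (EECs) — the
rare hormone-secreting cells of the intestinal epithelium.  EEC progenitors
(NEUROG3+) commit to distinct hormonal lineages: an enterochromaffin (EC,
serotonin) branch and peptidergic branches (ghrelin/motilin "XMD" and a
GLP-1/CCK/NTS/GIP/secretin/somatostatin "LINKSD" branch in matured human
intestinal organoids).  This package reconstructs those lineages from
plate-based (SORT-seq-like) count matrices and infers which transcription
factors drive each branch, and when.

## What it computes

The pipeline runs in stages, each usable on its own:

1. **QC and normalization** (`eecfate.io_qc`) — cell filters on
   mitochondrial fraction (> 0.20 mouse / 0.50 human), ERCC spike-in
   fraction (>= 0.50) and detected genes; equal-total normalization over
   non-spike genes.
2. **Embedding and clustering** (`eecfate.manifold`) — highly variable
   genes, PCA, a (batch-balanced) kNN graph with adaptive Gaussian edge
   weights, seeded modularity clustering, UMAP layouts, per-cluster
   dot-plot summaries.
3. **Markers and cell cycle** (`eecfate.markers`) — Wilcoxon rank-sum
   markers with BH-FDR and the filter cascade FDR <= 0.05, log2FC >= 1,
   expressed in >= 15% inside / <= 65% outside; pairwise condition
   contrasts; S/G2M scoring against expression-matched backgrounds.
4. **Lineage graph and pseudotime** (`eecfate.lineage`) — cluster
   connectivity as observed/expected inter-cluster edges
   (configuration-model null), and diffusion pseudotime from a root cell
   in eigenvalue-rescaled diffusion coordinates.
5. **Fate trajectories** (`eecfate.fate`) — the core model: a harmonic
   potential V on the cell graph (V = 1 on progenitor sources, V = 0 on
   terminal-fate sinks), a Markov chain with Boltzmann transitions
   P(i→j) ∝ exp(−β·(V(j)−V(i))) over each cell's neighborhood, Monte
   Carlo differentiation trajectories, *fate probabilities* as absorption
   probabilities (both empirical and exactly via B = (I−Q)⁻¹R), and
   trajectory-averaged dynamic profiles of any per-cell quantity.
6. **Motif activities** (`eecfate.motifs`) — per-cell TF activities from
   the linear regulation model E~ ≈ N·A (ridge-solved per cell with
   standard errors), activity z-scores, lagged expression–activity
   Pearson correlation (sign calls activator vs repressor), and
   differential selection of lineage-specific regulators at the
   thresholds z >= 1.4, trajectory SD >= 0.004, peak |ρ| >= 0.7.
7. **Synthetic data** (`eecfate.synthetic`) — a generator with a planted
   branching lineage, motif-target matrix and time-varying TF activities,
   so every stage above can be scored against ground truth
   (`eecfate.recovery` runs the whole loop).

## Worked example

Generate a synthetic study (800 cells, 2 000 genes, three branches, nine
planted driver motifs among 25) and run the full pipeline against its
ground truth:

```python
from eecfate import synthetic, recovery

ds = synthetic.generate_dataset(seed=1)
res = recovery.run_recovery(ds, seed=1)
m = res.metrics
print(f"cells kept after QC : {m['n_cells_kept']}")
print(f"clustering ARI      : {m['clustering_ari']:.3f}")
print(f"fate argmax accuracy: {m['fate_argmax_accuracy']:.3f}")
print(res.report[["motif", "specificity", "zscore", "role"]].head(3).to_string(index=False))
```

prints

```
cells kept after QC : 784
clustering ARI      : 0.901
fate argmax accuracy: 0.979
         motif specificity   zscore      role
   motif_XMD_0         XMD 3.291289 activator
motif_LINKSD_0      LINKSD 3.391197 activator
    motif_EC_0          EC 3.701863 activator
```

Of the 800 simulated cells, the 16 planted high-mitochondria cells are
removed by QC; unsupervised clustering recovers the progenitor pool and
the three branches (adjusted Rand index 0.901 against the planted
populations); 97.9% of committed cells are assigned their true fate by the
exact absorption probabilities; and the differential motif report returns
exactly the planted drivers, each labeled with its true branch and an
activator role (the planted TF mRNA leads its activity).  The same run is
available from the shell:

```bash
eecfate run --out runs/demo --seed 1
eecfate report --run-dir runs/demo
```

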