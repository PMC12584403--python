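"""Synthetic plate-based scRNA-seq datasets with a planted branching lineage.

The generator emulates a SORT-seq-like experiment on differentiating
enteroendocrine cells: a progenitor pool that branches at pseudotime
``t_branch`` into three terminal fates (EC, XMD, LINKSD), negative-binomial
counts with log-normal library sizes, ERCC spike-ins, mitochondrial genes
(with a planted subset of high-mito cells for the QC filters), several
batches, and -- crucially -- gene expression driven by a known motif-target
matrix N* and known time-varying TF activities A*(t), so that clustering,
pseudotime, fate probabilities and motif-activity inference can all be
scored against ground truth.

Expression model (natural-log scale of the NB mean):

    log mu_gc = baseline_g + program effects + snr * sum_m N*_gm A*_m(c)
                + batch effect_g(batch c)

Driver motifs carry smooth branch-specific sigmoidal activity curves with
staggered onsets (so "which was active first" is testable); null motifs
carry low-amplitude white noise.  Each motif maps to a TF gene whose own
mRNA follows the activity curve with a small lead, giving the planted
expression-activity correlation its sign and lag.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from anndata import AnnData

from .io_qc import annotate_genes
from .motifs import MotifTargetMatrix

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "SyntheticDataset",
    "simulate_lineage",
    "simulate_regulation",
    "sample_counts",
    "generate_dataset",
]

BRANCHES = ("EC", "XMD", "LINKSD")
PROGENITOR = "Progenitor"


@dataclass
class SyntheticConfig:
    """Study conditions of the simulated experiment (sizes scaled to a
    plate-based dataset: hundreds of cells, a few thousand genes)."""

    n_cells: int = 800
    n_genes: int = 2000              # biological genes incl. mitochondrial
    n_motifs: int = 25
    n_driver_per_fate: int = 3
    t_branch: float = 0.3
    branch_proportions: tuple = (1 / 3, 1 / 3, 1 / 3)
    targets_per_motif: float = 40.0  # Poisson mean
    snr: float = 0.5                 # scale of the regulatory term
    driver_amplitude: float = 1.0
    driver_onsets: tuple = (0.40, 0.55, 0.70)
    driver_width: float = 0.04
    null_amplitude: float = 0.05
    tf_amplitude: float = 1.5
    tf_lead: float = 0.05            # TF mRNA rises slightly before activity
    n_program_genes: int = 60        # progenitor program
    n_branch_genes: int = 40         # identity ramp genes per branch
    n_hormone_genes: int = 5         # strong late markers per branch
    n_cycle_genes: int = 30          # planted S and G2M programs, each
    program_amplitude: float = 3.0
    hormone_amplitude: float = 4.0
    cycle_amplitude: float = 1.5
    cycling_fraction: float = 0.10   # of progenitor cells, per phase
    nb_dispersion: float = 3.0       # var = mu + mu^2 / dispersion
    mean_total_counts: float = 4000.0
    library_sigma: float = 0.3       # log-normal library-size spread
    n_batches: int = 2
    batch_sd: float = 0.15
    frac_mito_genes: float = 0.02
    n_ercc: int = 20
    frac_high_mito_cells: float = 0.02
    high_mito_fraction: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.t_branch <= 1.0:
            raise ValueError("t_branch must lie in (0, 1]")
        if abs(sum(self.branch_proportions) - 1.0) > 1e-9:
            raise ValueError("branch proportions must sum to 1")


@dataclass
class GroundTruth:
    branch: np.ndarray               # per cell: Progenitor/EC/XMD/LINKSD
    pseudotime: np.ndarray           # per cell, in [0, 1]
    fate: np.ndarray                 # terminal branch, "" for progenitors
    activities: pd.DataFrame         # motifs x cells, planted A*
    sites: pd.DataFrame              # genes x motifs, planted N*
    motif_to_tf: dict
    driver_pairs: list               # [(motif, fate), ...]
    log_means: np.ndarray            # genes x cells, noiseless biology
    library_size: np.ndarray
    batch: np.ndarray
    high_mito_cells: np.ndarray
    progenitor_genes: list
    branch_genes: dict               # branch -> gene names
    hormone_genes: dict
    s_phase: dict = field(default_factory=dict)    # genes + cells planted
    g2m_phase: dict = field(default_factory=dict)


@dataclass
class SyntheticDataset:
    adata: AnnData                   # raw counts, cells x genes (+ ERCC)
    truth: GroundTruth
    config: SyntheticConfig

    @property
    def motif_matrix(self) -> MotifTargetMatrix:
        return MotifTargetMatrix(sites=self.truth.sites.copy(),
                                 motif_to_tf=dict(self.truth.motif_to_tf))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def simulate_lineage(cfg: SyntheticConfig, rng: np.random.Generator):
    """Uniform pseudotime; cells past ``t_branch`` drawn into one of the
    terminal branches with the configured proportions."""
    t = rng.uniform(0.0, 1.0, size=cfg.n_cells)
    branch = np.full(cfg.n_cells, PROGENITOR, dtype=object)
    post = t >= cfg.t_branch
    branch[post] = rng.choice(BRANCHES, size=int(post.sum()), p=cfg.branch_proportions)
    return branch, t


def _gene_names(cfg: SyntheticConfig):
    n_mito = max(int(round(cfg.frac_mito_genes * cfg.n_genes)), 1)
    names = [f"mt-G{i:04d}" for i in range(n_mito)]
    names += [f"G{i:04d}" for i in range(cfg.n_genes - n_mito)]
    return names, n_mito


def simulate_regulation(cfg: SyntheticConfig, branch, t, batch, rng):
    """Plant N*, A*(t) and the per-cell gene log-means."""
    gene_names, n_mito = _gene_names(cfg)
    n_genes, n_cells = cfg.n_genes, cfg.n_cells

    # --- reserved gene blocks (disjoint; targets drawn from what is left)
    cursor = n_mito
    def take(k):
        nonlocal cursor
        block = list(range(cursor, cursor + k))
        cursor += k
        return block

    prog_idx = take(cfg.n_program_genes)
    branch_idx = {b: take(cfg.n_branch_genes) for b in BRANCHES}
    hormone_idx = {b: take(cfg.n_hormone_genes) for b in BRANCHES}
    s_idx = take(cfg.n_cycle_genes)
    g2m_idx = take(cfg.n_cycle_genes)
    tf_idx = take(cfg.n_motifs)
    if cursor >= n_genes:
        raise ValueError(
            f"n_genes={n_genes} is too small for the reserved gene blocks "
            f"({cursor} genes of programs, cycle sets and TFs)"
        )
    pool = np.arange(cursor, n_genes)

    # --- motifs: drivers per fate with staggered onsets, the rest null
    motif_names, driver_pairs, onsets = [], [], {}
    for b in BRANCHES:
        for j in range(cfg.n_driver_per_fate):
            name = f"motif_{b}_{j}"
            motif_names.append(name)
            driver_pairs.append((name, b))
            onsets[name] = cfg.driver_onsets[j % len(cfg.driver_onsets)]
    n_null = cfg.n_motifs - len(motif_names)
    if n_null < 0:
        raise ValueError("n_motifs too small for the requested drivers")
    motif_names += [f"motif_null_{j}" for j in range(n_null)]
    motif_to_tf = {m: gene_names[tf_idx[i]] for i, m in enumerate(motif_names)}

    # --- planted site-count matrix N*
    sites = np.zeros((n_genes, cfg.n_motifs))
    for mi in range(cfg.n_motifs):
        while True:
            n_targets = rng.poisson(cfg.targets_per_motif)
            if n_targets > 0:
                break
        targets = rng.choice(pool, size=min(n_targets, pool.size), replace=False)
        sites[targets, mi] = 1.0 + rng.poisson(1.5, size=targets.size)

    # --- planted activities A*(cell)
    driver_fate = dict(driver_pairs)
    activities = np.zeros((cfg.n_motifs, n_cells))
    for mi, m in enumerate(motif_names):
        if m in driver_fate:
            on_branch = branch == driver_fate[m]
            curve = cfg.driver_amplitude * _sigmoid((t - onsets[m]) / cfg.driver_width)
            activities[mi] = np.where(on_branch, curve, 0.0)
        else:
            activities[mi] = rng.normal(0.0, cfg.null_amplitude, size=n_cells)

    # --- baseline: log-normal relative abundances scaled to the target depth
    rel = rng.lognormal(mean=0.0, sigma=1.2, size=n_genes)
    baseline = np.log(rel / rel.sum() * cfg.mean_total_counts)

    log_means = np.tile(baseline[:, None], (1, n_cells))

    # progenitor program decays after the branch point
    prog_curve = 1.0 - _sigmoid((t - cfg.t_branch) / 0.05)
    log_means[np.ix_(prog_idx, np.arange(n_cells))] += cfg.program_amplitude * prog_curve

    # branch identity programs: commitment is fast relative to maturation,
    # so the ramp rises as sqrt of branch progress and saturates
    for b in BRANCHES:
        on = branch == b
        progress = np.clip((t - cfg.t_branch) / (1 - cfg.t_branch), 0, 1)
        ramp = np.where(on, np.sqrt(progress), 0.0)
        log_means[np.ix_(branch_idx[b], np.arange(n_cells))] += cfg.program_amplitude * ramp
        horm = np.where(on, _sigmoid((t - 0.42) / 0.06), 0.0)
        log_means[np.ix_(hormone_idx[b], np.arange(n_cells))] += cfg.hormone_amplitude * horm

    # planted cell-cycle programs in a fraction of progenitor cells
    prog_cells = np.nonzero(branch == PROGENITOR)[0]
    n_cyc = int(round(cfg.cycling_fraction * prog_cells.size))
    cyc = rng.permutation(prog_cells)[: 2 * n_cyc]
    s_cells, g2m_cells = cyc[:n_cyc], cyc[n_cyc: 2 * n_cyc]
    log_means[np.ix_(s_idx, s_cells)] += cfg.cycle_amplitude
    log_means[np.ix_(g2m_idx, g2m_cells)] += cfg.cycle_amplitude

    # TF mRNA follows its motif's activity with a small lead
    for mi, m in enumerate(motif_names):
        if m in driver_fate:
            on = branch == driver_fate[m]
            curve = cfg.tf_amplitude * _sigmoid((t - (onsets[m] - cfg.tf_lead)) / cfg.driver_width)
            log_means[tf_idx[mi]] += np.where(on, curve, 0.0)

    # regulatory term and batch effect
    log_means += cfg.snr * (sites @ activities)
    if cfg.n_batches > 1:
        shifts = rng.normal(0.0, cfg.batch_sd, size=(n_genes, cfg.n_batches))
        shifts[:, 0] = 0.0
        log_means += shifts[:, batch]

    truth = GroundTruth(
        branch=branch,
        pseudotime=t,
        fate=np.where(branch == PROGENITOR, "", branch),
        activities=pd.DataFrame(activities, index=pd.Index(motif_names, name="motif")),
        sites=pd.DataFrame(sites, index=pd.Index(gene_names, name="gene"),
                           columns=pd.Index(motif_names, name="motif")),
        motif_to_tf=motif_to_tf,
        driver_pairs=driver_pairs,
        log_means=log_means,
        library_size=np.array([]),
        batch=batch,
        high_mito_cells=np.array([], dtype=int),
        progenitor_genes=[gene_names[i] for i in prog_idx],
        branch_genes={b: [gene_names[i] for i in branch_idx[b]] for b in BRANCHES},
        hormone_genes={b: [gene_names[i] for i in hormone_idx[b]] for b in BRANCHES},
        s_phase={"genes": [gene_names[i] for i in s_idx], "cells": s_cells},
        g2m_phase={"genes": [gene_names[i] for i in g2m_idx], "cells": g2m_cells},
    )
    return truth


def sample_counts(cfg: SyntheticConfig, truth: GroundTruth, rng) -> AnnData:
    """Negative-binomial counts (gamma-Poisson mixture; dispersion -> inf
    recovers Poisson) with log-normal library sizes; ERCC spike-ins at
    fixed means independent of the library size; a planted fraction of
    cells gets its mitochondrial means inflated to a target mito fraction
    so the QC filters have known positives."""
    n_cells = cfg.n_cells
    gene_names, n_mito = _gene_names(cfg)
    lib = rng.lognormal(mean=0.0, sigma=cfg.library_sigma, size=n_cells)
    lib /= lib.mean() if lib.mean() > 0 else 1.0

    mu = np.exp(np.clip(truth.log_means, None, 20.0)) * lib[None, :]

    # plant high-mito cells: inflate mito means to reach the target fraction
    n_bad = int(round(cfg.frac_high_mito_cells * n_cells))
    bad = rng.choice(n_cells, size=n_bad, replace=False) if n_bad else np.array([], int)
    f = cfg.high_mito_fraction
    for c in bad:
        mito_mass = mu[:n_mito, c].sum()
        other_mass = mu[n_mito:, c].sum()
        if mito_mass > 0:
            mu[:n_mito, c] *= (f / (1 - f)) * other_mass / mito_mass

    disp = cfg.nb_dispersion
    lam = rng.gamma(shape=disp, scale=mu / disp)
    counts = rng.poisson(lam).astype(np.float64)

    ercc_names = [f"ERCC-{i:04d}" for i in range(cfg.n_ercc)]
    ercc_mu = rng.lognormal(mean=1.0, sigma=1.0, size=cfg.n_ercc)
    ercc_lam = rng.gamma(shape=disp, scale=np.tile(ercc_mu[:, None], (1, n_cells)) / disp)
    ercc_counts = rng.poisson(ercc_lam).astype(np.float64)

    x = np.vstack([counts, ercc_counts]).T  # cells x genes
    all_genes = gene_names + ercc_names
    adata = AnnData(
        X=x,
        obs=pd.DataFrame(
            {
                "batch": pd.Categorical([f"batch{b}" for b in truth.batch]),
                "true_branch": truth.branch,
                "true_pseudotime": truth.pseudotime,
            },
            index=pd.Index([f"cell{i:04d}" for i in range(n_cells)], name="cell_id"),
        ),
        var=pd.DataFrame(index=pd.Index(all_genes, name="gene_id")),
    )
    annotate_genes(adata)
    adata.uns["normalized"] = False
    truth.library_size = lib
    truth.high_mito_cells = np.sort(bad)
    return adata


def generate_dataset(cfg: SyntheticConfig | None = None, seed: int | None = None) -> SyntheticDataset:
    """Compose lineage, regulation and count sampling; all randomness flows
    from a single generator, so config + seed is bit-reproducible."""
    cfg = cfg or SyntheticConfig()
    if seed is not None:
        cfg = SyntheticConfig(**{**asdict(cfg), "seed": seed})
    rng = np.random.default_rng(cfg.seed)
    branch, t = simulate_lineage(cfg, rng)
    batch = rng.integers(0, cfg.n_batches, size=cfg.n_cells)
    truth = simulate_regulation(cfg, branch, t, batch, rng)
    adata = sample_counts(cfg, truth, rng)
    return SyntheticDataset(adata=adata, truth=truth, config=cfg)
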