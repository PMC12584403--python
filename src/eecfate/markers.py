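"""Marker genes, pairwise differential expression and cell-cycle scoring.

Marker calls use the two-sided Wilcoxon rank-sum test on (log-)normalized
expression with Benjamini-Hochberg FDR control, then a four-way filter
cascade: FDR <= 0.05, log2 fold change >= 1, expressed in at least 15-20%
of the cells inside the group and in at most 60-65% outside.  Defaults sit
at the permissive ends of those ranges (0.15 in / 0.65 out) and are
configurable.

Cell-cycle phases are assigned from S and G2/M scores, each the average
expression of a phase gene set minus the average of a background set drawn
from matching expression-level bins; a cell is S or G2M when the larger
score is positive, G1 otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "MarkerFilterConfig",
    "rank_markers",
    "pairwise_de",
    "score_gene_set",
    "assign_phase",
    "score_cell_cycle",
    "benjamini_hochberg",
]

LFC_CAP = 10.0
LFC_PSEUDO_SCALE = 1e-9


@dataclass
class MarkerFilterConfig:
    max_fdr: float = 0.05
    min_lfc: float = 1.0          # log2 scale
    min_frac_in: float = 0.15     # paper range 0.15-0.20
    max_frac_out: float = 0.65    # paper range 0.60-0.65

    def __post_init__(self) -> None:
        if not 0.0 < self.max_fdr < 1.0:
            raise ValueError("max_fdr must lie in (0, 1)")
        for name in ("min_frac_in", "max_frac_out"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


def benjamini_hochberg(pvals) -> np.ndarray:
    """BH step-up adjusted p-values (statsmodels backend)."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals
    return multipletests(pvals, method="fdr_bh")[1]


def _wilcoxon_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided rank-sum p-value; exact when samples are small and
    tie-free, normal approximation (tie-corrected) otherwise."""
    if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
        return 1.0
    pooled = np.concatenate([x, y])
    exact = max(len(x), len(y)) <= 25 and len(np.unique(pooled)) == len(pooled)
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return float(res.pvalue)


def _log2_fold_change(mean_in: float, mean_out: float, global_mean: float) -> float:
    # tiny pseudocount proportional to the gene's global mean; capped
    eps = LFC_PSEUDO_SCALE * max(global_mean, 1e-300)
    if mean_in <= 0 and mean_out <= 0:
        return 0.0
    lfc = np.log2((mean_in + eps) / (mean_out + eps))
    return float(np.clip(lfc, -LFC_CAP, LFC_CAP))


def rank_markers(
    values: np.ndarray,
    labels,
    group,
    reference="rest",
    cfg: MarkerFilterConfig | None = None,
    gene_names=None,
    raw_values: np.ndarray | None = None,
) -> pd.DataFrame:
    """Differential expression of ``group`` against ``reference`` (another
    label, or ``"rest"``).

    ``values`` (cells x genes, normalized; log scale is fine since the
    test is rank-based) drives the Wilcoxon p-values and expressing
    fractions; fold changes use ``raw_values`` (normalized, non-log) when
    given, else ``values``.  Returns one row per gene with p, BH FDR,
    log2FC, frac_in/out and the ``passed`` flag of the filter cascade.
    """
    cfg = cfg or MarkerFilterConfig()
    values = np.asarray(values, dtype=np.float64)
    labels = np.asarray(labels)
    in_mask = labels == group
    out_mask = (labels != group) if (isinstance(reference, str) and reference == "rest") else (labels == reference)
    if in_mask.sum() < 2:
        raise ValueError(f"group {group!r} has fewer than 2 cells")
    if out_mask.sum() < 2:
        raise ValueError(f"reference {reference!r} has fewer than 2 cells")
    fc_vals = np.asarray(raw_values, dtype=np.float64) if raw_values is not None else values
    xin, xout = values[in_mask], values[out_mask]
    fin, fout = fc_vals[in_mask], fc_vals[out_mask]
    n_genes = values.shape[1]
    gene_names = list(gene_names) if gene_names is not None else list(range(n_genes))

    pvals = np.array([_wilcoxon_p(xin[:, g], xout[:, g]) for g in range(n_genes)])
    fdr = benjamini_hochberg(pvals)
    mean_in, mean_out = fin.mean(axis=0), fout.mean(axis=0)
    global_mean = fc_vals.mean(axis=0)
    lfc = np.array(
        [_log2_fold_change(mean_in[g], mean_out[g], global_mean[g]) for g in range(n_genes)]
    )
    frac_in = (xin > 0).mean(axis=0)
    frac_out = (xout > 0).mean(axis=0)
    passed = (
        (fdr <= cfg.max_fdr)
        & (lfc >= cfg.min_lfc)
        & (frac_in >= cfg.min_frac_in)
        & (frac_out <= cfg.max_frac_out)
    )
    return pd.DataFrame(
        {
            "gene": gene_names,
            "group": group,
            "p_value": pvals,
            "fdr": fdr,
            "log_fold_change": lfc,
            "frac_in": frac_in,
            "frac_out": frac_out,
            "passed": passed,
        }
    )


def pairwise_de(
    values: np.ndarray,
    population_labels,
    condition_labels,
    cfg: MarkerFilterConfig | None = None,
    gene_names=None,
    populations=None,
    raw_values: np.ndarray | None = None,
) -> pd.DataFrame:
    """Within each population, test one condition against the other (the
    organoid-versus-transplanted comparison pattern); both directions are
    reported with group labels ``"<population>:<condition>"``."""
    population_labels = np.asarray(population_labels)
    condition_labels = np.asarray(condition_labels)
    values = np.asarray(values, dtype=np.float64)
    populations = populations if populations is not None else np.unique(population_labels)
    tables = []
    for pop in populations:
        mask = population_labels == pop
        conds = np.unique(condition_labels[mask])
        if len(conds) < 2:
            raise ValueError(
                f"population {pop!r} lacks both conditions (has {list(conds)})"
            )
        sub_vals = values[mask]
        sub_raw = raw_values[mask] if raw_values is not None else None
        sub_cond = condition_labels[mask]
        for a in conds:
            b = [c for c in conds if c != a]
            if len(b) != 1:
                raise ValueError("pairwise_de expects exactly two conditions")
            tab = rank_markers(
                sub_vals, sub_cond, a, reference=b[0], cfg=cfg,
                gene_names=gene_names, raw_values=sub_raw,
            )
            tab["group"] = f"{pop}:{a}"
            tables.append(tab)
    return pd.concat(tables, ignore_index=True)


def score_gene_set(
    values: np.ndarray,
    gene_set,
    n_bins: int = 25,
    ctrl_size: int = 50,
    seed: int = 0,
) -> np.ndarray:
    """Per-cell score: mean expression over ``gene_set`` minus the mean
    over a background set sampled per expression-level bin (``ctrl_size``
    genes per set member, without replacement within a bin)."""
    values = np.asarray(values, dtype=np.float64)
    gene_set = np.asarray(gene_set, dtype=int)
    if gene_set.size == 0:
        raise ValueError("gene_set is empty")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    rng = np.random.default_rng(seed)
    mean = values.mean(axis=0)
    order = np.argsort(mean, kind="stable")
    n_genes = values.shape[1]
    bins = np.empty(n_genes, dtype=int)
    bins[order] = np.minimum((np.arange(n_genes) * n_bins) // n_genes, n_bins - 1)

    ctrl = []
    for b in np.unique(bins[gene_set]):
        pool = np.nonzero(bins == b)[0]
        n_members = int((bins[gene_set] == b).sum())
        take = min(ctrl_size * n_members, pool.size)
        if take == pool.size:
            ctrl.append(pool)
        else:
            ctrl.append(rng.choice(pool, size=take, replace=False))
    ctrl = np.unique(np.concatenate(ctrl))
    return values[:, gene_set].mean(axis=1) - values[:, ctrl].mean(axis=1)


def read_gene_set(path) -> list:
    """One gene symbol per line; blank lines and '#' comments ignored."""
    from pathlib import Path

    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def assign_phase(s_score: float, g2m_score: float) -> str:
    """S if the S score wins and is positive, G2M if the G2/M score wins
    (ties go to G2M) and is positive, else G1."""
    if s_score > g2m_score and s_score > 0:
        return "S"
    if g2m_score >= s_score and g2m_score > 0:
        return "G2M"
    return "G1"


def score_cell_cycle(
    values: np.ndarray,
    s_genes,
    g2m_genes,
    n_bins: int = 25,
    ctrl_size: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """S/G2M scores plus the assigned phase for every cell."""
    s = score_gene_set(values, s_genes, n_bins, ctrl_size, seed)
    g = score_gene_set(values, g2m_genes, n_bins, ctrl_size, seed + 1)
    phase = [assign_phase(si, gi) for si, gi in zip(s, g)]
    return pd.DataFrame({"s_score": s, "g2m_score": g, "phase": phase})
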