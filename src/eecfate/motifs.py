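"""Per-cell TF (motif) activity inference and differential-activity selection.

The linear model of gene regulation explains the gene-centered expression
of cell c as a weighted sum of motif activities,

    E_gc - <E_g>  ~  sum_m  N_gm * A_mc ,

where N is the (column-standardized) gene x motif site-count matrix.  The
per-cell ridge solution A_.c = (N'N + lambda I)^-1 N' E~_.c disentangles
TFs sharing target genes; standard errors come from the per-cell residual
variance propagated through the sandwich covariance, and activities are
centered per motif so only coordinated deviations from the mean count.

Lineage-specific regulators are selected by three criteria: an activity
z-score >= 1.4 (signal relative to estimation error), a standard deviation
of the trajectory-averaged activity profile >= 0.004 (dynamic range along a
lineage), and a peak |Pearson| >= 0.7 between the TF's expression and
activity profiles across a window of time lags, whose sign calls the TF an
activator or a repressor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd

from .fate import DynamicProfile

__all__ = [
    "MotifTargetMatrix",
    "ActivityMatrix",
    "LaggedCorrelation",
    "DifferentialThresholds",
    "fit_activities",
    "activity_zscores",
    "profile_std",
    "lagged_correlation",
    "select_differential",
]


@dataclass
class MotifTargetMatrix:
    """Nonnegative gene x motif site counts plus the motif -> TF-gene map
    used to look up the regulator's own mRNA expression."""

    sites: pd.DataFrame                 # genes x motifs
    motif_to_tf: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = self.sites.to_numpy()
        if (vals < 0).any():
            raise ValueError("site counts must be nonnegative")
        zero = vals.sum(axis=0) == 0
        if zero.any():
            dropped = list(self.sites.columns[zero])
            warnings.warn(f"dropping all-zero motif columns: {dropped}")
            self.sites = self.sites.loc[:, ~zero]

    @property
    def motif_names(self):
        return list(self.sites.columns)

    @classmethod
    def from_long(cls, table: pd.DataFrame, gene_order, motif_to_tf=None):
        """Build from a long (gene, motif, count) table aligned to
        ``gene_order``."""
        wide = table.pivot_table(index="gene", columns="motif", values="count",
                                 aggfunc="sum", fill_value=0.0)
        wide = wide.reindex(gene_order, fill_value=0.0)
        return cls(sites=wide, motif_to_tf=motif_to_tf or {})


@dataclass
class ActivityMatrix:
    activities: pd.DataFrame            # motifs x cells, centered per motif
    se: pd.DataFrame                    # matching delta-A, > 0
    ridge_penalty: float
    residual_variance: np.ndarray       # per cell


@dataclass
class LaggedCorrelation:
    lags: np.ndarray
    rho: np.ndarray
    peak_lag: int
    peak_rho: float                     # signed value at the peak |rho|
    role: str                           # "activator" | "repressor" | "none"


@dataclass
class DifferentialThresholds:
    min_zscore: float = 1.4
    min_profile_std: float = 0.004
    min_abs_correlation: float = 0.7


def standardize_columns(n: np.ndarray) -> np.ndarray:
    """Zero mean, unit variance per motif over genes; puts activities on
    comparable scales so one trajectory-SD threshold is meaningful."""
    n = np.asarray(n, dtype=np.float64)
    mu = n.mean(axis=0)
    sd = n.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("constant motif column cannot be standardized")
    return (n - mu) / sd


def fit_activities(
    expression: np.ndarray,
    sites: "MotifTargetMatrix | pd.DataFrame | np.ndarray",
    ridge_penalty: float | None = None,
    cell_names=None,
    standardize: bool = True,
) -> ActivityMatrix:
    """Ridge fit of motif activities from genes x cells expression.

    ``expression`` is (log-)normalized genes x cells; it is centered per
    gene here.  ``ridge_penalty`` defaults to 0.1 x the mean eigenvalue of
    N'N; pass 0 for plain least squares (requires full column rank).
    """
    if isinstance(sites, MotifTargetMatrix):
        n_df = sites.sites
        motif_names = sites.motif_names
        n_raw = n_df.to_numpy(dtype=np.float64)
    elif isinstance(sites, pd.DataFrame):
        motif_names = list(sites.columns)
        n_raw = sites.to_numpy(dtype=np.float64)
    else:
        n_raw = np.asarray(sites, dtype=np.float64)
        motif_names = list(range(n_raw.shape[1]))
    e = np.asarray(expression, dtype=np.float64)
    if e.shape[0] != n_raw.shape[0]:
        raise ValueError(
            f"expression has {e.shape[0]} genes but the site matrix has {n_raw.shape[0]}"
        )
    n_mat = standardize_columns(n_raw) if standardize else n_raw
    g, m = n_mat.shape
    e_centered = e - e.mean(axis=1, keepdims=True)

    ntn = n_mat.T @ n_mat
    if ridge_penalty is None:
        ridge_penalty = 0.1 * float(np.trace(ntn)) / m
    if ridge_penalty < 0:
        raise ValueError("ridge penalty must be >= 0")
    reg = ntn + ridge_penalty * np.eye(m)
    if ridge_penalty == 0:
        if np.linalg.matrix_rank(ntn) < m:
            raise ValueError(
                "N'N is rank-deficient; use a ridge penalty > 0"
            )
    reg_inv = np.linalg.inv(reg)
    a = reg_inv @ (n_mat.T @ e_centered)              # motifs x cells

    resid = e_centered - n_mat @ a
    dof = max(g - m, 1)
    sigma2 = (resid ** 2).sum(axis=0) / dof           # per cell
    core = np.diag(reg_inv @ ntn @ reg_inv)           # sandwich diagonal
    se = np.sqrt(np.maximum(np.outer(core, sigma2), 1e-300))

    a = a - a.mean(axis=1, keepdims=True)             # center per motif
    cells = pd.Index(cell_names if cell_names is not None else np.arange(e.shape[1]),
                     name="cell")
    motifs = pd.Index(motif_names, name="motif")
    return ActivityMatrix(
        activities=pd.DataFrame(a, index=motifs, columns=cells),
        se=pd.DataFrame(se, index=motifs, columns=cells),
        ridge_penalty=float(ridge_penalty),
        residual_variance=sigma2,
    )


def activity_zscores(am: ActivityMatrix) -> pd.Series:
    """Per motif, root-mean-square over cells of A/deltaA: how much the
    activity varies across cells relative to its estimated error."""
    ratio = am.activities.to_numpy() / am.se.to_numpy()
    z = np.sqrt((ratio ** 2).mean(axis=1))
    return pd.Series(z, index=am.activities.index, name="zscore")


def profile_std(profile: "DynamicProfile | np.ndarray") -> float:
    """Population standard deviation of the binned mean-activity values."""
    vals = profile.mean if isinstance(profile, DynamicProfile) else np.asarray(profile, float)
    if vals.size < 2:
        raise ValueError("profile needs at least 2 bins")
    return float(np.std(vals))


def lagged_correlation(
    expr_profile: np.ndarray,
    act_profile: np.ndarray,
    max_lag_bins: int | None = None,
    min_overlap: int = 5,
    role_threshold: float = 0.7,
) -> LaggedCorrelation:
    """Pearson correlation between expression and activity profiles at
    integer bin shifts tau in [-L, L]; positive tau means the activity
    trails the expression.  The peak is the maximum |rho| over lags with at
    least ``min_overlap`` overlapping bins; its sign calls the role."""
    e = np.asarray(expr_profile, dtype=np.float64)
    a = np.asarray(act_profile, dtype=np.float64)
    if e.shape != a.shape:
        raise ValueError("profiles must share the same grid")
    n = e.size
    if max_lag_bins is None:
        max_lag_bins = max(1, n // 4)
    lags, rhos = [], []
    for tau in range(-max_lag_bins, max_lag_bins + 1):
        if tau >= 0:
            x, y = e[: n - tau], a[tau:]
        else:
            x, y = e[-tau:], a[: n + tau]
        if x.size < min_overlap:
            continue
        sx, sy = x.std(), y.std()
        if sx == 0 or sy == 0:
            continue
        rhos.append(float(np.corrcoef(x, y)[0, 1]))
        lags.append(tau)
    if not rhos:
        raise ValueError("no lag had enough overlapping bins")
    lags = np.asarray(lags)
    rhos = np.asarray(rhos)
    best = int(np.argmax(np.abs(rhos)))
    peak_rho = float(rhos[best])
    if peak_rho >= role_threshold:
        role = "activator"
    elif peak_rho <= -role_threshold:
        role = "repressor"
    else:
        role = "none"
    return LaggedCorrelation(lags=lags, rho=rhos, peak_lag=int(lags[best]),
                             peak_rho=peak_rho, role=role)


def _onset_bin(profile_values: np.ndarray) -> int:
    """First grid bin where activity exceeds half its profile range
    (the "which was active first" ordering)."""
    vals = np.asarray(profile_values, dtype=np.float64)
    lo, hi = vals.min(), vals.max()
    if hi <= lo:
        return len(vals)
    crossing = np.nonzero(vals > lo + 0.5 * (hi - lo))[0]
    return int(crossing[0]) if crossing.size else len(vals)


def select_differential(
    zscores: pd.Series,
    profiles: dict,
    correlations: dict,
    thresholds: DifferentialThresholds | None = None,
    fates: tuple | None = None,
) -> pd.DataFrame:
    """Differential motif-activity report.

    ``profiles`` and ``correlations`` map (motif, fate) to a
    :class:`DynamicProfile` (or bin-value array) and a
    :class:`LaggedCorrelation`.  A motif passes fate F iff z >= 1.4 AND
    profile SD >= 0.004 AND peak |rho| >= 0.7 (defaults); a missing
    (motif, fate) entry fails closed with a warning.  The report lists one
    row per selected motif with its passing-fate set (specificity label),
    role and per-fate activation-onset bin.
    """
    thresholds = thresholds or DifferentialThresholds()
    if fates is None:
        fates = tuple(sorted({f for (_, f) in profiles}))
    rows = []
    for motif in zscores.index:
        z = float(zscores[motif])
        passing, roles, onsets, stds, rhos = [], {}, {}, {}, {}
        for fate_name in fates:
            prof = profiles.get((motif, fate_name))
            corr = correlations.get((motif, fate_name))
            if prof is None or corr is None:
                warnings.warn(f"missing profile/correlation for {motif!r} in {fate_name!r}")
                continue
            vals = prof.mean if isinstance(prof, DynamicProfile) else np.asarray(prof, float)
            sd = profile_std(vals)
            stds[fate_name] = sd
            rhos[fate_name] = corr.peak_rho
            roles[fate_name] = corr.role
            onsets[fate_name] = _onset_bin(vals)
            if (
                z >= thresholds.min_zscore
                and sd >= thresholds.min_profile_std
                and abs(corr.peak_rho) >= thresholds.min_abs_correlation
            ):
                passing.append(fate_name)
        if not passing:
            continue
        label = "+".join(passing)
        rows.append(
            {
                "motif": motif,
                "zscore": z,
                "specificity": label,
                "n_fates": len(passing),
                "fates": tuple(passing),
                "role": roles[passing[0]],
                **{f"std_{f}": stds.get(f, np.nan) for f in fates},
                **{f"rho_{f}": rhos.get(f, np.nan) for f in fates},
                **{f"onset_{f}": onsets.get(f, np.nan) for f in fates},
            }
        )
    report = pd.DataFrame(rows)
    if len(report):
        # within-fate ordering: earliest activation first
        first_fate = report["fates"].map(lambda fs: fs[0])
        onset_key = [row[f"onset_{f}"] for row, f in zip(rows, first_fate)]
        report = report.assign(_onset=onset_key).sort_values(
            ["n_fates", "_onset"], ascending=[False, True]
        ).drop(columns="_onset").reset_index(drop=True)
    return report


def specificity_categories(report: pd.DataFrame, fates: tuple) -> pd.Series:
    """Count selected motifs per passing-fate set (the seven categories for
    three fates: each single fate, each pair, all three)."""
    from itertools import combinations

    cats = []
    for r in range(len(fates), 0, -1):
        for combo in combinations(fates, r):
            cats.append("+".join(combo))
    counts = {c: 0 for c in cats}
    if len(report):
        for fs in report["fates"]:
            key = "+".join(fs)
            counts[key] = counts.get(key, 0) + 1
    return pd.Series(counts, name="n_motifs")
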