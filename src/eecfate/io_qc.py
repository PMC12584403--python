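"""Count-matrix loading, gene flagging, cell quality control and normalization.

The in-memory container is :class:`anndata.AnnData` (cells x genes).  Raw
integer counts are preserved in ``layers["raw"]`` once the matrix is
normalized; gene flags live in ``var["is_mito"]`` / ``var["is_ercc"]``.

Filter semantics follow the plate-based (SORT-seq) conventions used for
enteroendocrine-cell profiling: a cell is removed when its mitochondrial
count fraction is strictly above ``max_mito_fraction`` (20% for mouse, 50%
for human data), when 50% or more of its reads are ERCC spike-ins, or when
it expresses fewer than ``min_genes`` genes (500 / 3000 / 1000 depending on
the dataset).  Spike-ins measure technical capture, not biology, so they are
excluded from the per-cell totals used for normalization and from
detected-gene counts.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

__all__ = [
    "QCConfig",
    "QCReport",
    "QCError",
    "load_counts",
    "annotate_genes",
    "filter_cells",
    "normalize_total",
    "log1p_layer",
]

MITO_REGEX_DEFAULT = r"^mt-"
ERCC_PREFIX_DEFAULT = "ERCC-"


class QCError(ValueError):
    """Structured QC / loading failure; carries an optional report."""

    def __init__(self, message: str, report: "QCReport | None" = None):
        super().__init__(message)
        self.report = report


@dataclass
class QCConfig:
    """Cell-filter thresholds and normalization target.

    max_mito_fraction : remove cells with mito fraction strictly above this
        (0.20 mouse, 0.50 human).
    max_ercc_fraction : remove cells with spike-in fraction at or above this.
    min_genes : remove cells detecting fewer than this many non-spike genes.
    target_total : per-cell non-spike total after normalization
        (``None`` = median of per-cell totals).
    """

    max_mito_fraction: float = 0.20
    max_ercc_fraction: float = 0.50
    min_genes: int = 500
    target_total: float | None = None
    drop_zero_genes: bool = False
    mito_regex: str = MITO_REGEX_DEFAULT
    ercc_prefix: str = ERCC_PREFIX_DEFAULT

    def __post_init__(self) -> None:
        for name in ("max_mito_fraction", "max_ercc_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.min_genes < 0:
            raise ValueError("min_genes must be >= 0")


@dataclass
class QCReport:
    n_cells_in: int = 0
    n_cells_kept: int = 0
    n_genes_in: int = 0
    n_genes_kept: int = 0
    n_failed_mito: int = 0
    n_failed_ercc: int = 0
    n_failed_min_genes: int = 0
    removal_counts: dict = field(default_factory=dict)

    @property
    def n_cells_removed(self) -> int:
        return self.n_cells_in - self.n_cells_kept

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def _dense(x) -> np.ndarray:
    return np.asarray(x.todense()) if sp.issparse(x) else np.asarray(x)


def load_counts(
    counts_path: str | Path,
    fmt: str | None = None,
    genes_path: str | Path | None = None,
    cells_path: str | Path | None = None,
    cell_meta_path: str | Path | None = None,
    mito_regex: str = MITO_REGEX_DEFAULT,
    ercc_prefix: str = ERCC_PREFIX_DEFAULT,
) -> AnnData:
    """Read a raw cell x gene count matrix.

    ``fmt`` is ``"mtx_triplet"`` (MatrixMarket matrix plus one-id-per-line
    gene and cell files) or ``"delimited"`` (TSV/CSV with cell ids in the
    first column and gene ids in the header); inferred from the suffix when
    omitted.  Raises :class:`QCError` on dimension mismatches or
    non-integer entries.
    """
    counts_path = Path(counts_path)
    if not counts_path.exists():
        raise QCError(f"counts file not found: {counts_path}")
    if fmt is None:
        fmt = "mtx_triplet" if counts_path.suffix == ".mtx" else "delimited"

    if fmt == "mtx_triplet":
        from scipy.io import mmread

        mat = sp.csr_matrix(mmread(counts_path))
        if genes_path is None or cells_path is None:
            raise QCError("mtx_triplet format requires genes_path and cells_path")
        gene_ids = Path(genes_path).read_text().split()
        cell_ids = Path(cells_path).read_text().split()
        if mat.shape == (len(cell_ids), len(gene_ids)):
            pass  # stored cells x genes
        elif mat.shape == (len(gene_ids), len(cell_ids)):
            mat = mat.T.tocsr()  # stored genes x cells; flip to cells x genes
        else:
            raise QCError(
                f"matrix {counts_path} has shape {mat.shape} but gene id file "
                f"{genes_path} lists {len(gene_ids)} genes and cell id file "
                f"{cells_path} lists {len(cell_ids)} cells"
            )
        x = mat
        values = mat.data
    elif fmt == "delimited":
        sep = "," if counts_path.suffix == ".csv" else "\t"
        df = pd.read_csv(counts_path, sep=sep, index_col=0)
        cell_ids = [str(c) for c in df.index]
        gene_ids = [str(g) for g in df.columns]
        x = df.to_numpy()
        values = x.ravel()
    else:
        raise QCError(f"unknown format {fmt!r}")

    if not np.allclose(values, np.round(values)):
        raise QCError(f"raw counts in {counts_path} contain non-integer entries")
    if np.any(values < 0):
        raise QCError(f"raw counts in {counts_path} contain negative entries")
    if len(set(cell_ids)) != len(cell_ids):
        raise QCError("cell ids are not unique")
    if len(set(gene_ids)) != len(gene_ids):
        raise QCError("gene ids are not unique")

    adata = AnnData(
        X=np.asarray(x, dtype=np.float64) if not sp.issparse(x) else x.astype(np.float64),
        obs=pd.DataFrame(index=pd.Index(cell_ids, name="cell_id")),
        var=pd.DataFrame(index=pd.Index(gene_ids, name="gene_id")),
    )
    if cell_meta_path is not None:
        meta = pd.read_csv(cell_meta_path, sep="\t", index_col=0)
        if "batch" not in meta.columns:
            raise QCError(f"cell metadata {cell_meta_path} lacks required column 'batch'")
        missing = adata.obs_names.difference(meta.index)
        if len(missing):
            raise QCError(f"cell metadata {cell_meta_path} misses {len(missing)} cells")
        for col in meta.columns:
            adata.obs[col] = meta.loc[adata.obs_names, col].values
    annotate_genes(adata, mito_regex=mito_regex, ercc_prefix=ercc_prefix)
    adata.uns["normalized"] = False
    return adata


def annotate_genes(
    adata: AnnData,
    mito_regex: str = MITO_REGEX_DEFAULT,
    ercc_prefix: str = ERCC_PREFIX_DEFAULT,
) -> AnnData:
    """Flag mitochondrial genes (case-insensitive prefix regex, accepts
    mt-/MT-/Mt-) and ERCC spike-ins (literal prefix) in ``var``."""
    pat = re.compile(mito_regex, re.IGNORECASE)
    names = adata.var_names.astype(str)
    adata.var["is_mito"] = np.array([bool(pat.match(n)) for n in names])
    adata.var["is_ercc"] = np.array([n.startswith(ercc_prefix) for n in names])
    return adata


def qc_metrics(adata: AnnData) -> pd.DataFrame:
    """Per-cell mito fraction (of non-spike counts), ERCC fraction (of all
    counts) and detected non-spike gene count, computed on raw counts."""
    if "is_mito" not in adata.var or "is_ercc" not in adata.var:
        annotate_genes(adata)
    x = adata.layers["raw"] if "raw" in adata.layers else adata.X
    x = _dense(x)
    is_ercc = adata.var["is_ercc"].to_numpy()
    is_mito = adata.var["is_mito"].to_numpy()
    total_all = x.sum(axis=1)
    bio = x[:, ~is_ercc]
    total_bio = bio.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total_bio > 0, x[:, is_mito].sum(axis=1) / total_bio, 0.0)
        ercc_frac = np.where(total_all > 0, x[:, is_ercc].sum(axis=1) / total_all, 0.0)
    n_genes = (bio > 0).sum(axis=1)
    return pd.DataFrame(
        {
            "mito_fraction": mito_frac,
            "ercc_fraction": ercc_frac,
            "n_genes_detected": n_genes,
            "total_counts": total_bio,
        },
        index=adata.obs_names,
    )


def filter_cells(adata: AnnData, cfg: QCConfig | None = None) -> tuple[AnnData, QCReport]:
    """Apply the three cell filters; returns a filtered copy plus a report.

    Removal rules: mito fraction ``>`` threshold, ERCC fraction ``>=``
    threshold, detected genes ``<`` minimum.  Genes are untouched unless
    ``cfg.drop_zero_genes``.  Idempotent.  Raises :class:`QCError` if no
    cell survives.
    """
    cfg = cfg or QCConfig()
    annotate_genes(adata, cfg.mito_regex, cfg.ercc_prefix)
    metrics = qc_metrics(adata)
    fail_mito = metrics["mito_fraction"].to_numpy() > cfg.max_mito_fraction
    fail_ercc = metrics["ercc_fraction"].to_numpy() >= cfg.max_ercc_fraction
    fail_genes = metrics["n_genes_detected"].to_numpy() < cfg.min_genes
    keep = ~(fail_mito | fail_ercc | fail_genes)

    report = QCReport(
        n_cells_in=adata.n_obs,
        n_cells_kept=int(keep.sum()),
        n_genes_in=adata.n_vars,
        n_failed_mito=int(fail_mito.sum()),
        n_failed_ercc=int(fail_ercc.sum()),
        n_failed_min_genes=int(fail_genes.sum()),
    )
    report.removal_counts = {
        "mito": report.n_failed_mito,
        "ercc": report.n_failed_ercc,
        "min_genes": report.n_failed_min_genes,
    }
    if not keep.any():
        raise QCError("no cell passed quality control", report=report)

    out = adata[keep].copy()
    for col in metrics.columns:
        out.obs[col] = metrics.loc[keep, col].values
    if cfg.drop_zero_genes:
        gene_keep = np.asarray(_dense(out.X).sum(axis=0) > 0)
        out = out[:, gene_keep].copy()
    report.n_genes_kept = out.n_vars
    return out, report


def normalize_total(adata: AnnData, target_total: float | None = None) -> AnnData:
    """Scale each cell so its non-spike total equals ``target_total``
    (median of per-cell totals when ``None``).  Raw counts are preserved in
    ``layers["raw"]``; spike-in columns are excluded from the total but
    scaled by the same per-cell factor.
    """
    if adata.uns.get("normalized", False):
        raise QCError("matrix is already normalized")
    annotate_genes(adata) if "is_ercc" not in adata.var else None
    x = _dense(adata.X).astype(np.float64)
    is_ercc = adata.var["is_ercc"].to_numpy()
    totals = x[:, ~is_ercc].sum(axis=1)
    if np.any(totals <= 0):
        bad = list(adata.obs_names[totals <= 0][:5])
        raise QCError(f"cells with zero non-spike totals cannot be normalized: {bad}")
    if target_total is None:
        target_total = float(np.median(totals))
    if target_total <= 0:
        raise QCError("target_total must be positive")
    out = adata.copy()
    out.layers["raw"] = x.copy()
    factors = target_total / totals
    out.X = x * factors[:, None]
    out.obs["norm_factor"] = factors
    out.uns["normalized"] = True
    out.uns["target_total"] = float(target_total)
    return out


def log1p_layer(adata: AnnData, layer_out: str = "lognorm") -> AnnData:
    """Record log1p of the normalized matrix in ``layers[layer_out]``.

    The log transform is an explicit, optional step: rank-based marker
    tests are invariant to it but PCA is not, so embeddings default to the
    log layer while dot-plot style summaries use plain normalized means.
    """
    if not adata.uns.get("normalized", False):
        raise QCError("log1p_layer expects a normalized matrix")
    adata.layers[layer_out] = np.log1p(_dense(adata.X))
    return adata


def get_values(adata: AnnData, layer: str | None = None) -> np.ndarray:
    """Dense cells x genes view of ``X`` or a layer."""
    x = adata.X if layer is None else adata.layers[layer]
    return _dense(x)
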