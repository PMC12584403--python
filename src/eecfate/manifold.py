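"""Highly-variable genes, PCA, (batch-balanced) kNN graphs, clustering,
2-D/10-D embeddings and per-cluster expression summaries.

The neighbor graph is the single structure every downstream stage consumes:
PAGA-style cluster connectivity, diffusion pseudotime and the Markov fate
chain all run on :class:`NeighborGraph`.  Edge weights use a Gaussian
kernel with per-node adaptive bandwidth (distance to the k-th neighbor), so
they stay in (0, 1] and decay smoothly with distance.

Community detection and manifold layout are treated as pluggable backends
(leidenalg / umap-learn): the contract is only determinism given a seed and
modularity maximization at a resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EmbeddingConfig",
    "NeighborGraph",
    "select_hvg",
    "pca_embed",
    "knn_graph",
    "batch_balanced_neighbors",
    "cluster_graph",
    "cluster_at_n",
    "subcluster",
    "embed_2d",
    "summarize_by_cluster",
]


@dataclass
class EmbeddingConfig:
    """Defaults follow the plate-based settings: a 15-nearest-neighbor graph
    on the first 15 principal components of the highly variable genes, with
    batch-balanced neighbors when several stages/batches are pooled; the
    fate-simulation graph instead uses k=10 on a 10-dimensional embedding."""

    n_hvg: int = 1000
    n_pcs: int = 15
    k_neighbors: int = 15
    batch_balanced: bool = False
    n_embed_dims: int = 2
    cluster_resolutions: tuple = (1.0,)
    random_seed: int = 0


@dataclass
class NeighborGraph:
    """Directed neighbor lists plus the symmetrized weighted adjacency."""

    neighbor_lists: list  # per node, np.ndarray of neighbor indices
    connectivities: "scipy.sparse.csr_matrix"  # symmetric, weights in (0, 1]
    provenance: str = "knn"
    k: int = 0

    @property
    def n_obs(self) -> int:
        return self.connectivities.shape[0]

    def edge_list(self) -> pd.DataFrame:
        coo = self.connectivities.tocoo()
        mask = coo.row < coo.col
        return pd.DataFrame(
            {"cell_i": coo.row[mask], "cell_j": coo.col[mask], "weight": coo.data[mask]}
        )


def select_hvg(values: np.ndarray, n_hvg: int, n_bins: int = 20) -> np.ndarray:
    """Rank genes by mean-binned normalized dispersion; return the indices
    of the top ``n_hvg``.

    Dispersion is variance/mean; within each of ``n_bins`` equal-count mean
    bins it is z-scored so highly expressed genes do not dominate.  Genes
    with zero variance are never selected ahead of any variable gene.
    """
    values = np.asarray(values, dtype=np.float64)
    n_genes = values.shape[1]
    if n_hvg > n_genes:
        raise ValueError(f"n_hvg={n_hvg} exceeds the {n_genes} available genes")
    mean = values.mean(axis=0)
    var = values.var(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / np.maximum(mean, 1e-12), 0.0)

    # equal-width bins on the mean so equal-mean genes share a bin
    lo, hi = mean.min(), mean.max()
    if hi > lo:
        edges = np.linspace(lo, hi, n_bins + 1)
        bins = np.clip(np.digitize(mean, edges[1:-1]), 0, n_bins - 1)
    else:
        bins = np.zeros(n_genes, dtype=int)
    norm_disp = np.zeros(n_genes)
    for b in np.unique(bins):
        idx = bins == b
        d = disp[idx]
        s = d.std()
        norm_disp[idx] = (d - d.mean()) / s if s > 0 else 0.0
    norm_disp[var == 0] = -np.inf  # constant genes carry no information
    ranking = np.lexsort((np.arange(n_genes), -norm_disp))
    return np.sort(ranking[:n_hvg])


def pca_embed(
    values: np.ndarray, n_pcs: int, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Centered PCA; returns (coords, explained_variance_ratio).

    Columns are ordered by decreasing explained variance and the sign of
    each component is fixed (largest-magnitude loading positive) so runs
    are reproducible.  Raises if ``n_pcs`` exceeds the matrix rank.
    """
    from sklearn.decomposition import PCA

    values = np.asarray(values, dtype=np.float64)
    n, g = values.shape
    if n_pcs > min(n, g):
        raise ValueError(f"n_pcs={n_pcs} exceeds min(n_cells, n_genes)={min(n, g)}")
    solver = "full" if min(n, g) <= 1500 else "randomized"
    pca = PCA(n_components=min(n, g) if solver == "full" else n_pcs,
              svd_solver=solver, random_state=seed)
    coords = pca.fit_transform(values)
    sv = pca.singular_values_
    rank = int((sv > sv[0] * max(n, g) * np.finfo(float).eps).sum()) if sv[0] > 0 else 0
    if n_pcs > rank:
        raise ValueError(f"n_pcs={n_pcs} exceeds the data rank {rank}")
    coords = coords[:, :n_pcs]
    comps = pca.components_[:n_pcs]
    signs = np.sign(comps[np.arange(n_pcs), np.abs(comps).argmax(axis=1)])
    signs[signs == 0] = 1.0
    return coords * signs, pca.explained_variance_ratio_[:n_pcs]


def _pairwise_sq_dists(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    d = (a * a).sum(1)[:, None] + (b * b).sum(1)[None, :] - 2.0 * (a @ b.T)
    return np.maximum(d, 0.0)


def _rank_neighbors(coords: np.ndarray, query: np.ndarray, pool: np.ndarray, k: int):
    """k nearest (by Euclidean distance, ties broken by cell index) of each
    query cell among ``pool``, excluding the query itself."""
    d2 = _pairwise_sq_dists(coords[query], coords[pool])
    for r, q in enumerate(query):
        hit = np.nonzero(pool == q)[0]
        if hit.size:
            d2[r, hit[0]] = np.inf
    # stable argsort on distance; pool assumed sorted ascending so index
    # order breaks ties
    order = np.argsort(d2, axis=1, kind="stable")[:, :k]
    nbr = pool[order]
    dist = np.sqrt(np.take_along_axis(d2, order, axis=1))
    return nbr, dist


def _assemble_graph(n: int, neighbor_lists, dists, provenance: str, k: int) -> NeighborGraph:
    import scipy.sparse as sp

    # adaptive bandwidth: distance to the farthest selected neighbor
    sigma = np.array([max(float(np.max(d)), 1e-12) if len(d) else 1.0 for d in dists])
    rows, cols, vals = [], [], []
    for i, (nbrs, d) in enumerate(zip(neighbor_lists, dists)):
        w = np.exp(-(d ** 2) / (sigma[i] * sigma[nbrs]))
        rows.append(np.full(len(nbrs), i))
        cols.append(nbrs)
        vals.append(np.maximum(w, 1e-300))
    a = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    conn = a.maximum(a.T)  # union symmetrization keeps weights in (0, 1]
    return NeighborGraph(neighbor_lists=list(neighbor_lists), connectivities=conn,
                         provenance=provenance, k=k)


def knn_graph(coords: np.ndarray, k: int) -> NeighborGraph:
    """Euclidean kNN graph; symmetrized union with adaptive Gaussian weights."""
    coords = np.asarray(coords, dtype=np.float64)
    n = coords.shape[0]
    if not 1 <= k < n:
        raise ValueError(f"k={k} must satisfy 1 <= k < n_cells={n}")
    everyone = np.arange(n)
    nbr, dist = _rank_neighbors(coords, everyone, everyone, k)
    return _assemble_graph(n, list(nbr), list(dist), "knn", k)


def batch_balanced_neighbors(
    coords: np.ndarray, batches, k_per_batch: int
) -> NeighborGraph:
    """Each cell's neighbor list is the union over batches of its
    ``k_per_batch`` nearest cells within that batch, then symmetrized;
    with a single batch this reduces exactly to :func:`knn_graph`."""
    coords = np.asarray(coords, dtype=np.float64)
    batches = np.asarray(batches)
    n = coords.shape[0]
    uniq = np.unique(batches)
    for b in uniq:
        size = int((batches == b).sum())
        if size < k_per_batch + 1:
            raise ValueError(
                f"batch {b!r} has {size} cells; needs at least {k_per_batch + 1}"
            )
    nbr_lists = [[] for _ in range(n)]
    dist_lists = [[] for _ in range(n)]
    everyone = np.arange(n)
    for b in uniq:
        pool = everyone[batches == b]
        nbr, dist = _rank_neighbors(coords, everyone, pool, k_per_batch)
        for i in range(n):
            nbr_lists[i].append(nbr[i])
            dist_lists[i].append(dist[i])
    merged_n, merged_d = [], []
    for i in range(n):
        nb = np.concatenate(nbr_lists[i])
        dd = np.concatenate(dist_lists[i])
        order = np.argsort(nb, kind="stable")
        merged_n.append(nb[order])
        merged_d.append(dd[order])
    g = _assemble_graph(n, merged_n, merged_d, "bbknn", k_per_batch)
    return g


def cluster_graph(graph: NeighborGraph, resolution: float = 1.0, seed: int = 0) -> np.ndarray:
    """Modularity-maximizing community detection on the weighted graph
    (Leiden backend), deterministic given the seed; labels contiguous from
    0, ordered by decreasing cluster size."""
    import igraph as ig
    import leidenalg

    coo = graph.connectivities.tocoo()
    mask = coo.row < coo.col
    g = ig.Graph(
        n=graph.n_obs,
        edges=list(zip(coo.row[mask].tolist(), coo.col[mask].tolist())),
        edge_attrs={"weight": coo.data[mask].tolist()},
    )
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=-1,
    )
    labels = np.asarray(part.membership)
    # relabel by decreasing size, ties by first occurrence
    sizes = np.bincount(labels)
    order = np.lexsort((np.arange(sizes.size), -sizes))
    remap = np.empty(sizes.size, dtype=int)
    remap[order] = np.arange(sizes.size)
    return remap[labels]


def cluster_at_n(
    graph: NeighborGraph,
    n_clusters: int,
    seed: int = 0,
    res_lo: float = 1e-3,
    res_hi: float = 5.0,
    max_iter: int = 40,
) -> np.ndarray:
    """Bisection on the resolution parameter targeting a given number of
    communities (useful when the number of populations is known, as in
    recovery experiments).  Among partitions with exactly the requested
    count the one with the highest plain weighted modularity is returned;
    if none is found, the closest count wins."""
    import igraph as ig

    coo = graph.connectivities.tocoo()
    mask = coo.row < coo.col
    g = ig.Graph(
        n=graph.n_obs,
        edges=list(zip(coo.row[mask].tolist(), coo.col[mask].tolist())),
        edge_attrs={"weight": coo.data[mask].tolist()},
    )

    def modularity(labels):
        return g.modularity(labels.tolist(), weights="weight")

    exact, fallback, fallback_gap = {}, None, np.inf
    lo, hi = res_lo, res_hi
    first_exact = None
    for _ in range(max_iter):
        res = np.sqrt(lo * hi)
        labels = cluster_graph(graph, resolution=res, seed=seed)
        n = labels.max() + 1
        if n == n_clusters:
            exact[res] = labels
            if first_exact is None:
                first_exact = res
            break
        if n < n_clusters:
            lo = res
        else:
            hi = res
        gap = abs(n - n_clusters)
        if gap < fallback_gap:
            fallback, fallback_gap = labels, gap
        if hi / lo < 1.02:
            break
    if first_exact is not None:
        # probe nearby resolutions: several partitions may have the right
        # count and they can differ; keep the most modular one
        for f in (0.5, 0.67, 0.85, 1.2, 1.5, 2.0, 3.0):
            res = first_exact * f
            labels = cluster_graph(graph, resolution=res, seed=seed)
            if labels.max() + 1 == n_clusters:
                exact[res] = labels
        return max(exact.values(), key=modularity)
    return fallback


def subcluster(
    graph: NeighborGraph,
    labels: np.ndarray,
    target_label: int,
    resolution: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Re-cluster the cells of one label on the induced subgraph and splice
    the refined labels back (new labels appended after the existing ones)."""
    labels = np.asarray(labels)
    mask = labels == target_label
    if mask.sum() < 2:
        return labels.copy()
    sub = graph.connectivities[mask][:, mask].tocsr()
    subgraph = NeighborGraph(
        neighbor_lists=[np.array([], dtype=int)] * int(mask.sum()),
        connectivities=sub,
        provenance=f"{graph.provenance}[subset]",
        k=graph.k,
    )
    sub_labels = cluster_graph(subgraph, resolution=resolution, seed=seed)
    out = labels.copy()
    base = labels.max() + 1
    refined = np.where(sub_labels == 0, target_label, base + sub_labels - 1)
    out[mask] = refined
    return out


def embed_2d(
    coords: np.ndarray,
    n_dims: int = 2,
    seed: int = 0,
    n_neighbors: int = 15,
    min_dist: float = 0.5,
) -> np.ndarray:
    """UMAP layout of the expression coordinates (2-D for viewing, 10-D for
    the fate-simulation graph); deterministic given the seed."""
    import umap

    reducer = umap.UMAP(
        n_components=n_dims,
        n_neighbors=n_neighbors,
        min_dist=min_dist,
        random_state=seed,
    )
    return np.asarray(reducer.fit_transform(np.asarray(coords, dtype=np.float64)))


def summarize_by_cluster(
    values: np.ndarray,
    labels: np.ndarray,
    gene_names,
    scale01: bool = False,
) -> pd.DataFrame:
    """Mean (normalized) expression and expressing fraction per
    cluster x gene, long format; with ``scale01`` the means are min-max
    scaled to [0, 1] per gene across clusters (heatmap convention)."""
    values = np.asarray(values, dtype=np.float64)
    labels = np.asarray(labels)
    clusters = np.unique(labels)
    for c in clusters:
        if (labels == c).sum() == 0:  # pragma: no cover - unique() precludes
            raise ValueError(f"empty cluster {c}")
    means = np.vstack([values[labels == c].mean(axis=0) for c in clusters])
    fracs = np.vstack([(values[labels == c] > 0).mean(axis=0) for c in clusters])
    if scale01:
        lo, hi = means.min(axis=0), means.max(axis=0)
        rng = hi - lo
        scaled = np.where(rng > 0, (means - lo) / np.where(rng > 0, rng, 1.0), 0.0)
    rows = []
    for ci, c in enumerate(clusters):
        for gi, gname in enumerate(gene_names):
            row = {
                "cluster": c,
                "gene": gname,
                "mean_expression": means[ci, gi],
                "frac_expressing": fracs[ci, gi],
            }
            if scale01:
                row["scaled_mean"] = scaled[ci, gi]
            rows.append(row)
    return pd.DataFrame(rows)
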