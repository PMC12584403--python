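"""Cluster-level lineage abstraction and diffusion pseudotime.

``paga_connectivity`` scores each cluster pair by the observed number of
inter-cluster edges relative to its expectation under random edge
allocation given cluster degrees (configuration-model null); values near 1
mean "as connected as random", and the confidence reported to users is the
ratio clipped to [0, 1].

Diffusion pseudotime orders cells by Euclidean distance from a root cell in
eigenvalue-rescaled diffusion-map coordinates: component i is weighted by
lambda_i / (1 - lambda_i), so slowly decaying (large-scale) components
dominate.  The root is, by default, the most central cell of the
progenitor cluster (maximal mean edge weight to its own cluster).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .manifold import NeighborGraph

__all__ = [
    "AbstractGraph",
    "DiffusionMap",
    "PseudotimeField",
    "paga_connectivity",
    "diffusion_map",
    "diffusion_pseudotime",
    "pick_root_cell",
]


@dataclass
class AbstractGraph:
    """Cluster-level connectivity; symmetric tables indexed by cluster."""

    confidence: pd.DataFrame   # clipped to [0, 1]
    ratio: pd.DataFrame        # raw observed / expected
    n_edges: pd.DataFrame      # observed inter-cluster edge counts

    def edge_table(self) -> pd.DataFrame:
        rows = []
        clusters = list(self.confidence.index)
        for i, a in enumerate(clusters):
            for b in clusters[i + 1:]:
                rows.append(
                    {
                        "cluster_a": a,
                        "cluster_b": b,
                        "confidence": self.confidence.loc[a, b],
                        "n_edges": self.n_edges.loc[a, b],
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class DiffusionMap:
    coords: np.ndarray        # cells x n_components, nontrivial components
    eigenvalues: np.ndarray   # descending, leading (trivial) value included
    n_trivial: int            # leading eigenvalues ~1 (one per component)


@dataclass
class PseudotimeField:
    root: int
    pseudotime: np.ndarray    # >= 0; inf for cells unreachable from root


def paga_connectivity(graph: NeighborGraph, labels) -> AbstractGraph:
    """Partition-based graph abstraction connectivity between clusters."""
    labels = np.asarray(labels)
    clusters = np.unique(labels)
    if len(clusters) < 2:
        raise ValueError("paga_connectivity needs at least 2 clusters")
    adj = (graph.connectivities > 0).astype(np.int64)
    adj.setdiag(0)
    adj.eliminate_zeros()
    total_edges = adj.sum() / 2.0
    k = len(clusters)
    obs = np.zeros((k, k))
    deg = np.asarray(adj.sum(axis=1)).ravel()
    cluster_deg = np.array([deg[labels == c].sum() for c in clusters])
    if total_edges == 0:
        warnings.warn("graph has no edges; connectivity is all zero")
        ratio = np.zeros((k, k))
    else:
        member = np.vstack([(labels == c).astype(np.int64) for c in clusters])
        inter = member @ adj @ member.T  # cluster x cluster edge-endpoint counts
        obs = inter - np.diag(np.diag(inter))
        expected = np.outer(cluster_deg, cluster_deg) / (2.0 * total_edges)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(expected > 0, obs / expected, 0.0)
        ratio[obs == 0] = 0.0
    np.fill_diagonal(ratio, 0.0)
    conf = np.clip(ratio, 0.0, 1.0)
    idx = pd.Index(clusters, name="cluster")
    return AbstractGraph(
        confidence=pd.DataFrame(conf, index=idx, columns=idx),
        ratio=pd.DataFrame(ratio, index=idx, columns=idx),
        n_edges=pd.DataFrame(obs, index=idx, columns=idx, dtype=int),
    )


def diffusion_map(graph: NeighborGraph, n_components: int = 15) -> DiffusionMap:
    """Spectral decomposition of the symmetric-normalized transition kernel
    built from the edge weights; deterministic up to the fixed sign
    convention (largest-magnitude entry positive)."""
    w = graph.connectivities.astype(np.float64)
    n = w.shape[0]
    if n_components >= n:
        raise ValueError(f"n_components={n_components} must be < n_cells={n}")
    d = np.asarray(w.sum(axis=1)).ravel()
    d_safe = np.where(d > 0, d, 1.0)
    d_inv_sqrt = 1.0 / np.sqrt(d_safe)
    m_sym = sp.diags(d_inv_sqrt) @ w @ sp.diags(d_inv_sqrt)

    k = n_components + 1  # keep the trivial stationary component too
    if n <= 512 or k >= n - 1:
        vals, vecs = np.linalg.eigh(np.asarray(m_sym.todense()))
        vals, vecs = vals[::-1], vecs[:, ::-1]
        vals, vecs = vals[:k], vecs[:, :k]
    else:
        from scipy.sparse.linalg import eigsh

        vals, vecs = eigsh(m_sym.tocsc(), k=k, which="LA")
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]

    # right eigenvectors of the row-stochastic kernel, normalized so the
    # trivial component is the constant 1 (scale-free in the edge weights)
    psi = vecs * d_inv_sqrt[:, None] * np.sqrt(d.sum())
    signs = np.sign(psi[np.abs(psi).argmax(axis=0), np.arange(psi.shape[1])])
    signs[signs == 0] = 1.0
    psi = psi * signs
    n_trivial = int(np.sum(vals > 1.0 - 1e-10))
    n_trivial = max(n_trivial, 1)
    return DiffusionMap(coords=psi[:, n_trivial:], eigenvalues=vals, n_trivial=n_trivial)


def diffusion_pseudotime(
    dmap: DiffusionMap, root: int, graph: NeighborGraph | None = None
) -> PseudotimeField:
    """Distance from the root in lambda/(1-lambda)-rescaled diffusion
    coordinates; cells in a different connected component than the root are
    flagged infinite (requires ``graph`` to detect components)."""
    lam = dmap.eigenvalues[dmap.n_trivial:]
    keep = lam < 1.0 - 1e-10
    lam = np.clip(lam[keep], None, 1.0 - 1e-12)
    coords = dmap.coords[:, keep] * (lam / (1.0 - lam))[None, :]
    diff = coords - coords[root]
    pt = np.sqrt((diff ** 2).sum(axis=1))
    pt[root] = 0.0
    if graph is not None:
        n_comp, comp = connected_components(graph.connectivities, directed=False)
        if n_comp > 1:
            pt = np.where(comp == comp[root], pt, np.inf)
    return PseudotimeField(root=int(root), pseudotime=pt)


def pick_root_cell(graph: NeighborGraph, labels, progenitor_label) -> int:
    """Most central progenitor: the cell of the progenitor cluster with the
    largest mean edge weight to cells of its own cluster."""
    labels = np.asarray(labels)
    mask = labels == progenitor_label
    if not mask.any():
        raise ValueError(f"no cell carries label {progenitor_label!r}")
    idx = np.nonzero(mask)[0]
    sub = graph.connectivities[idx][:, idx]
    centrality = np.asarray(sub.sum(axis=1)).ravel()
    return int(idx[int(np.argmax(centrality))])
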