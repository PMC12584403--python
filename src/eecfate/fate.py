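"""Potential-energy-biased Markov-chain fate engine.

Differentiation is modeled as a discrete Markov process on the cell
neighbor graph.  A scalar potential V plays the role of an energy
landscape: V = 1 on progenitor (source) cells, V = 0 on terminal-fate
(sink) cells, and harmonic in between -- every interior cell's potential is
the weighted mean of its neighbors', the solution of the graph-Laplace
boundary problem.  Transitions from a non-absorbing cell i go to its closed
neighborhood with Boltzmann weights exp(-beta * (V(j) - V(i))), so walks
drift downhill at a bias set by the single inverse-temperature parameter
beta; sink cells are absorbing.

Fate probabilities are absorption probabilities of that chain, available
two ways: empirically from Monte Carlo walk ensembles (the route used for
trajectory-averaged dynamic profiles) and exactly from the absorbing-chain
linear system B = (I - Q)^-1 R, which serves as the oracle the simulator is
checked against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.ndimage import uniform_filter1d
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import spsolve

from .manifold import NeighborGraph

__all__ = [
    "PotentialField",
    "MarkovChain",
    "TrajectoryEnsemble",
    "FateProbabilities",
    "DynamicProfile",
    "solve_potential",
    "build_chain",
    "simulate_walks",
    "absorption_exact",
    "fate_from_ensemble",
    "trajectory_profile",
]

UNABSORBED = "unabsorbed"


@dataclass
class PotentialField:
    potential: np.ndarray            # per cell, in [0, 1]
    sources: np.ndarray              # cell indices, V = 1
    sinks: dict                      # fate name -> cell indices, V = 0
    residual: float

    @property
    def sink_cells(self) -> np.ndarray:
        if not self.sinks:
            return np.array([], dtype=int)
        return np.unique(np.concatenate([np.asarray(v, dtype=int) for v in self.sinks.values()]))


@dataclass
class MarkovChain:
    transition: sp.csr_matrix        # row-stochastic, support = N(i) + self
    beta: float
    absorbing: np.ndarray            # boolean mask
    fates: dict                      # fate name -> sink cell indices
    graph: NeighborGraph | None = None

    @property
    def n_states(self) -> int:
        return self.transition.shape[0]


@dataclass
class TrajectoryEnsemble:
    walks: list | None               # per walk, np.ndarray of cell indices
    fate_labels: np.ndarray          # per walk, fate name or "unabsorbed"
    start_cells: np.ndarray
    seed: int
    max_steps: int
    n_iterations: int
    fates: tuple

    @property
    def n_walks(self) -> int:
        return len(self.fate_labels)

    @property
    def n_absorbed(self) -> int:
        return int((self.fate_labels != UNABSORBED).sum())


@dataclass
class FateProbabilities:
    probabilities: pd.DataFrame      # cells x fates
    method: str                      # "empirical" or "exact"
    unabsorbed: np.ndarray | None = None
    se: pd.DataFrame | None = None
    n_visits: np.ndarray | None = None
    low_confidence: np.ndarray | None = None


@dataclass
class DynamicProfile:
    fate: str
    t_grid: np.ndarray               # bin centers in [0, 1]
    mean: np.ndarray
    se: np.ndarray
    n_per_bin: np.ndarray
    smooth_window: int
    n_walks: int


def solve_potential(graph: NeighborGraph, sources, sinks: dict) -> PotentialField:
    """Solve the weighted graph-Laplace (harmonic) boundary problem with
    V = 1 on sources and V = 0 on every sink cell.

    Interior cells must be connected to the boundary; disconnected interior
    cells are reported by index.  The maximum principle guarantees interior
    values strictly inside (0, 1) on connected instances.
    """
    w = graph.connectivities.astype(np.float64).tocsr()
    n = w.shape[0]
    sources = np.unique(np.asarray(sources, dtype=int))
    sinks = {name: np.unique(np.asarray(cells, dtype=int)) for name, cells in sinks.items()}
    if sources.size == 0 or not sinks or all(len(v) == 0 for v in sinks.values()):
        raise ValueError("sources and sinks must both be nonempty")
    sink_cells = np.unique(np.concatenate(list(sinks.values())))
    overlap = np.intersect1d(sources, sink_cells)
    if overlap.size:
        raise ValueError(f"cells {overlap[:5].tolist()} are both source and sink")

    boundary = np.zeros(n, dtype=bool)
    boundary[sources] = True
    boundary[sink_cells] = True
    v = np.zeros(n)
    v[sources] = 1.0

    interior = ~boundary
    if interior.any():
        n_comp, comp = connected_components(w, directed=False)
        boundary_comps = set(comp[boundary])
        stranded = np.nonzero(interior & ~np.isin(comp, list(boundary_comps)))[0]
        if stranded.size:
            raise ValueError(
                f"interior cells disconnected from every source/sink: {stranded[:10].tolist()}"
            )
        d = np.asarray(w.sum(axis=1)).ravel()
        lap = sp.diags(d) - w
        idx_i = np.nonzero(interior)[0]
        idx_b = np.nonzero(boundary)[0]
        a = lap[idx_i][:, idx_i].tocsc()
        rhs = -lap[idx_i][:, idx_b] @ v[idx_b]
        v[idx_i] = spsolve(a, rhs)

    residual = 0.0
    if interior.any():
        res_vec = (sp.diags(np.asarray(w.sum(axis=1)).ravel()) @ v - w @ v)[interior]
        residual = float(np.max(np.abs(res_vec)))
    v = np.clip(v, 0.0, 1.0)
    v[sources] = 1.0
    v[sink_cells] = 0.0
    return PotentialField(potential=v, sources=sources, sinks=sinks, residual=residual)


def build_chain(graph: NeighborGraph, potential: PotentialField, beta: float = 10.0) -> MarkovChain:
    """Boltzmann transition chain: P(i->j) proportional to
    exp(-beta (V(j) - V(i))) over the closed neighborhood N(i) + {i};
    beta = 0 gives an unbiased walk, large beta a steepest-descent walk.
    Sink cells are absorbing."""
    if beta < 0:
        raise ValueError(f"beta must be >= 0, got {beta}")
    w = graph.connectivities
    n = w.shape[0]
    v = np.asarray(potential.potential, dtype=np.float64)
    if v.shape[0] != n:
        raise ValueError("potential is not defined on every node")
    sink_cells = potential.sink_cells
    absorbing = np.zeros(n, dtype=bool)
    absorbing[sink_cells] = True

    indptr, indices = w.indptr, w.indices
    rows, cols, vals = [], [], []
    for i in range(n):
        if absorbing[i]:
            rows.append(np.array([i]))
            cols.append(np.array([i]))
            vals.append(np.array([1.0]))
            continue
        nbrs = indices[indptr[i]:indptr[i + 1]]
        support = np.append(nbrs, i)
        logits = -beta * (v[support] - v[i])
        logits -= logits.max()  # overflow guard
        p = np.exp(logits)
        p /= p.sum()
        rows.append(np.full(support.size, i))
        cols.append(support)
        vals.append(p)
    p = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))), shape=(n, n)
    )
    return MarkovChain(transition=p, beta=float(beta), absorbing=absorbing,
                       fates=potential.sinks, graph=graph)


def _fate_of_state(chain: MarkovChain) -> dict:
    lookup = {}
    for fate, cells in chain.fates.items():
        for c in np.asarray(cells, dtype=int):
            lookup[int(c)] = fate
    return lookup


def simulate_walks(
    chain: MarkovChain,
    start_cells,
    n_iterations: int = 1500,
    max_steps: int | None = None,
    seed: int = 0,
    record_paths: bool = True,
) -> TrajectoryEnsemble:
    """Monte Carlo ensemble of ``n_iterations`` walks (the "iterations" of
    the stochastic simulation), each from a uniformly drawn start cell,
    stepping by the chain until absorption or ``max_steps``; bit-for-bit
    reproducible from the seed.  ``record_paths=False`` keeps only the
    absorbing fate of each walk (cheap large-ensemble mode)."""
    start_cells = np.asarray(start_cells, dtype=int)
    if start_cells.size == 0:
        raise ValueError("start_cells is empty")
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    n = chain.n_states
    if max_steps is None:
        max_steps = 10 * n
    rng = np.random.default_rng(seed)
    dense_p = np.asarray(chain.transition.todense())
    cum_p = np.cumsum(dense_p, axis=1)
    cum_p[:, -1] = 1.0

    states = rng.choice(start_cells, size=n_iterations, replace=True)
    fate_lookup = _fate_of_state(chain)
    paths = [[int(s)] for s in states] if record_paths else None
    active = ~chain.absorbing[states]
    final = states.copy()
    for _ in range(max_steps):
        if not active.any():
            break
        idx = np.nonzero(active)[0]
        u = rng.random(idx.size)
        rows = cum_p[final[idx]]
        nxt = (rows < u[:, None]).sum(axis=1)
        final[idx] = nxt
        if record_paths:
            for w_i, s in zip(idx, nxt):
                paths[w_i].append(int(s))
        active[idx] = ~chain.absorbing[nxt]
    fate_labels = np.array(
        [fate_lookup.get(int(s), UNABSORBED) if not a else UNABSORBED
         for s, a in zip(final, active)],
        dtype=object,
    )
    if record_paths:
        paths = [np.asarray(p, dtype=np.int64) for p in paths]
    return TrajectoryEnsemble(
        walks=paths,
        fate_labels=fate_labels,
        start_cells=start_cells,
        seed=int(seed),
        max_steps=int(max_steps),
        n_iterations=int(n_iterations),
        fates=tuple(chain.fates.keys()),
    )


def absorption_exact(chain: MarkovChain, cell_names=None) -> FateProbabilities:
    """Exact per-cell absorption probabilities from the fundamental-matrix
    system B = (I - Q)^-1 R (sparse solve); rows over fates sum to 1 for
    every transient cell, sink cells are one-hot."""
    p = chain.transition.tocsr()
    n = chain.n_states
    absorbing = chain.absorbing
    transient = np.nonzero(~absorbing)[0]
    fates = list(chain.fates.keys())
    out = np.zeros((n, len(fates)))
    for fi, fate in enumerate(fates):
        out[np.asarray(chain.fates[fate], dtype=int), fi] = 1.0
    if transient.size:
        q = p[transient][:, transient]
        system = sp.identity(transient.size, format="csc") - q.tocsc()
        for fi, fate in enumerate(fates):
            sink_idx = np.asarray(chain.fates[fate], dtype=int)
            r = p[transient][:, sink_idx]
            b = spsolve(system, np.asarray(r.sum(axis=1)).ravel())
            out[transient, fi] = b
        row_sums = out[transient].sum(axis=1)
        bad = transient[~(row_sums > 1.0 - 1e-6)]  # catches NaN from singular systems
        if bad.size:
            raise ValueError(
                f"transient cells cannot reach any sink: {bad[:10].tolist()}"
            )
        out[transient] /= row_sums[:, None]
    index = pd.Index(cell_names if cell_names is not None else np.arange(n), name="cell")
    probs = pd.DataFrame(out, index=index, columns=fates)
    return FateProbabilities(probabilities=probs, method="exact")


def fate_from_ensemble(
    ensemble: TrajectoryEnsemble,
    n_cells: int,
    min_visits: int = 10,
    cell_names=None,
) -> FateProbabilities:
    """Visiting-walk estimator: a cell's probability for fate F is the
    fraction of absorbed walks passing through it that end in F.  Cells
    never visited are NaN (undefined), cells visited by fewer than
    ``min_visits`` walks are flagged low-confidence; unabsorbed walks carry
    no absorption information and are excluded."""
    if ensemble.walks is None:
        raise ValueError("ensemble was simulated without recorded paths")
    if ensemble.n_walks == 0:
        raise ValueError("ensemble is empty")
    fates = list(ensemble.fates)
    counts = np.zeros((n_cells, len(fates)))
    visits = np.zeros(n_cells, dtype=np.int64)
    for walk, fate in zip(ensemble.walks, ensemble.fate_labels):
        if fate == UNABSORBED:
            continue
        cells = np.unique(walk)
        visits[cells] += 1
        counts[cells, fates.index(fate)] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = counts / visits[:, None]
        se = np.sqrt(np.clip(probs * (1 - probs), 0, None) / np.maximum(visits[:, None], 1))
    probs[visits == 0] = np.nan
    se[visits == 0] = np.nan
    index = pd.Index(cell_names if cell_names is not None else np.arange(n_cells), name="cell")
    return FateProbabilities(
        probabilities=pd.DataFrame(probs, index=index, columns=fates),
        method="empirical",
        se=pd.DataFrame(se, index=index, columns=fates),
        n_visits=visits,
        low_confidence=visits < min_visits,
    )


def trajectory_profile(
    ensemble: TrajectoryEnsemble,
    per_cell_values: np.ndarray,
    fate: str,
    n_grid: int = 50,
    smooth_window: int = 5,
    min_walks: int = 10,
) -> DynamicProfile:
    """Average a per-cell quantity (gene expression or TF activity) over
    the walks absorbed in ``fate``: each walk is rescaled to t in [0, 1] by
    step index / walk length, values are pooled in ``n_grid`` bins and the
    bin means are smoothed with a centered moving average."""
    values = np.asarray(per_cell_values, dtype=np.float64)
    if ensemble.walks is None:
        raise ValueError("ensemble was simulated without recorded paths")
    walks = [w for w, f in zip(ensemble.walks, ensemble.fate_labels) if f == fate]
    if len(walks) == 0:
        raise ValueError(f"no walk was absorbed in fate {fate!r}")
    if len(walks) < min_walks:
        raise ValueError(
            f"only {len(walks)} walks absorbed in {fate!r}; min_walks={min_walks}"
        )
    sums = np.zeros(n_grid)
    sq_sums = np.zeros(n_grid)
    counts = np.zeros(n_grid, dtype=np.int64)
    for walk in walks:
        length = len(walk)
        t = np.linspace(0.0, 1.0, length) if length > 1 else np.array([1.0])
        bins = np.minimum((t * n_grid).astype(int), n_grid - 1)
        vals = values[walk]
        np.add.at(sums, bins, vals)
        np.add.at(sq_sums, bins, vals ** 2)
        np.add.at(counts, bins, 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        var = np.where(
            counts > 1,
            (sq_sums - counts * mean ** 2) / np.maximum(counts - 1, 1),
            0.0,
        )
        se = np.sqrt(np.clip(var, 0, None) / np.maximum(counts, 1))
    # fill empty bins by nearest populated neighbor before smoothing
    if np.isnan(mean).any():
        filled = np.nonzero(~np.isnan(mean))[0]
        mean = np.interp(np.arange(n_grid), filled, mean[filled])
    if smooth_window > 1:
        mean = uniform_filter1d(mean, size=smooth_window, mode="nearest")
        se = uniform_filter1d(se, size=smooth_window, mode="nearest")
    t_grid = (np.arange(n_grid) + 0.5) / n_grid
    return DynamicProfile(
        fate=fate, t_grid=t_grid, mean=mean, se=se, n_per_bin=counts,
        smooth_window=int(smooth_window), n_walks=len(walks),
    )
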