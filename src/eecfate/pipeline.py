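"""End-to-end orchestration: qc -> embed -> markers -> lineage -> fate ->
motifs -> report, from a single YAML-able config, with per-stage JSON
manifests and content-hash bookkeeping (a stage whose parameters and
upstream inputs are unchanged leaves its on-disk outputs untouched, so
repeated runs produce byte-identical artifacts).

Every stage seed derives deterministically from the global seed, so a run
is reproducible end to end.  The input is either a synthetic-dataset
section (the generator writes the same formats the real pipeline reads) or
paths to a count matrix and metadata.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import fate as fate_mod
from . import io_qc, lineage, manifold, markers, motifs
from .synthetic import BRANCHES, PROGENITOR, SyntheticConfig, generate_dataset

__all__ = ["default_config", "run", "report", "PipelineError"]

STAGES = ("simulate", "qc", "embed", "markers", "lineage", "fate", "motifs")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str, completed=()):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage
        self.completed = list(completed)


def default_config(out_dir: str, seed: int = 0) -> dict:
    """Synthetic-source configuration exercising every stage."""
    return {
        "out_dir": str(out_dir),
        "seed": int(seed),
        "stages": {s: True for s in STAGES},
        "synthetic": {},
        "qc": {"max_mito_fraction": 0.5, "max_ercc_fraction": 0.5, "min_genes": 200},
        "embed": {
            "n_hvg": 800,
            "n_pcs": 15,
            "k_neighbors": 15,
            "batch_balanced": True,
            "k_per_batch": 8,
            "n_clusters": 4,
        },
        "markers": {"n_top": 20},
        "lineage": {"n_components": 15},
        "fate": {
            "beta": 10.0,
            "n_iterations": 1500,
            "max_steps": None,
            "source_quantile": 0.4,
            "sink_quantile": 0.6,
            "n_grid": 50,
            "smooth_window": 5,
            "min_visits": 10,
        },
        "motifs": {"max_lag_frac": 0.25},
    }


def _hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()


def _stage_dir(out_dir: Path, stage: str) -> Path:
    d = out_dir / stage
    d.mkdir(parents=True, exist_ok=True)
    return d


def _manifest_matches(stage_dir: Path, key: str) -> bool:
    mf = stage_dir / "manifest.json"
    if not mf.exists():
        return False
    try:
        return json.loads(mf.read_text()).get("hash") == key
    except json.JSONDecodeError:
        return False


def _write_manifest(stage_dir: Path, key: str, params, seed: int, outputs) -> None:
    (stage_dir / "manifest.json").write_text(
        json.dumps(
            {"hash": key, "params": params, "seed": seed,
             "outputs": [str(o) for o in outputs]},
            indent=2, default=str,
        )
    )


def _seed_for(global_seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2 ** 31)


def run(config: dict) -> Path:
    """Execute the enabled stages in order; returns the run directory.

    A failing stage raises :class:`PipelineError` naming the stage and the
    manifests of the stages already completed.
    """
    out_dir = Path(config["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    stages = config.get("stages", {s: True for s in STAGES})
    completed = []
    state: dict = {}
    chain_key = _hash({"seed": seed})

    def do(stage, params, fn):
        nonlocal chain_key
        if not stages.get(stage, True):
            return False
        chain_key = _hash({"prev": chain_key, "stage": stage, "params": params})
        sdir = _stage_dir(out_dir, stage)
        cached = _manifest_matches(sdir, chain_key)
        try:
            outputs = fn(sdir, cached)
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001 - surfaced with stage name
            raise PipelineError(stage, str(exc), completed) from exc
        _write_manifest(sdir, chain_key, params, _seed_for(seed, stage), outputs)
        completed.append(stage)
        return True

    # ---- simulate ------------------------------------------------------
    syn_params = config.get("synthetic", {})

    def stage_simulate(sdir, cached):
        cfg = SyntheticConfig(**{**syn_params, "seed": _seed_for(seed, "simulate")})
        ds = generate_dataset(cfg)
        state["ds"] = ds
        state["adata_raw"] = ds.adata
        if not cached:
            ds.adata.write_h5ad(sdir / "counts.h5ad")
            truth_tab = pd.DataFrame(
                {"branch": ds.truth.branch, "pseudotime": ds.truth.pseudotime},
                index=ds.adata.obs_names,
            )
            truth_tab.to_csv(sdir / "ground_truth_cells.tsv", sep="\t")
            ds.truth.sites.to_csv(sdir / "ground_truth_sites.tsv", sep="\t")
            ds.truth.activities.to_csv(sdir / "ground_truth_activities.tsv", sep="\t")
        return ["counts.h5ad", "ground_truth_cells.tsv", "ground_truth_sites.tsv",
                "ground_truth_activities.tsv"]

    if "counts_path" in config:
        from anndata import read_h5ad

        state["adata_raw"] = (
            read_h5ad(config["counts_path"])
            if str(config["counts_path"]).endswith(".h5ad")
            else io_qc.load_counts(
                config["counts_path"],
                genes_path=config.get("genes_path"),
                cells_path=config.get("cells_path"),
                cell_meta_path=config.get("cell_meta_path"),
            )
        )
    else:
        do("simulate", syn_params, stage_simulate)

    # ---- qc ------------------------------------------------------------
    qc_params = config.get("qc", {})

    def stage_qc(sdir, cached):
        cfg = io_qc.QCConfig(**qc_params)
        filtered, rep = io_qc.filter_cells(state["adata_raw"], cfg)
        norm = io_qc.normalize_total(filtered)
        io_qc.log1p_layer(norm)
        state["adata"] = norm
        if not cached:
            rep.to_json(sdir / "qc_report.json")
            norm.write_h5ad(sdir / "normalized.h5ad")
        return ["qc_report.json", "normalized.h5ad"]

    do("qc", qc_params, stage_qc)

    # ---- embed ---------------------------------------------------------
    em = config.get("embed", {})

    def stage_embed(sdir, cached):
        adata = state["adata"]
        bio = ~adata.var["is_ercc"].to_numpy()
        log_vals = io_qc.get_values(adata, "lognorm")[:, bio]
        state["bio_mask"] = bio
        state["log_vals"] = log_vals
        state["gene_names"] = list(adata.var_names[bio])
        s = _seed_for(seed, "embed")
        hvg = manifold.select_hvg(log_vals, min(em.get("n_hvg", 800), log_vals.shape[1]))
        coords, evr = manifold.pca_embed(log_vals[:, hvg], em.get("n_pcs", 15), seed=s)
        batches = (
            adata.obs["batch"].to_numpy()
            if em.get("batch_balanced", False) and "batch" in adata.obs
            else np.zeros(adata.n_obs, dtype=int)
        )
        if len(np.unique(batches)) > 1:
            graph = manifold.batch_balanced_neighbors(coords, batches, em.get("k_per_batch", 8))
        else:
            graph = manifold.knn_graph(coords, em.get("k_neighbors", 15))
        if "n_clusters" in em and em["n_clusters"]:
            labels = manifold.cluster_at_n(graph, em["n_clusters"], seed=s)
        else:
            labels = manifold.cluster_graph(graph, em.get("resolution", 1.0), seed=s)
        state.update(coords=coords, graph=graph, labels=labels)
        if not cached:
            pd.DataFrame(coords, index=adata.obs_names).to_csv(sdir / "pca.tsv", sep="\t")
            pd.Series(labels, index=adata.obs_names, name="cluster").to_csv(
                sdir / "clusters.tsv", sep="\t"
            )
            graph.edge_list().to_csv(sdir / "edges.tsv", sep="\t", index=False)
        return ["pca.tsv", "clusters.tsv", "edges.tsv"]

    do("embed", em, stage_embed)

    # ---- markers -------------------------------------------------------
    mk = config.get("markers", {})

    def stage_markers(sdir, cached):
        labels = state["labels"]
        tables = []
        norm_vals = io_qc.get_values(state["adata"])[:, state["bio_mask"]]
        for c in np.unique(labels):
            if (labels == c).sum() < 2:
                continue
            tab = markers.rank_markers(
                state["log_vals"], labels, c, gene_names=state["gene_names"],
                raw_values=norm_vals,
            )
            tables.append(tab)
        table = pd.concat(tables, ignore_index=True)
        state["markers"] = table
        if not cached:
            table.to_csv(sdir / "markers.tsv", sep="\t", index=False)
        return ["markers.tsv"]

    do("markers", mk, stage_markers)

    # ---- lineage -------------------------------------------------------
    ln = config.get("lineage", {})

    def stage_lineage(sdir, cached):
        graph, labels = state["graph"], state["labels"]
        abstract = lineage.paga_connectivity(graph, labels)
        prog_cluster = _progenitor_cluster(state, config)
        root = lineage.pick_root_cell(graph, labels, prog_cluster)
        dmap = lineage.diffusion_map(graph, ln.get("n_components", 15))
        pt = lineage.diffusion_pseudotime(dmap, root, graph=graph)
        state.update(abstract=abstract, pseudotime=pt, prog_cluster=prog_cluster)
        if not cached:
            abstract.edge_table().to_csv(sdir / "paga.tsv", sep="\t", index=False)
            pd.Series(pt.pseudotime, index=state["adata"].obs_names, name="dpt").to_csv(
                sdir / "pseudotime.tsv", sep="\t"
            )
        return ["paga.tsv", "pseudotime.tsv"]

    do("lineage", ln, stage_lineage)

    # ---- fate ----------------------------------------------------------
    ft = config.get("fate", {})

    def stage_fate(sdir, cached):
        graph, labels = state["graph"], state["labels"]
        pt = state["pseudotime"].pseudotime
        annotation = _annotate(state, config)
        named = np.array([annotation[c] for c in labels], dtype=object)
        prog_mask = named == PROGENITOR
        sources = np.nonzero(
            prog_mask & (pt <= np.quantile(pt[prog_mask], ft.get("source_quantile", 0.4)))
        )[0]
        sinks = {}
        for name in sorted(set(annotation.values()) - {PROGENITOR}):
            mask = named == name
            cut = np.quantile(pt[mask], ft.get("sink_quantile", 0.6))
            sinks[name] = np.nonzero(mask & (pt >= cut))[0]
        potential = fate_mod.solve_potential(graph, sources, sinks)
        chain = fate_mod.build_chain(graph, potential, beta=ft.get("beta", 10.0))
        ensemble = fate_mod.simulate_walks(
            chain, sources, n_iterations=ft.get("n_iterations", 1500),
            max_steps=ft.get("max_steps"), seed=_seed_for(seed, "fate"),
        )
        exact = fate_mod.absorption_exact(chain, cell_names=state["adata"].obs_names)
        empirical = fate_mod.fate_from_ensemble(
            ensemble, chain.n_states, min_visits=ft.get("min_visits", 10),
            cell_names=state["adata"].obs_names,
        )
        state.update(potential=potential, chain=chain, ensemble=ensemble,
                     fate_exact=exact, fate_empirical=empirical, named=named)
        if not cached:
            exact.probabilities.to_csv(sdir / "fate_probabilities.tsv", sep="\t")
            empirical.probabilities.to_csv(sdir / "fate_probabilities_empirical.tsv", sep="\t")
            pd.Series(potential.potential, index=state["adata"].obs_names,
                      name="potential").to_csv(sdir / "potential.tsv", sep="\t")
            with open(sdir / "walks.jsonl", "w") as fh:
                for walk, fl in zip(ensemble.walks, ensemble.fate_labels):
                    fh.write(json.dumps({"fate": fl, "cells": walk.tolist()}) + "\n")
        return ["fate_probabilities.tsv", "fate_probabilities_empirical.tsv",
                "potential.tsv", "walks.jsonl"]

    do("fate", ft, stage_fate)

    # ---- motifs --------------------------------------------------------
    mo = config.get("motifs", {})

    def stage_motifs(sdir, cached):
        sites = _site_matrix(state, config)
        gene_index = {g: i for i, g in enumerate(state["gene_names"])}
        rows = [gene_index[g] for g in sites.sites.index if g in gene_index]
        site_df = sites.sites.loc[[state["gene_names"][r] for r in rows]]
        expr = state["log_vals"][:, rows].T
        am = motifs.fit_activities(expr, site_df, cell_names=state["adata"].obs_names)
        z = motifs.activity_zscores(am)
        ensemble = state["ensemble"]
        fates = [f for f in ensemble.fates]
        n_grid = config.get("fate", {}).get("n_grid", 50)
        smooth = config.get("fate", {}).get("smooth_window", 5)
        profiles, corrs = {}, {}
        act = am.activities.to_numpy()
        for f in fates:
            for mi, m in enumerate(am.activities.index):
                prof = fate_mod.trajectory_profile(
                    ensemble, act[mi], f, n_grid=n_grid, smooth_window=smooth, min_walks=5
                )
                profiles[(m, f)] = prof
                tf_gene = sites.motif_to_tf.get(m)
                if tf_gene is None or tf_gene not in gene_index:
                    continue
                eprof = fate_mod.trajectory_profile(
                    ensemble, state["log_vals"][:, gene_index[tf_gene]], f,
                    n_grid=n_grid, smooth_window=smooth, min_walks=5,
                )
                corrs[(m, f)] = motifs.lagged_correlation(
                    eprof.mean, prof.mean,
                    max_lag_bins=max(1, int(n_grid * mo.get("max_lag_frac", 0.25))),
                )
        rep = motifs.select_differential(z, profiles, corrs, fates=tuple(fates))
        state.update(activity=am, zscores=z, motif_report=rep, motif_fates=tuple(fates))
        if not cached:
            am.activities.to_csv(sdir / "activities.tsv", sep="\t")
            z.to_csv(sdir / "zscores.tsv", sep="\t")
            rep.to_csv(sdir / "differential_motifs.tsv", sep="\t", index=False)
        return ["activities.tsv", "zscores.tsv", "differential_motifs.tsv"]

    do("motifs", mo, stage_motifs)

    state["completed"] = completed
    (out_dir / "run_manifest.json").write_text(
        json.dumps({"seed": seed, "completed": completed}, indent=2)
    )
    run._last_state = state  # inspection hook for tests/reporting
    return out_dir


def _progenitor_cluster(state, config):
    """Cluster with the highest mean expression of the progenitor markers
    (config ``annotation.progenitor_markers`` or the synthetic truth)."""
    ann = config.get("annotation", {})
    prog_markers = ann.get("progenitor_markers")
    if prog_markers is None and "ds" in state:
        prog_markers = state["ds"].truth.progenitor_genes
    if prog_markers is None:
        raise ValueError("annotation.progenitor_markers is required for real data")
    gene_index = {g: i for i, g in enumerate(state["gene_names"])}
    idx = [gene_index[g] for g in prog_markers if g in gene_index]
    labels = state["labels"]
    scores = {c: state["log_vals"][np.ix_(labels == c, idx)].mean() for c in np.unique(labels)}
    return max(scores, key=scores.get)


def _annotate(state, config):
    ann = config.get("annotation", {})
    fate_markers = ann.get("fate_markers")
    if fate_markers is None and "ds" in state:
        fate_markers = state["ds"].truth.hormone_genes
    if fate_markers is None:
        raise ValueError("annotation.fate_markers is required for real data")
    gene_index = {g: i for i, g in enumerate(state["gene_names"])}
    labels = state["labels"]
    prog_cluster = state.get("prog_cluster", _progenitor_cluster(state, config))
    annotation = {prog_cluster: PROGENITOR}
    for c in np.unique(labels):
        if c == prog_cluster:
            continue
        scores = {}
        for name, genes in fate_markers.items():
            idx = [gene_index[g] for g in genes if g in gene_index]
            scores[name] = state["log_vals"][np.ix_(labels == c, idx)].mean()
        annotation[c] = max(scores, key=scores.get)
    return annotation


def _site_matrix(state, config):
    mo = config.get("motifs", {})
    if "sites_path" in mo:
        table = pd.read_csv(mo["sites_path"], sep="\t")
        tf_map = {}
        if "tf_map_path" in mo:
            mdf = pd.read_csv(mo["tf_map_path"], sep="\t")
            tf_map = dict(zip(mdf.iloc[:, 0], mdf.iloc[:, 1]))
        return motifs.MotifTargetMatrix.from_long(table, state["gene_names"], tf_map)
    if "ds" in state:
        return state["ds"].motif_matrix
    raise ValueError("motifs.sites_path is required for real data")


def report(out_dir: str | Path) -> dict:
    """Aggregate a completed (or partial) run into one summary dict; an
    incomplete run is flagged rather than failing."""
    out_dir = Path(out_dir)
    summary: dict = {"run_dir": str(out_dir)}
    mf = out_dir / "run_manifest.json"
    completed = json.loads(mf.read_text())["completed"] if mf.exists() else []
    summary["completed_stages"] = completed
    summary["partial"] = not set(completed) >= {"qc", "embed"}

    qc_file = out_dir / "qc" / "qc_report.json"
    if qc_file.exists():
        summary["qc"] = json.loads(qc_file.read_text())
    cl_file = out_dir / "embed" / "clusters.tsv"
    if cl_file.exists():
        labels = pd.read_csv(cl_file, sep="\t", index_col=0)["cluster"]
        summary["cluster_sizes"] = labels.value_counts().sort_index().to_dict()
    mk_file = out_dir / "markers" / "markers.tsv"
    if mk_file.exists():
        tab = pd.read_csv(mk_file, sep="\t")
        summary["n_marker_genes_passed"] = int(tab["passed"].sum())
    fp_file = out_dir / "fate" / "fate_probabilities.tsv"
    if fp_file.exists():
        probs = pd.read_csv(fp_file, sep="\t", index_col=0)
        summary["mean_fate_probabilities"] = probs.mean().round(4).to_dict()
    dm_file = out_dir / "motifs" / "differential_motifs.tsv"
    if dm_file.exists():
        rep = pd.read_csv(dm_file, sep="\t")
        fates = sorted({f for fs in rep.get("specificity", []) for f in fs.split("+")}) \
            if len(rep) else []
        cats: dict = {}
        if len(rep):
            for s in rep["specificity"]:
                cats[s] = cats.get(s, 0) + 1
        summary["n_differential_motifs"] = int(len(rep))
        summary["motif_categories"] = cats
    (out_dir / "report.json").write_text(json.dumps(summary, indent=2, default=str))
    return summary
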