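"""End-to-end orchestration of the MCSM workflow.

Two modes share the core (joint Laplacian → manifold optimization →
per-view k-means → alignment → KNN integration):

* real mode — read per-omic feature tables, preprocess, build heat-kernel
  KNN graphs;
* simulation mode — generate multi-view SBM networks whose binary
  adjacencies feed the Laplacian directly, then score against the planted
  labels.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clustering import (
    IntegratedClustering,
    ViewLabels,
    align_labels,
    integrate_knn,
    kmeans_per_view,
    select_k,
)
from .graph import ViewGraph, heat_kernel, joint_laplacian, knn_graph
from .metrics import EvalReport, evaluate_runs
from .optimizer import OptParams, OptTrace, StackedEmbedding, optimize
from .preprocess import read_matrix, preprocess_views
from .simulate import SBMSpec, SimulatedMultiView, simulate_multiview

__all__ = ["RunConfig", "cluster_adjacencies", "run_pipeline", "simulation_study"]


@dataclass
class RunConfig:
    """Everything needed to re-execute a run deterministically."""

    mode: str = "simulate"  # "real" | "simulate"
    view_paths: list = field(default_factory=list)
    setting: int = 1
    pmatrix: int = 1
    n_runs: int = 1
    K: int | None = 3
    k_auto_range: tuple = (2, 10)
    beta: float = 1.0
    t: float | None = None
    k_neighbors: int | None = None
    k_integrate: int | None = None
    max_missing_frac: float = 0.2
    impute_k: int = 20
    opt: OptParams = field(default_factory=OptParams)
    seed: int = 0
    out_dir: str | None = None


def default_k_neighbors(n: int) -> int:
    """Neighbourhood size heuristic for patient-similarity graphs."""
    return min(max(10, round(n / 10)), n - 1)


def cluster_adjacencies(
    adjacencies: list,
    K: int,
    beta: float = 1.0,
    opt: OptParams | None = None,
    seed: int = 0,
    k_integrate: int | None = None,
):
    """Core pipeline from adjacency matrices to an integrated clustering.

    Returns ``(integrated, embedding, trace)``; the per-view aligned labels
    live on ``integrated.per_view``.
    """
    views = [ViewGraph.from_adjacency(a) for a in adjacencies]
    joint = joint_laplacian(views, beta=beta)
    opt = opt or OptParams(seed=seed)
    U, trace = optimize(joint, K, params=opt)
    labels = kmeans_per_view(U, K, seed=seed)
    labels = align_labels(labels)
    if k_integrate is None:
        k_integrate = default_k_neighbors(joint.N)
    integrated = integrate_knn(U, labels, k_integrate=k_integrate)
    return integrated, U, trace


def _label_views(sim: SimulatedMultiView, K: int, beta: float, opt: OptParams, seed: int):
    integrated, _, _ = cluster_adjacencies(
        sim.adjacencies, K=K, beta=beta, opt=opt, seed=seed
    )
    return integrated.per_view.labels


def simulation_study(
    setting: int,
    pmatrix: int,
    n_runs: int = 50,
    seed: int = 0,
    beta: float = 1.0,
    opt: OptParams | None = None,
) -> EvalReport:
    """Replicated SBM study: simulate, cluster, score per view, average."""
    spec = SBMSpec.from_setting(setting, pmatrix, seed=seed)
    opt = opt or OptParams(seed=seed)
    return evaluate_runs(
        spec,
        pipeline=lambda sim: _label_views(sim, K=spec.K, beta=beta, opt=opt, seed=seed),
        n_runs=n_runs,
        seed=seed,
    )


def _write_artifacts(
    out_dir: Path,
    config: RunConfig,
    integrated: IntegratedClustering,
    trace: OptTrace,
    sample_ids: list[str],
    report: EvalReport | None = None,
) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    labels = integrated.per_view.labels
    df = pd.DataFrame({"sample_id": sample_ids, "final_label": integrated.final_labels})
    for m in range(labels.shape[0]):
        df[f"view{m + 1}_label"] = labels[m]
    df.to_csv(out_dir / "labels.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"objective": trace.objective_per_iter}
    ).to_csv(out_dir / "objective_trace.csv", index=False)
    manifest = {
        "package": "mcsm",
        "version": __version__,
        "seed": config.seed,
        "config": {k: v for k, v in asdict(config).items() if k != "opt"},
        "opt": asdict(config.opt),
        "K": integrated.K,
        "converged": trace.converged,
        "ch_scores": integrated.ch_scores,
    }
    if report is not None:
        manifest["evaluation"] = report.to_dict()
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def run_pipeline(config: RunConfig):
    """Execute a full run from a :class:`RunConfig`; optionally write artifacts.

    Real mode returns ``(integrated, trace)``; simulation mode returns
    ``(integrated, trace, report)`` with the planted-label evaluation of
    the last replicate.
    """
    if config.mode == "real":
        mats = [read_matrix(p) for p in config.view_paths]
        mats = preprocess_views(
            mats, max_missing_frac=config.max_missing_frac, impute_k=config.impute_k
        )
        n = mats[0].n_samples
        kn = config.k_neighbors or default_k_neighbors(n)
        graphs = [knn_graph(heat_kernel(m, t=config.t), kn) for m in mats]
        joint = joint_laplacian(graphs, beta=config.beta)
        if config.K is None:
            # scan K on an embedding computed at the upper end of the range
            k_min, k_max = config.k_auto_range
            U_scan, _ = optimize(joint, k_max, params=config.opt)
            K = select_k(U_scan, k_min, min(k_max, n - 1), seed=config.seed).best_k
        else:
            K = config.K
        U, trace = optimize(joint, K, params=config.opt)
        labels = align_labels(kmeans_per_view(U, K, seed=config.seed))
        integrated = integrate_knn(
            U, labels, k_integrate=config.k_integrate or kn
        )
        if config.K is None:
            integrated.ch_scores = select_k(
                U, config.k_auto_range[0], min(config.k_auto_range[1], n - 1), seed=config.seed
            ).scores
        if config.out_dir:
            _write_artifacts(Path(config.out_dir), config, integrated, trace, mats[0].sample_ids)
        return integrated, trace

    if config.mode != "simulate":
        raise ValueError("mode must be 'real' or 'simulate'")
    spec = SBMSpec.from_setting(config.setting, config.pmatrix, seed=config.seed)
    K = config.K or spec.K
    report = simulation_study(
        config.setting,
        config.pmatrix,
        n_runs=config.n_runs,
        seed=config.seed,
        beta=config.beta,
        opt=config.opt,
    )
    sim = simulate_multiview(spec)
    integrated, _, trace = cluster_adjacencies(
        sim.adjacencies, K=K, beta=config.beta, opt=config.opt, seed=config.seed,
        k_integrate=config.k_integrate,
    )
    if config.out_dir:
        ids = [f"node{i}" for i in range(spec.N)]
        _write_artifacts(Path(config.out_dir), config, integrated, trace, ids, report)
    return integrated, trace, report
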