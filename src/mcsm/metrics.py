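"""Clustering evaluation: Rand index, NMI and replicated simulation studies.

Both indices are computed from the contingency table of the two partitions.
The Rand index is the fraction of unordered sample pairs on which the
partitions agree (placed together in both, or apart in both).  NMI is
2·MI(U,V) / (H(U) + H(V)) with natural-log entropies and the convention
0·log 0 = 0; two single-cluster partitions are identical, so NMI is 1.

In the simulation studies every view has its own planted partition, so RI
and NMI are computed per view against that view's truth and then averaged
over views and replicate runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .simulate import SBMSpec, SimulatedMultiView, simulate_multiview

__all__ = ["EvalReport", "rand_index", "nmi", "evaluate_runs"]


def _contingency(pred: np.ndarray, truth: np.ndarray) -> np.ndarray:
    pred = np.asarray(pred).ravel()
    truth = np.asarray(truth).ravel()
    if pred.shape != truth.shape:
        raise ValueError("label vectors must have equal length")
    _, pi = np.unique(pred, return_inverse=True)
    _, ti = np.unique(truth, return_inverse=True)
    k1, k2 = pi.max() + 1, ti.max() + 1
    cont = np.zeros((k1, k2), dtype=np.int64)
    np.add.at(cont, (pi, ti), 1)
    return cont


def rand_index(pred, truth) -> float:
    """Fraction of sample pairs on which the two partitions agree."""
    cont = _contingency(pred, truth)
    n = int(cont.sum())
    if n < 2:
        raise ValueError("need at least 2 samples")
    comb2 = lambda x: x * (x - 1) // 2  # noqa: E731
    tp = int(comb2(cont).sum())  # pairs together in both
    same_pred = int(comb2(cont.sum(axis=1)).sum())
    same_truth = int(comb2(cont.sum(axis=0)).sum())
    total = comb2(n)
    tn = total - same_pred - same_truth + tp
    return (tp + tn) / total


def nmi(pred, truth) -> float:
    """Normalized mutual information, 2·MI / (H(pred) + H(truth))."""
    cont = _contingency(pred, truth).astype(float)
    n = cont.sum()
    pij = cont / n
    pi = pij.sum(axis=1)
    pj = pij.sum(axis=0)
    h_u = -np.sum(pi[pi > 0] * np.log(pi[pi > 0]))
    h_v = -np.sum(pj[pj > 0] * np.log(pj[pj > 0]))
    if h_u + h_v == 0:
        return 1.0  # both partitions are single-cluster, hence identical
    nz = pij > 0
    mi = float(np.sum(pij[nz] * np.log(pij[nz] / np.outer(pi, pj)[nz])))
    return max(0.0, 2.0 * mi / (h_u + h_v))


@dataclass
class EvalReport:
    """Per-run, per-view RI/NMI of a replicated simulation study."""

    ri: np.ndarray  # runs × views
    nmi: np.ndarray  # runs × views
    n_runs: int
    n_failures: int = 0
    failures: list = field(default_factory=list)

    @property
    def ri_per_view(self) -> np.ndarray:
        return self.ri.mean(axis=0)

    @property
    def nmi_per_view(self) -> np.ndarray:
        return self.nmi.mean(axis=0)

    @property
    def mean_ri(self) -> float:
        return float(self.ri.mean())

    @property
    def mean_nmi(self) -> float:
        return float(self.nmi.mean())

    def to_dict(self) -> dict:
        return {
            "n_runs": self.n_runs,
            "n_failures": self.n_failures,
            "mean_ri": self.mean_ri,
            "mean_nmi": self.mean_nmi,
            "ri_per_view": self.ri_per_view.tolist(),
            "nmi_per_view": self.nmi_per_view.tolist(),
            "ri_per_run": self.ri.tolist(),
            "nmi_per_run": self.nmi.tolist(),
        }


def evaluate_runs(
    spec: SBMSpec,
    pipeline: Callable[[SimulatedMultiView], np.ndarray],
    n_runs: int = 50,
    seed: int = 0,
) -> EvalReport:
    """Replicate simulate → cluster → score and average the results.

    ``pipeline`` maps a simulated multi-view network to an M × N array of
    per-view predicted labels.  Each run re-simulates with a fresh seed
    derived from ``seed``; per-view RI/NMI are scored against that view's
    planted labels.  A run whose pipeline raises is recorded and excluded.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    run_seeds = np.random.SeedSequence(seed).generate_state(n_runs) % (2**31)
    ri_rows, nmi_rows, failures = [], [], []
    for r in range(n_runs):
        sim = simulate_multiview(spec.with_seed(int(run_seeds[r])))
        try:
            pred = np.asarray(pipeline(sim))
        except Exception as exc:  # noqa: BLE001 - report, don't abort the study
            failures.append((r, repr(exc)))
            continue
        if pred.shape != sim.truth.shape:
            failures.append((r, f"pipeline returned shape {pred.shape}"))
            continue
        ri_rows.append([rand_index(pred[m], sim.truth[m]) for m in range(sim.M)])
        nmi_rows.append([nmi(pred[m], sim.truth[m]) for m in range(sim.M)])
    if not ri_rows:
        raise RuntimeError("every run failed; see failures")
    return EvalReport(
        ri=np.array(ri_rows),
        nmi=np.array(nmi_rows),
        n_runs=len(ri_rows),
        n_failures=len(failures),
        failures=failures,
    )
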