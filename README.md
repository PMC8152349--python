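# mcsm — multi-view clustering of omics samples on Stiefel manifolds

Patients profiled on several omics platforms (gene expression, miRNA, DNA
methylation, …) rarely fall into identical subtypes in every data type:
the subtypes are partly shared and partly view-specific. `mcsm` clusters
such cohorts by embedding each view's patient-similarity network jointly,
so that views inform each other without being forced onto one consensus,
and then reads off both per-view and integrated cluster labels. It is
aimed at computational biologists doing multi-omics subtype discovery,
and at methodologists studying multi-layer network clustering.

## The model

For each of the M views a patient-similarity graph with adjacency W<sup>m</sup>
is built (heat-kernel similarity `exp(−‖x_i − x_j‖²/2t²)` sparsified to a
symmetric k-nearest-neighbour graph), with Laplacian L<sub>m</sub> = D<sub>m</sub> − W<sup>m</sup>.
The per-view spectral embeddings U<sub>m</sub> ∈ ℝ<sup>N×K</sup> are coupled through the
joint block matrix

```
L = blockdiag(L_1, …, L_M) − β · (off-diagonal I_N blocks),
```

and found by solving

```
min  trace(UᵀLU)   s.t.  U_mᵀU_m = I_K  for every view m,
```

a minimization over a product of Stiefel manifolds. The solver is
projected gradient descent: the negative Euclidean gradient Z = −2LU is
projected onto each tangent space
(η<sub>m</sub> = Z<sub>m</sub> − ½U<sub>m</sub>(U<sub>m</sub>ᵀZ<sub>m</sub> + Z<sub>m</sub>ᵀU<sub>m</sub>)), an Armijo backtracking line
search picks the step, and the stepped point is retracted to the manifold
through the polar factor of its thin SVD. Each U<sub>m</sub> is then clustered by
k-means (K selectable by the Calinski–Harabasz score), labels are matched
across views by Hungarian assignment, and cross-view disagreements are
resolved by a k-nearest-neighbour majority vote in the concatenated
embedding.

The package also ships a multi-view stochastic-block-model simulator
(each view draws an independent network from shared block probabilities
but its own cluster-size vector, so planted partitions differ across
views) and Rand-index / NMI evaluation utilities.

## Worked example

```python
import numpy as np
from mcsm import SBMSpec, simulate_multiview, rand_index
from mcsm.pipeline import cluster_adjacencies

spec = SBMSpec.from_setting(setting=1, pmatrix=3, seed=1)   # M=3 views, N=150
sim = simulate_multiview(spec)
integrated, U, trace = cluster_adjacencies(sim.adjacencies, K=3, seed=1)

print("objective start/end:", round(trace.objective_per_iter[0], 3),
      round(trace.objective_per_iter[-1], 3))
for m in range(sim.M):
    print(f"view {m}: RI vs planted labels =",
          round(rand_index(integrated.per_view.labels[m], sim.truth[m]), 3))
```

prints

```
objective start/end: -11.57 -11.572
view 0: RI vs planted labels = 1.0
view 1: RI vs planted labels = 1.0
view 2: RI vs planted labels = 0.981
```

The objective starts near its optimum because the solver is warm-started
from the joint matrix's bottom-K eigenvectors and only polishes from
there; the per-view Rand indices show each view's planted partition is
recovered almost perfectly even though the three views disagree on 40+
node assignments.

The same pipeline runs from the shell:

```sh
mcsm simulate --setting 1 --pmatrix 3 --seed 1 --out-dir sim/
mcsm cluster --graphs sim/view1.mtx --graphs sim/view2.mtx --graphs sim/view3.mtx \
     --k 3 --seed 1 --out labels.tsv
mcsm evaluate --setting 1 --pmatrix 3 --runs 50 --seed 1 --out report.json
```

Real data enters as per-omic TSV matrices (features × samples, first row
sample IDs) via `mcsm preprocess` / `mcsm run --config cfg.yaml`.

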