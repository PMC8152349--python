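# Methods

## Problem and model

Given M data types measured on the same N samples, each view m contributes
a weighted undirected graph G^m over the samples with adjacency W^m,
degree matrix D_m and Laplacian L_m = D_m − W^m. Relaxing the per-view
normalized-cut indicator vectors to orthonormal frames and rewarding
cross-view agreement yields the joint problem

    min  Σ_m trace(U_mᵀ L_m U_m) − β Σ_{l≠m} trace(U_mᵀ U_l)
    s.t. U_mᵀ U_m = I_K,

equivalently min trace(UᵀLU) with U the MN × K vertical stack of the U_m
and L the block matrix with the L_m on the diagonal and −β·I_N in every
off-diagonal block. β balances within-view cut quality against cross-view
coherence; when the view graphs are built at comparable edge densities a
neutral β = 1 is appropriate and is the default. The joint L is symmetric
but indefinite for β > 0 (its smallest eigenvalue is bounded below by
−β(M−1)); only the per-view diagonal blocks are PSD.

With M = 1 the problem is exactly the classical spectral-clustering
relaxation and its minimizer is the span of the K smallest-eigenvalue
eigenvectors of L_1; this equivalence is used as an oracle test.

## Graph construction

Similarity between samples i and j in a view is the heat kernel
exp(−‖x_i − x_j‖² / 2t²) computed on the preprocessed (standardized)
feature profiles. The bandwidth t defaults to the median off-diagonal
pairwise distance of that view — a self-tuning choice that keeps the
kernel responsive across views with different feature dimensionalities;
it is overridable. The kernel is sparsified to a k-nearest-neighbour
graph with union symmetrization (an edge survives if either endpoint
ranks the other among its k most similar; mutual-KNN is available behind
a flag); ties at the k-th neighbour break deterministically by node
index. k defaults to max(10, N/10), a common operating point for
patient-similarity networks at cohort sizes of roughly 100–1000. The
diagonal is zeroed before degrees are computed — self-loops cancel in
D − W regardless, and a hollow W is easier to interpret. Simulated binary
adjacency matrices skip the kernel and feed the Laplacian directly.

## Optimization on the product of Stiefel manifolds

Each iteration performs:

1. **Gradient.** Z = −2LU (the factor 2 comes from the symmetric quadratic
   form; it only rescales the search direction and is absorbed by the
   line search).
2. **Tangent projection.** Per view,
   η_m = Z_m − ½ U_m (U_mᵀ Z_m + Z_mᵀ U_m), the orthogonal projection
   onto {H : U_mᵀH + HᵀU_m = 0}.
3. **Backtracking line search.** One global step α shared by all views
   (the objective couples them; per-view steps are available behind a
   flag). Starting at α₀, the step shrinks geometrically (α ← τα) until
   the retracted candidate satisfies the sufficient-decrease condition

       f(R(U + αη)) ≤ f(U) − α · c_eff · |⟨η, Z⟩|,

   where ⟨·,·⟩ is the trace inner product and R the retraction. The
   condition is evaluated *after* retraction, since U + αη leaves the
   manifold. The configured control parameter c defaults to 6 with
   τ = 0.1 and α₀ = 0.01; because a slope coefficient above 1 demands
   more decrease than the first-order model can supply (the condition
   then fails for every α), the effective coefficient is capped at
   c_eff = min(c, 0.99). The uncapped condition is available as
   `armijo="literal"`. If `max_backtracks` trials all fail, the step is
   reported as α = 0 and the loop stops — descent is never faked.
4. **Retraction.** Per view, the polar factor W·Vᵀ of the thin SVD
   Y = WΣVᵀ, i.e. the orthonormal matrix nearest to Y in Frobenius norm.
   A rank-deficient Y raises rather than silently degenerating.

Stopping: `max_iter` (default 20) or relative objective change below
`tol` (default 1e-6), whichever first. The accepted-step sequence makes
the objective trace non-increasing by construction.

### Initialization

The default warm start takes the K smallest-eigenvalue eigenvectors of
the **joint** matrix L, splits them into the M view blocks and retracts
each block to its Stiefel manifold. These eigenvectors solve the
single-constraint relaxation (UᵀU = I_K) exactly, so the feasible point
obtained after blockwise retraction already sits close to the coupled
optimum and the iterations above act as a polish; with one view this
reduces to the standard spectral-clustering embedding. The alternative
warm start from each view's own bottom-K eigenvectors
(`init="spectral_per_view"`) ignores the coupling term and, at β = 1,
starts far from the joint optimum — with the small default step size the
loop then stalls long before the coupled solution, which is why it is
not the default. A seeded random orthonormal start (`init="random"`)
is provided for convergence experiments; it reaches the warm-started
objective but needs on the order of a thousand iterations.

The eigenvectors are computed densely for n ≤ 600 and otherwise by
Lanczos iteration on cI − L with c a Gershgorin bound on the spectrum,
which needs only matrix-vector products and avoids the fill-in of
shift-invert factorizations on the MN × MN matrix.

## From embedding to labels

Rows of each U_m are normalized to unit length before k-means (standard
for spectral embeddings, where cluster information lives in direction,
not magnitude; disableable). k-means uses k-means++ with 50 restarts and
a fixed seed, so results are deterministic. When K is unknown it is
chosen as the argmax of the Calinski–Harabasz score of k-means on the
row-concatenated embedding over a scan range (default 2–10), ties going
to the smaller K.

k-means labels are arbitrary per view, so views 2..M are aligned to view
1 by maximum-overlap assignment on the pairwise contingency table
(Hungarian algorithm). This alignment is plumbing the integration step
requires, not part of the clustering model.

**Integration.** Samples on which all views agree keep their common
label. For a sample whose views disagree, the final label is the
majority over the M·(k+1) aligned labels of the sample itself and its k
nearest neighbours in the concatenated embedding, ties broken by the
sample's own majority view label and then by the smallest label index.
Restricting the vote to disagreement cases keeps integration the
identity whenever the views are unanimous, for every neighbourhood size;
an unconditional neighbourhood majority would let neighbours overrule a
label all M data types agree on. The vote is isolated in one operation
(`integrate_knn`) so alternative fusion rules can be swapped in.

## Preprocessing of real data

Fixed order: (1) drop samples missing strictly more than 20% of entries
in any omic (a sample unusable in one data type is removed everywhere);
(2) drop features missing in strictly more than 20% of samples; boundary
cases at exactly the threshold are kept in both filters; (3) impute each
remaining missing cell with the mean of that feature over the k = 20
nearest samples, where sample distances use only mutually observed
features rescaled by p/|shared| so sparse overlap does not fake
proximity — if none of the k neighbours observes the feature, the
feature's overall observed mean is used; (4) log-transform, natural log
of (value + 1), both base and offset configurable; (5) standardize every
feature to mean 0 and variance 1, using the population denominator N
(ddof configurable). Zero-variance features cannot be standardized and
are dropped with a warning rather than emitting NaN. Samples with no
observed features, or sharing no features with any neighbour, are
errors, not silent guesses.

## The simulator and what it does (not) emulate

`simulate` draws M independent binary networks over the same N nodes.
Nodes are assigned to K clusters per view by a deterministic contiguous
rule (first n₁ nodes → cluster 0, …), so that views with different
cluster-size vectors share cluster identity for core nodes and differ
only at block boundaries — an interpretable realization of "views
disagree about subtype membership". Edges are independent
Bernoulli(P[c_i, c_j]) draws on unordered pairs; the diagonal is zero
and the matrix symmetric. The built-in probability matrices P1–P4 put
within-cluster probabilities at 16–18/N and between-cluster
probabilities from 0 (P1) to 1.8/N (P4); the two built-in settings are
M = 3, N = 150 with size vectors (50,50,50), (30,90,30), (40,60,50) and
M = 6, N = 1000 with six vectors around (300,300,400). Each view uses
seed + view-index, so a spec reproduces bit-identically.

The simulator emulates the network structure only: binary, unweighted,
degree-homogeneous within blocks, with independent edges. Real
patient-similarity graphs are weighted, have hub structure and
correlated edges, and their noise enters through the feature matrices
and kernel, not through Bernoulli edges. Passing the simulated studies
therefore demonstrates that the joint embedding and integration recover
planted multi-view block structure at realistic sparsity — it does not
by itself validate preprocessing or kernel choices on real cohorts.

## Evaluation

The Rand index is the fraction of unordered sample pairs on which two
partitions agree (together in both or apart in both), computed from the
contingency table. NMI is 2·MI/(H(U)+H(V)) with natural logarithms and
0·log 0 = 0; two single-cluster partitions score 1. Both are invariant
to label permutation; both are cross-checked against scikit-learn's
implementations in the test suite while remaining independent code
paths. Because every view has its own planted partition, replicated
studies score each view's predicted labels against that view's truth
and average over views and replicates; per-run values are retained for
variance reporting.

Replicated studies use 50 runs at N = 150 and 10 runs at N = 1000 — the
larger setting's per-run variance is roughly N-fold smaller, so fewer
replicates estimate the mean to comparable precision.

## Numerical choices and limitations

- Orthonormality is enforced to ‖U_mᵀU_m − I‖_F < 1e-8 after every
  retraction; Laplacian row sums are zero to 1e-10.
- KNN ties (graph construction and neighbour queries) break by node
  index; k-means ties are resolved by the fixed-seed restart scheme.
- The indefinite joint matrix means the objective is unbounded below
  only on the *unconstrained* space; on the product manifold it is
  bounded and the monotone trace converges.
- The method assumes all views share the same sample set and the same K;
  per-view cluster counts are out of scope.
- Cluster-number selection by Calinski–Harabasz is a heuristic; on
  embeddings with near-duplicate rows the score can drift upward with K,
  so the scan range should stay well below N.
- Very sparse views (expected degree ≲ 3) can produce disconnected
  graphs whose extra null-space directions blur that view's embedding;
  the coupling term mitigates but does not eliminate this.
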