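"""Cleaning and normalization of multi-omics matrices.

Each omic is a features × samples table over a shared sample set.  Before
graph construction the matrices pass through a fixed chain: drop samples
with too much missing data in any omic, drop features with too much missing
data, impute the remainder by a k-nearest-neighbour rule, log-transform,
and standardize every feature to mean 0 / variance 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "OmicsMatrix",
    "read_matrix",
    "write_matrix",
    "filter_samples",
    "filter_features",
    "knn_impute",
    "log_transform",
    "standardize",
    "preprocess_views",
]

_NA_VALUES = ["", "NA", "NaN", "nan"]


@dataclass
class OmicsMatrix:
    """One omic's ``p`` features × ``N`` samples numeric table.

    Missing entries are encoded as NaN in ``values``.  Sample and feature
    identifiers must be unique.
    """

    values: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    feature_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D features × samples array")
        p, n = self.values.shape
        if not self.sample_ids:
            self.sample_ids = [f"S{j}" for j in range(n)]
        if not self.feature_ids:
            self.feature_ids = [f"F{i}" for i in range(p)]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match values")
        if len(self.feature_ids) != p:
            raise ValueError("feature_ids length does not match values")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids must be unique")
        if len(set(self.feature_ids)) != p:
            raise ValueError("feature_ids must be unique")

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean mask, True where a cell is missing."""
        return np.isnan(self.values)

    def copy(self) -> "OmicsMatrix":
        return OmicsMatrix(self.values.copy(), list(self.sample_ids), list(self.feature_ids))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)


def read_matrix(path: str, sep: str | None = None) -> OmicsMatrix:
    """Read a TSV/CSV matrix: first row sample IDs, first column feature IDs.

    Missing values may be encoded as empty cells, ``NA`` or ``NaN``.  The
    separator is inferred from the extension when not given (``.csv`` →
    comma, otherwise tab).
    """
    if sep is None:
        sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0, na_values=_NA_VALUES, keep_default_na=False)
    return OmicsMatrix(df.to_numpy(dtype=float), list(df.columns), list(df.index))


def write_matrix(matrix: OmicsMatrix, path: str, sep: str | None = None) -> None:
    if sep is None:
        sep = "," if str(path).endswith(".csv") else "\t"
    matrix.to_frame().to_csv(path, sep=sep, na_rep="NA")


def _check_shared_samples(matrices: list[OmicsMatrix]) -> None:
    if not matrices:
        raise ValueError("need at least one matrix")
    ref = matrices[0].sample_ids
    for m in matrices[1:]:
        if m.sample_ids != ref:
            raise ValueError("all matrices must share the same sample_ids in the same order")


def filter_samples(
    matrices: list[OmicsMatrix], max_missing_frac: float = 0.2
) -> list[OmicsMatrix]:
    """Drop samples whose missing fraction exceeds the threshold in any omic.

    A sample is removed from *every* matrix as soon as its missing fraction
    is strictly greater than ``max_missing_frac`` in *one* matrix; sample
    order is preserved.  Boundary cases (exactly at the threshold) are kept.
    """
    if not 0.0 <= max_missing_frac <= 1.0:
        raise ValueError("max_missing_frac must lie in [0, 1]")
    _check_shared_samples(matrices)
    n = matrices[0].n_samples
    keep = np.ones(n, dtype=bool)
    for m in matrices:
        frac = m.missing_mask.mean(axis=0)
        keep &= frac <= max_missing_frac
    if not keep.any():
        raise ValueError("sample filter removed every sample")
    return [
        OmicsMatrix(
            m.values[:, keep],
            [s for s, k in zip(m.sample_ids, keep) if k],
            list(m.feature_ids),
        )
        for m in matrices
    ]


def filter_features(matrix: OmicsMatrix, max_missing_frac: float = 0.2) -> OmicsMatrix:
    """Drop features missing in strictly more than ``max_missing_frac`` of samples."""
    if not 0.0 <= max_missing_frac <= 1.0:
        raise ValueError("max_missing_frac must lie in [0, 1]")
    frac = matrix.missing_mask.mean(axis=1)
    keep = frac <= max_missing_frac
    if not keep.any():
        raise ValueError("feature filter removed every feature")
    return OmicsMatrix(
        matrix.values[keep],
        list(matrix.sample_ids),
        [f for f, k in zip(matrix.feature_ids, keep) if k],
    )


def _masked_sample_distances(values: np.ndarray) -> np.ndarray:
    """Pairwise sample distances using only mutually observed features.

    The squared distance over the shared features is rescaled by
    p / n_shared so samples with few overlapping features are not
    artificially close.  Pairs sharing no features get distance +inf.
    """
    p, n = values.shape
    obs = ~np.isnan(values)
    x = np.where(obs, values, 0.0)
    # sum over shared features of (x_i - x_j)^2, expanded so missing terms drop out
    sq = x**2
    shared = obs.T.astype(float) @ obs.astype(float)  # n × n counts
    cross = x.T @ x
    si = sq.T @ obs.astype(float)  # sum_i over features observed in both
    d2 = si + si.T - 2.0 * cross
    with np.errstate(divide="ignore", invalid="ignore"):
        d2 = np.where(shared > 0, d2 * (p / shared), np.inf)
    d2 = np.maximum(d2, 0.0)
    d = np.sqrt(d2)
    np.fill_diagonal(d, np.inf)
    return d


def knn_impute(matrix: OmicsMatrix, k: int = 20) -> OmicsMatrix:
    """Fill missing cells with the feature mean over the k nearest samples.

    Distances between samples use only mutually observed features (scaled by
    the number of shared features).  If none of the k nearest samples has the
    feature observed, the overall observed mean of the feature is used.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    values = matrix.values.copy()
    mask = np.isnan(values)
    if not mask.any():
        return matrix.copy()
    n = matrix.n_samples
    if k >= n:
        warnings.warn(f"k={k} >= n_samples={n}; clamping to {n - 1}", stacklevel=2)
        k = n - 1
    obs = ~mask
    if (~obs).all(axis=0).any():
        bad = [matrix.sample_ids[j] for j in np.flatnonzero((~obs).all(axis=0))]
        raise ValueError(f"samples with no observed features: {bad}")
    dist = _masked_sample_distances(values)
    if np.isinf(dist).all(axis=1).any():
        raise ValueError("a sample shares no observed features with any other sample")
    feat_mean = np.nanmean(values, axis=1)
    order = np.argsort(dist, axis=1, kind="stable")
    for j in np.flatnonzero(mask.any(axis=0)):
        nbrs = order[j, :k]
        for i in np.flatnonzero(mask[:, j]):
            vals = values[i, nbrs]
            vals = vals[~np.isnan(vals)]
            values[i, j] = vals.mean() if vals.size else feat_mean[i]
    if np.isnan(values).any():
        raise ValueError("imputation left missing values (feature observed nowhere?)")
    return OmicsMatrix(values, list(matrix.sample_ids), list(matrix.feature_ids))


def log_transform(matrix: OmicsMatrix, offset: float = 1.0) -> OmicsMatrix:
    """Elementwise natural log of (value + offset); requires positivity."""
    shifted = matrix.values + offset
    bad = np.nonzero(np.nanmin(shifted, axis=1) <= 0)[0]
    if bad.size:
        raise ValueError(
            f"log transform undefined for features {[matrix.feature_ids[i] for i in bad[:5]]}"
            f" (value + offset <= 0)"
        )
    return OmicsMatrix(np.log(shifted), list(matrix.sample_ids), list(matrix.feature_ids))


def standardize(matrix: OmicsMatrix, ddof: int = 0) -> OmicsMatrix:
    """Scale each feature to mean 0, variance 1 across samples.

    Uses the population variance denominator N by default (``ddof=1`` for
    the unbiased convention).  Zero-variance features cannot be scaled and
    are dropped with a warning.
    """
    if np.isnan(matrix.values).any():
        raise ValueError("standardize requires a complete matrix (impute first)")
    mean = matrix.values.mean(axis=1, keepdims=True)
    var = matrix.values.var(axis=1, ddof=ddof, keepdims=True)
    keep = var[:, 0] > 1e-12
    if not keep.all():
        dropped = [f for f, k in zip(matrix.feature_ids, keep) if not k]
        warnings.warn(f"dropping {len(dropped)} zero-variance feature(s)", stacklevel=2)
    if not keep.any():
        raise ValueError("all features have zero variance")
    out = (matrix.values[keep] - mean[keep]) / np.sqrt(var[keep])
    return OmicsMatrix(out, list(matrix.sample_ids), [f for f, k in zip(matrix.feature_ids, keep) if k])


def preprocess_views(
    matrices: list[OmicsMatrix],
    max_missing_frac: float = 0.2,
    impute_k: int = 20,
    log_offset: float = 1.0,
    apply_log: bool = True,
    ddof: int = 0,
) -> list[OmicsMatrix]:
    """Full chain: sample filter → feature filter → impute → log → standardize."""
    mats = filter_samples(matrices, max_missing_frac)
    mats = [filter_features(m, max_missing_frac) for m in mats]
    mats = [knn_impute(m, impute_k) if m.missing_mask.any() else m for m in mats]
    if apply_log:
        mats = [log_transform(m, log_offset) for m in mats]
    return [standardize(m, ddof=ddof) for m in mats]
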