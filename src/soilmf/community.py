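"""Beta diversity: Bray-Curtis distances, NMDS, PerMANOVA and Mantel tests.

Permutation p-values use the add-one estimator
``p = (1 + #{permuted statistic >= observed}) / (1 + n_permutations)`` so a
permutation test can never report p = 0; for small designs the label
permutations are enumerated exhaustively instead of sampled.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import smacof

from .synthetic import ASVTable

__all__ = [
    "DistanceMatrix",
    "OrdinationResult",
    "PermutationTestResult",
    "bray_curtis",
    "nmds",
    "permanova",
    "mantel",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise dissimilarities with sample labels."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match {n} labels")
        if len(set(self.labels)) != n:
            raise ValueError("labels must be unique")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if (np.diag(v) != 0).any():
            raise ValueError("distance matrix diagonal must be exactly 0")
        if (v < 0).any():
            raise ValueError("distances must be non-negative")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def condensed(self) -> np.ndarray:
        """Lower-triangle entries in scipy condensed order."""
        return squareform(self.values, checks=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.labels), columns=list(self.labels))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "DistanceMatrix":
        if list(frame.index) != list(frame.columns):
            raise ValueError("row and column labels differ")
        return cls(tuple(str(x) for x in frame.index), frame.to_numpy(dtype=float))


@dataclass(frozen=True)
class OrdinationResult:
    """NMDS configuration with its Kruskal stress-1."""

    coordinates: pd.DataFrame
    stress: float
    n_restarts_used: int
    converged: bool


@dataclass(frozen=True)
class PermutationTestResult:
    """Outcome of a label-permutation test (add-one p estimator)."""

    statistic: float
    p_value: float
    n_permutations: int
    seed: int | None
    exhaustive: bool
    method: str = ""


def bray_curtis(asv: ASVTable | pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between samples on raw counts.

    d(x, y) = 1 - 2 sum(min(x_i, y_i)) / (sum x + sum y), in [0, 1].
    """
    counts = asv.counts if isinstance(asv, ASVTable) else asv
    x = counts.to_numpy(dtype=float)
    totals = x.sum(axis=1)
    empty = [s for s, t in zip(counts.index, totals) if t == 0]
    if empty:
        raise ValueError(f"samples with zero total count: {empty}")
    d = squareform(pdist(x, metric="braycurtis"))
    return DistanceMatrix(tuple(str(s) for s in counts.index), d)


def _classical_mds(d: np.ndarray, k: int) -> np.ndarray:
    """Torgerson principal-coordinates configuration used as first restart."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:k]
    vals = np.clip(vals[order], 0, None)
    return vecs[:, order] * np.sqrt(vals)


def kruskal_stress(d: np.ndarray, coords: np.ndarray) -> float:
    """Kruskal stress-1 of a configuration against the dissimilarities.

    Disparities are the isotonic (monotone, ties-share-a-block) regression
    of configuration distances on the dissimilarities; stress-1 is
    sqrt(sum((dhat - disparity)^2) / sum(dhat^2)) over all pairs, with dhat
    the configuration distances.
    """
    dis = squareform(d, checks=False)
    dhat = pdist(coords)
    disparity = IsotonicRegression(increasing=True).fit(dis, dhat).predict(dis)
    denom = float((dhat**2).sum())
    if denom == 0:
        return 1.0
    return float(np.sqrt(((dhat - disparity) ** 2).sum() / denom))


def nmds(
    d: DistanceMatrix,
    k: int = 2,
    seed: int = 0,
    n_restarts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-6,
) -> OrdinationResult:
    """Non-metric multidimensional scaling by SMACOF with restarts.

    Restart 1 starts from the classical (metric) MDS configuration; further
    restarts use random Gaussian configurations. The restart with the
    lowest Kruskal stress-1 is returned.
    """
    n = len(d)
    if k >= n - 1:
        raise ValueError(f"k={k} requires at least k+2={k+2} samples, got {n}")
    rng = np.random.default_rng(seed)
    dmat = d.values
    best: tuple[float, np.ndarray, int] | None = None
    for restart in range(max(n_restarts, 1)):
        init = _classical_mds(dmat, k) if restart == 0 else rng.standard_normal((n, k))
        coords, _, n_iter = smacof(
            dmat,
            metric=False,
            n_components=k,
            init=init,
            n_init=1,
            max_iter=max_iter,
            eps=tol,
            normalized_stress=True,
            return_n_iter=True,
        )
        stress = kruskal_stress(dmat, coords)
        if best is None or stress < best[0]:
            best = (stress, coords, n_iter)
    stress, coords, n_iter = best
    frame = pd.DataFrame(
        coords, index=list(d.labels), columns=[f"NMDS{i+1}" for i in range(k)]
    )
    return OrdinationResult(frame, stress, max(n_restarts, 1), bool(n_iter < max_iter))


def _group_indices(labels: Sequence[str]) -> dict[str, np.ndarray]:
    labels = np.asarray(labels)
    return {g: np.flatnonzero(labels == g) for g in pd.unique(labels)}


def _pseudo_f(d2: np.ndarray, label_array: np.ndarray) -> float:
    """PerMANOVA pseudo-F from squared distances and group labels."""
    n = d2.shape[0]
    iu = np.triu_indices(n, 1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    groups = _group_indices(label_array)
    for idx in groups.values():
        sub = d2[np.ix_(idx, idx)]
        ss_within += np.triu(sub, 1).sum() / len(idx)
    g = len(groups)
    ss_among = ss_total - ss_within
    return (ss_among / (g - 1)) / (ss_within / (n - g))


def permanova(
    d: DistanceMatrix,
    groups: Sequence[str],
    n_permutations: int = 999,
    seed: int = 0,
    exhaustive_limit: int = 10_000,
) -> PermutationTestResult:
    """Permutational multivariate ANOVA on a distance matrix.

    pseudo-F = (SS_among / (g-1)) / (SS_within / (N-g)) with sums of
    squares computed directly from pairwise distances; the null permutes
    group labels (every label ordering is enumerated when N! does not
    exceed ``exhaustive_limit``).
    """
    labels = np.asarray(list(groups))
    if len(labels) != len(d):
        raise ValueError("one group label per sample required")
    counts = pd.Series(labels).value_counts()
    if len(counts) < 2:
        raise ValueError("need at least 2 groups")
    if (counts < 2).any():
        raise ValueError(f"groups of size 1: {counts[counts < 2].index.tolist()}")
    d2 = d.values**2
    observed = _pseudo_f(d2, labels)
    n = len(labels)
    exhaustive = math.factorial(n) <= exhaustive_limit
    if exhaustive:
        perms = itertools.permutations(labels)
        stats_null = np.fromiter((_pseudo_f(d2, np.array(p)) for p in perms), dtype=float)
        n_perm = len(stats_null)
    else:
        rng = np.random.default_rng(seed)
        stats_null = np.array(
            [_pseudo_f(d2, rng.permutation(labels)) for _ in range(n_permutations)]
        )
        n_perm = n_permutations
    p = (1 + (stats_null >= observed - 1e-12).sum()) / (1 + n_perm)
    return PermutationTestResult(float(observed), float(p), n_perm, seed, exhaustive, "permanova")


def _mantel_r(v1: np.ndarray, v2: np.ndarray) -> float:
    return float(np.corrcoef(v1, v2)[0, 1])


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_permutations: int = 999,
    seed: int = 0,
    exhaustive_limit_n: int = 7,
) -> PermutationTestResult:
    """Mantel test: Pearson correlation of two distance matrices.

    The statistic is the correlation of the lower-triangle vectors; the
    null simultaneously permutes rows and columns of ``d2``. One-sided
    (upper tail) with the add-one correction; exhaustive for N <= 7.
    """
    if d1.labels != d2.labels:
        diff = set(d1.labels).symmetric_difference(d2.labels) or "ordering differs"
        raise ValueError(f"distance matrices must share labels in order: {diff}")
    v1 = d1.condensed
    if np.ptp(v1) == 0 or np.ptp(d2.condensed) == 0:
        raise ValueError("zero variance among distances; Mantel r undefined")
    observed = _mantel_r(v1, d2.condensed)
    n = len(d1)
    exhaustive = n <= exhaustive_limit_n
    m2 = d2.values
    if exhaustive:
        orders = itertools.permutations(range(n))
        stats_null = np.array(
            [_mantel_r(v1, squareform(m2[np.ix_(o, o)], checks=False)) for o in orders]
        )
        n_perm = len(stats_null)
    else:
        rng = np.random.default_rng(seed)
        stats_null = np.empty(n_permutations)
        for i in range(n_permutations):
            o = rng.permutation(n)
            stats_null[i] = _mantel_r(v1, squareform(m2[np.ix_(o, o)], checks=False))
        n_perm = n_permutations
    p = (1 + (stats_null >= observed - 1e-12).sum()) / (1 + n_perm)
    return PermutationTestResult(float(observed), float(p), n_perm, seed, exhaustive, "mantel")
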