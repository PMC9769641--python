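"""Distances, ordination and hypothesis tests on presence profiles.

Jaccard distances between per-sample presence vectors, classical
principal-coordinate analysis (metric MDS via the double-centred -D²/2
eigendecomposition), PERMANOVA computed directly from the distance matrix
(Anderson's distance-based pseudo-F with a seeded label-permutation null),
and two-sided Wilcoxon rank-sum comparisons of per-sample feature counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import mannwhitneyu


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if np.abs(np.diag(self.d)).max(initial=0.0) > 1e-12:
            raise ValueError("distance matrix diagonal is not zero")
        if (self.d < -1e-12).any():
            raise ValueError("negative distances")


@dataclass
class OrdinationResult:
    coordinates: np.ndarray  # points x axes (positive-eigenvalue axes)
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives reported)
    proportion_explained: np.ndarray  # per positive axis


@dataclass
class PermanovaResult:
    pseudo_F: float
    r_squared: float
    p_value: float
    n_permutations: int
    seed: int


def jaccard_distances(presence: pd.DataFrame) -> DistanceMatrix:
    """Pairwise Jaccard distances between the columns of a presence table.

    ``presence`` is a feature x point boolean table whose columns identify
    sample x method points on a common feature universe.  d = 1 - |A∩B|/|A∪B|;
    a pair of all-absent vectors gets d = 0 by convention (flagged).
    """
    mat = presence.to_numpy(dtype=bool).T
    if (~mat.any(axis=1)).sum() >= 2:
        warnings.warn("two or more all-absent vectors: their distance is 0 by convention")
    d = squareform(pdist(mat, metric="jaccard"))
    return DistanceMatrix(list(presence.columns), d)


def pcoa(dm: DistanceMatrix, n_axes: int | None = None) -> OrdinationResult:
    """Classical scaling of a distance matrix.

    Double-centres -D²/2, eigendecomposes, and embeds on the axes with
    positive eigenvalues (scaled by sqrt(eigenvalue)).  Negative
    eigenvalues — common for Jaccard matrices — are reported unaltered, not
    corrected.  When the matrix is Euclidean-embeddable, pairwise distances
    among the coordinates reproduce the input.
    """
    n = len(dm.labels)
    a = -0.5 * dm.d**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = j @ a @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos = eigvals > max(1e-12, 1e-10 * abs(eigvals[0]) if n else 0)
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    pos_sum = eigvals[pos].sum()
    prop = eigvals[pos] / pos_sum if pos_sum > 0 else np.zeros(int(pos.sum()))
    if n_axes is not None:
        coords = coords[:, :n_axes]
        prop = prop[:n_axes]
    return OrdinationResult(coords, eigvals, prop)


def _ss_within(d2: np.ndarray, labels: np.ndarray, groups: np.ndarray) -> float:
    ss = 0.0
    for g in groups:
        mask = labels == g
        n_g = int(mask.sum())
        ss += d2[np.ix_(mask, mask)].sum() / (2.0 * n_g)
    return ss


def permanova(
    dm: DistanceMatrix,
    groups,
    n_permutations: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """One-way PERMANOVA computed directly from the distance matrix.

    pseudo-F = (SS_between/(a-1)) / (SS_within/(N-a)) with the sums of
    squared distances taken directly from d (no coordinates needed);
    p = (1 + #{permuted F >= observed F}) / (1 + n_permutations), labels
    permuted with a seeded generator.
    """
    labels = np.asarray(list(groups))
    n = len(dm.labels)
    if labels.shape[0] != n:
        raise ValueError("one group label per point required")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    if (counts < 2).any():
        small = uniq[counts < 2]
        raise ValueError(f"groups of size 1: {list(small)}")

    d2 = dm.d**2
    ss_total = d2.sum() / (2.0 * n)
    a = len(uniq)
    df_between, df_within = a - 1, n - a

    codes = np.searchsorted(uniq, labels)
    # one-hot membership lets permuted within-group sums run as einsums
    def f_stat(code_rows: np.ndarray) -> np.ndarray:
        """F for each row of permuted group codes (rows x points)."""
        ssw = np.zeros(code_rows.shape[0])
        for g in range(a):
            m = (code_rows == g).astype(float)
            n_g = m[0].sum()
            ssw += np.einsum("pi,ij,pj->p", m, d2, m) / (2.0 * n_g)
        ssb = ss_total - ssw
        with np.errstate(divide="ignore", invalid="ignore"):
            return (ssb / df_between) / (ssw / df_within)

    ssw = _ss_within(d2, labels, uniq)
    ssb = ss_total - ssw
    with np.errstate(divide="ignore", invalid="ignore"):
        f_obs = float((ssb / df_between) / (ssw / df_within))
    r_squared = ssb / ss_total if ss_total > 0 else 0.0

    if not np.isfinite(f_obs):
        warnings.warn("degenerate pseudo-F (constant distances within groups)")

    rng = np.random.default_rng(seed)
    perm = np.tile(codes, (n_permutations, 1))
    perm = rng.permuted(perm, axis=1)
    f_perm = f_stat(perm)
    p = (1.0 + np.count_nonzero(f_perm >= f_obs)) / (1.0 + n_permutations)
    return PermanovaResult(f_obs, r_squared, p, n_permutations, seed)


def permanova_exact(dm: DistanceMatrix, groups) -> float:
    """Exhaustive permutation p-value (all label rearrangements).

    Feasible only for small designs; used as an oracle for the Monte-Carlo
    p-value.  Counts distinct assignments of points to the fixed group
    sizes, including the observed one.
    """
    labels = np.asarray(list(groups))
    uniq, counts = np.unique(labels, return_counts=True)
    d2 = dm.d**2
    n = len(labels)
    a = len(uniq)
    ss_total = d2.sum() / (2.0 * n)
    df_b, df_w = a - 1, n - a

    def f_of(lab: np.ndarray) -> float:
        ssw = _ss_within(d2, lab, uniq)
        return ((ss_total - ssw) / df_b) / (ssw / df_w)

    f_obs = f_of(labels)
    if a != 2:
        raise NotImplementedError("exact enumeration implemented for two groups")
    idx = np.arange(n)
    n1 = counts[0]
    total = 0
    ge = 0
    for members in combinations(idx, int(n1)):
        lab = np.full(n, uniq[1], dtype=labels.dtype)
        lab[list(members)] = uniq[0]
        total += 1
        if f_of(lab) >= f_obs - 1e-12:
            ge += 1
    return ge / total


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test on two count samples.

    Exact null distribution when both samples have <= 10 observations and
    no ties; otherwise the normal approximation with tie and continuity
    corrections.  Returns (U statistic, p value).
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical; p = 1")
        return float(len(x) * len(y) / 2.0), 1.0
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (no_ties and len(x) <= 10 and len(y) <= 10) else "asymptotic"
    res = mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def holm_adjust(p_values: dict[str, float]) -> dict[str, float]:
    """Holm step-down adjustment over a family of p-values (optional)."""
    items = sorted(p_values.items(), key=lambda kv: kv[1])
    m = len(items)
    adjusted: dict[str, float] = {}
    running = 0.0
    for rank, (key, p) in enumerate(items):
        running = max(running, min(1.0, (m - rank) * p))
        adjusted[key] = running
    return {k: adjusted[k] for k in p_values}
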