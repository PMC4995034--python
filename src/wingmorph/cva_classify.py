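"""Canonical variate analysis, Mahalanobis distances, and cross-validated
reclassification of landmark shape data.

With k landmarks the tangent space has rank at most 2k - 4 while group sample
sizes may be smaller, so the pooled within-group covariance can be singular.
All group-level statistics therefore operate in a principal-component subspace:
the tangent coordinates are reduced to the smaller of (components reaching
``variance_retained`` of the total variance) and (N - g - 1) dimensions before
the canonical axes, Mahalanobis distances, or classification rules are formed.

Canonical axes solve the between-group versus pooled within-group generalized
eigenproblem in the reduced space, scaled so the pooled within-group variance
along each axis is one (Mahalanobis scaling).  Leave-one-out reclassification
is strict: the reduction, group means, and pooled covariance are recomputed
for every fold with the held-out specimen excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.linalg

from .gpa import ProcrustesResult, generalized_procrustes
from .landmark_io import ShapeDataset, select_landmarks

logger = logging.getLogger(__name__)

#: landmark subsets evaluated by default (1-based): minimal five, seven, nine
DEFAULT_SUBSETS = (
    (1, 2, 14, 15, 16),
    (1, 2, 14, 15, 16, 17, 18),
    (1, 2, 12, 13, 14, 15, 16, 17, 18),
)


# ---------------------------------------------------------------------------
# linear-algebra helpers

def _pca_reduce(x: np.ndarray, n_groups: int, variance_retained: float):
    """Reduce centred data to min(PCs reaching variance_retained, N-g-1, rank).

    Returns (scores, basis, center) with basis of shape (d, p).
    """
    n = x.shape[0]
    center = x.mean(axis=0)
    xc = x - center
    _, s, vt = np.linalg.svd(xc, full_matrices=False)
    rank = int((s > s[0] * 1e-10).sum()) if s.size and s[0] > 0 else 0
    if rank == 0:
        raise ValueError("data have zero variance; nothing to analyse")
    var = s ** 2
    cum = np.cumsum(var) / var.sum()
    m_vr = int(np.searchsorted(cum, variance_retained - 1e-12) + 1)
    d = min(m_vr, n - n_groups - 1, rank)
    if d < 1:
        raise ValueError(
            f"too few specimens (n={n}) for {n_groups} groups after dimension reduction"
        )
    basis = vt[:d]
    return xc @ basis.T, basis, center


def mahalanobis_distance(mean_a: np.ndarray, mean_b: np.ndarray,
                         pooled_cov: np.ndarray) -> float:
    """Mahalanobis distance sqrt((a-b)' Sigma^-1 (a-b)) between two means."""
    delta = np.asarray(mean_a, float) - np.asarray(mean_b, float)
    try:
        cho = scipy.linalg.cho_factor(pooled_cov)
    except scipy.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "pooled covariance is singular in the working subspace; reduce the "
            "dimension (e.g. lower variance_retained)"
        ) from exc
    return float(np.sqrt(delta @ scipy.linalg.cho_solve(cho, delta)))


def _group_stats(y: np.ndarray, labels: np.ndarray, groups: Sequence[str]):
    """Group means and pooled within-group covariance of reduced scores."""
    n, d = y.shape
    g = len(groups)
    means = np.empty((g, d))
    within = np.zeros((d, d))
    for i, grp in enumerate(groups):
        yg = y[labels == grp]
        if len(yg) < 2:
            raise ValueError(f"group {grp!r} has fewer than 2 specimens")
        means[i] = yg.mean(axis=0)
        dev = yg - means[i]
        within += dev.T @ dev
    pooled = within / (n - g)
    return means, pooled


def _mahalanobis_matrix(means: np.ndarray, pooled: np.ndarray) -> np.ndarray:
    g = means.shape[0]
    try:
        cho = scipy.linalg.cho_factor(pooled)
    except scipy.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "pooled covariance is singular; reduce the dimension"
        ) from exc
    out = np.zeros((g, g))
    for i in range(g):
        for j in range(i + 1, g):
            delta = means[i] - means[j]
            out[i, j] = out[j, i] = np.sqrt(delta @ scipy.linalg.cho_solve(cho, delta))
    return out


def _ordered_groups(labels: np.ndarray) -> list:
    """Unique group labels in order of first appearance."""
    seen = dict.fromkeys(labels)
    return list(seen)


# ---------------------------------------------------------------------------
# canonical variate analysis

@dataclass
class CVAResult:
    """Canonical variate analysis of one grouping level.

    Attributes
    ----------
    grouping : str
        Level used (genus / subgenus / species).
    groups : list of str
    axes : (d, a) ndarray
        Canonical vectors in the reduced PC space, scaled so the pooled
        within-group variance along each axis is 1.
    axes_tangent : (2k, a) ndarray
        The same axes expressed in tangent-coordinate space.
    eigenvalues : (a,) ndarray, nonincreasing and nonnegative
    scores : (n, a) ndarray
        Specimen scores (CV1, CV2, ...).
    group_means : (g, d) ndarray
        Group means in the reduced space.
    mahalanobis : DataFrame
        Symmetric g x g Mahalanobis distance matrix of the group means.
    pc_dims_used : int
    pooled_cov : (d, d) ndarray
    labels : (n,) ndarray of group label per specimen
    """

    grouping: str
    groups: list
    axes: np.ndarray
    axes_tangent: np.ndarray
    eigenvalues: np.ndarray
    scores: np.ndarray
    group_means: np.ndarray
    mahalanobis: pd.DataFrame
    pc_dims_used: int
    pooled_cov: np.ndarray
    labels: np.ndarray

    def scores_frame(self) -> pd.DataFrame:
        cols = {f"CV{i + 1}": self.scores[:, i] for i in range(self.scores.shape[1])}
        return pd.DataFrame({"group": self.labels, **cols})


def cva(proc: ProcrustesResult, grouping: str,
        variance_retained: float = 0.99) -> CVAResult:
    """Canonical variate analysis of the superimposed sample at one level."""
    labels = proc.group_labels(grouping)
    groups = _ordered_groups(labels)
    g = len(groups)
    if g < 2:
        raise ValueError("CVA needs at least 2 groups")
    y, basis, _ = _pca_reduce(proc.tangent_coords, g, variance_retained)
    d = y.shape[1]
    means, pooled = _group_stats(y, labels, groups)
    counts = np.array([(labels == grp).sum() for grp in groups])
    grand = (counts[:, None] * means).sum(axis=0) / counts.sum()
    dev = means - grand
    between = (counts[:, None] * dev).T @ dev / (g - 1)

    try:
        evals, evecs = scipy.linalg.eigh(between, pooled)
    except scipy.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "pooled covariance singular in reduced space; lower variance_retained"
        ) from exc
    order = np.argsort(evals)[::-1]
    n_axes = min(g - 1, d)
    axes = evecs[:, order[:n_axes]]
    eigenvalues = np.clip(evals[order[:n_axes]], 0.0, None)
    # deterministic sign: largest-magnitude loading positive
    for j in range(axes.shape[1]):
        lead = np.argmax(np.abs(axes[:, j]))
        if axes[lead, j] < 0:
            axes[:, j] = -axes[:, j]

    scores = y @ axes
    maha = pd.DataFrame(_mahalanobis_matrix(means, pooled), index=groups, columns=groups)
    return CVAResult(
        grouping=grouping, groups=groups, axes=axes,
        axes_tangent=basis.T @ axes, eigenvalues=eigenvalues, scores=scores,
        group_means=means, mahalanobis=maha, pc_dims_used=d,
        pooled_cov=pooled, labels=labels,
    )


# ---------------------------------------------------------------------------
# cross-validated reclassification

def loo_reclassify(proc: ProcrustesResult, groups: Sequence[str],
                   grouping: str = "species",
                   variance_retained: float = 0.99):
    """Pairwise leave-one-out reclassification between two groups.

    For each specimen in turn the PCA reduction, group means, and pooled
    covariance are recomputed from the remaining specimens, and the held-out
    specimen is assigned to the group with the smaller Mahalanobis distance.
    Exact ties are broken toward the first group (and logged).

    Returns
    -------
    (percent_correct_group1, percent_correct_group2, assignments)
        Percent of each group's specimens correctly assigned, plus a DataFrame
        of per-specimen assignments.
    """
    if len(groups) != 2 or groups[0] == groups[1]:
        raise ValueError("loo_reclassify takes exactly two distinct group labels")
    labels_all = proc.group_labels(grouping)
    mask = np.isin(labels_all, list(groups))
    x = proc.tangent_coords[mask]
    y_lab = labels_all[mask]
    ids = [sid for sid, m in zip(proc.specimen_ids, mask) if m]
    for grp in groups:
        if (y_lab == grp).sum() < 3:
            raise ValueError(f"group {grp!r} has fewer than 3 specimens")

    n = len(y_lab)
    assigned = []
    for i in range(n):
        keep = np.ones(n, bool)
        keep[i] = False
        xtr, ytr = x[keep], y_lab[keep]
        yred, basis, center = _pca_reduce(xtr, 2, variance_retained)
        means, pooled = _group_stats(yred, ytr, groups)
        held = (x[i] - center) @ basis.T
        dist = [mahalanobis_distance(held, means[j], pooled) for j in range(2)]
        if dist[0] == dist[1]:
            logger.warning("tied Mahalanobis distances for %r; assigning to %r",
                           ids[i], groups[0])
            assigned.append(groups[0])
        else:
            assigned.append(groups[int(dist[1] < dist[0])])
    assigned = np.array(assigned)
    correct = assigned == y_lab
    pct = [100.0 * correct[y_lab == grp].mean() for grp in groups]
    table = pd.DataFrame({"specimen_id": ids, "true": y_lab,
                          "assigned": assigned, "correct": correct})
    return pct[0], pct[1], table


@dataclass
class ReclassificationTable:
    """Pairwise cross-validated reclassification rates.

    ``percent_correct`` holds, in cell (i, j) with i != j, the percent of
    group-i specimens correctly assigned in the pairwise i-vs-j test; the
    diagonal is undefined (NaN).  The table need not be symmetric.
    ``mean_rate`` is the unweighted mean of all off-diagonal cells.
    """

    taxa: list
    percent_correct: pd.DataFrame
    mean_rate: float

    @property
    def offdiag(self) -> np.ndarray:
        vals = self.percent_correct.to_numpy()
        return vals[~np.eye(len(self.taxa), dtype=bool)]


def pairwise_table(proc: ProcrustesResult, grouping: str,
                   variance_retained: float = 0.99) -> ReclassificationTable:
    """Run :func:`loo_reclassify` for every unordered pair of groups."""
    labels = proc.group_labels(grouping)
    taxa = _ordered_groups(labels)
    if len(taxa) < 2:
        raise ValueError("pairwise table needs at least 2 groups")
    g = len(taxa)
    table = np.full((g, g), np.nan)
    for i in range(g):
        for j in range(i + 1, g):
            pct_i, pct_j, _ = loo_reclassify(
                proc, (taxa[i], taxa[j]), grouping=grouping,
                variance_retained=variance_retained,
            )
            table[i, j] = pct_i
            table[j, i] = pct_j
    frame = pd.DataFrame(table, index=taxa, columns=taxa)
    mean_rate = float(np.nanmean(table))
    return ReclassificationTable(taxa=taxa, percent_correct=frame, mean_rate=mean_rate)


def evaluate_landmark_subsets(dataset: ShapeDataset,
                              subsets: Iterable[Sequence[int]] | None = None,
                              grouping: str = "genus",
                              variance_retained: float = 0.99) -> pd.DataFrame:
    """Reclassification performance of reduced landmark sets.

    For each subset of 1-based landmark indices the dataset is restricted to
    those landmarks, re-superimposed, and the pairwise cross-validated table
    recomputed at ``grouping`` level.  Returns one row per subset with the
    minimum and mean off-diagonal accuracy.
    """
    if subsets is None:
        subsets = DEFAULT_SUBSETS
    rows = []
    for subset in subsets:
        subset = tuple(subset)
        if len(subset) < 3:
            raise ValueError(f"subset {subset} has fewer than 3 landmarks")
        reduced = select_landmarks(dataset, subset)
        proc = generalized_procrustes(reduced)
        table = pairwise_table(proc, grouping, variance_retained=variance_retained)
        rows.append({
            "subset": ",".join(map(str, subset)),
            "n_landmarks": len(subset),
            "min_accuracy": float(np.nanmin(table.percent_correct.to_numpy())),
            "mean_accuracy": table.mean_rate,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# permutation test on group separation

def separation_permutation_p(proc: ProcrustesResult, grouping: str,
                             n_permutations: int = 1000, seed: int | None = 0,
                             variance_retained: float = 0.99) -> float:
    """Permutation p-value for overall group separation.

    Statistic: mean pairwise Mahalanobis distance between group means,
    recomputed under random permutations of the group labels in the fixed
    global PC space (add-one corrected).
    """
    labels = proc.group_labels(grouping)
    groups = _ordered_groups(labels)
    y, _, _ = _pca_reduce(proc.tangent_coords, len(groups), variance_retained)

    def stat(lab):
        means, pooled = _group_stats(y, lab, groups)
        m = _mahalanobis_matrix(means, pooled)
        return m[np.triu_indices_from(m, k=1)].mean()

    observed = stat(labels)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        count += stat(rng.permutation(labels)) >= observed
    return (1 + count) / (1 + n_permutations)


def mean_silhouette(points: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette coefficient of a labelled point cloud.

    For each point, a = mean distance to its own cluster, b = smallest mean
    distance to another cluster; the silhouette is (b - a) / max(a, b).
    Used to quantify cluster distinctness in CVA morphospace.
    """
    points = np.asarray(points, float)
    labels = np.asarray(labels)
    groups = _ordered_groups(labels)
    if len(groups) < 2:
        raise ValueError("silhouette needs at least 2 clusters")
    d = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    n = len(points)
    sil = np.empty(n)
    for i in range(n):
        own = labels == labels[i]
        n_own = own.sum()
        if n_own == 1:
            sil[i] = 0.0
            continue
        a = d[i, own].sum() / (n_own - 1)
        b = min(d[i, labels == grp].mean() for grp in groups if grp != labels[i])
        sil[i] = (b - a) / max(a, b)
    return float(sil.mean())
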