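"""Generalized Procrustes analysis for 2-D landmark configurations.

Superimposition removes translation, scale, and rotation from a sample of
configurations, leaving pure shape variation around a consensus (mean) shape.
The fit is a full Procrustes fit: every configuration is scaled to unit
centroid size, and only rotations (no reflections — all specimens are the same
side's wing) are optimized against the running consensus.  Shape coordinates
are returned both as aligned (k, 2) configurations and as tangent-space
vectors obtained by orthogonal projection at the consensus, in which standard
multivariate statistics are valid for small variation.

After convergence the whole solution is rotated so the consensus sits in a
canonical orientation (principal axes, sign fixed by coordinate third moments),
which makes the consensus invariant to specimen input order rather than merely
invariant up to rotation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .landmark_io import LandmarkConfiguration, ShapeDataset

logger = logging.getLogger(__name__)


def centroid_size(config) -> float:
    """Centroid size: root of summed squared landmark distances to the centroid.

    Accepts a :class:`LandmarkConfiguration` or a (k, 2) array.  Invariant to
    rotation and translation; scales linearly under uniform scaling.
    """
    coords = config.coords if isinstance(config, LandmarkConfiguration) else np.asarray(config, float)
    if coords.ndim != 2 or coords.shape[1] != 2 or coords.shape[0] < 3:
        raise ValueError("centroid size needs a (k>=3, 2) configuration")
    centered = coords - coords.mean(axis=0)
    cs = float(np.sqrt((centered ** 2).sum()))
    if cs <= 0.0:
        raise ValueError("degenerate configuration: all landmarks coincide")
    return cs


class OPAResult(NamedTuple):
    aligned: np.ndarray      # source mapped onto target, (k, 2)
    angle: float             # rotation angle (radians)
    scale: float             # scale factor applied to the centred source
    residual: float          # root summed squared distance to target


def opa_align(source: np.ndarray, target: np.ndarray) -> OPAResult:
    """Ordinary (full) Procrustes alignment of ``source`` onto ``target``.

    Minimizes the summed squared landmark distances over translation, scale and
    rotation; reflections are not allowed.
    """
    s = np.asarray(source, float)
    t = np.asarray(target, float)
    if s.shape != t.shape or s.ndim != 2 or s.shape[1] != 2:
        raise ValueError(f"shape mismatch: {s.shape} vs {t.shape}")
    sc = s - s.mean(axis=0)
    tc = t - t.mean(axis=0)
    ss = (sc ** 2).sum()
    if ss <= 0 or (tc ** 2).sum() <= 0:
        raise ValueError("degenerate configuration in OPA")
    a = float((sc * tc).sum())
    b = float((sc[:, 0] * tc[:, 1] - sc[:, 1] * tc[:, 0]).sum())
    theta = float(np.arctan2(b, a))
    beta = float(np.hypot(a, b) / ss)
    c, sn = np.cos(theta), np.sin(theta)
    rot = np.array([[c, -sn], [sn, c]])
    aligned = beta * sc @ rot.T + t.mean(axis=0)
    resid_ss = max((tc ** 2).sum() - (a * a + b * b) / ss, 0.0)
    return OPAResult(aligned, theta, beta, float(np.sqrt(resid_ss)))


@dataclass
class ProcrustesResult:
    """Output of generalized Procrustes analysis.

    Attributes
    ----------
    consensus : (k, 2) ndarray
        Mean shape, centred at the origin with unit centroid size.
    aligned : (n, k, 2) ndarray
        Procrustes shape coordinates (centred, unit centroid size, rotated).
    tangent_coords : (n, 2k) ndarray
        Tangent-space coordinates at the consensus (consensus plus the
        component of each aligned shape orthogonal to the consensus).
    centroid_sizes : (n,) ndarray
        Centroid sizes in the input units.
    specimen_ids : list of str
    labels : DataFrame or None
        Per-specimen labels (genus/subgenus/species/site) when built from a
        labelled dataset.
    iterations : int
    converged : bool
    """

    consensus: np.ndarray
    aligned: np.ndarray
    tangent_coords: np.ndarray
    centroid_sizes: np.ndarray
    specimen_ids: list
    labels: pd.DataFrame | None
    iterations: int
    converged: bool

    @property
    def n_specimens(self) -> int:
        return self.aligned.shape[0]

    @property
    def landmark_count(self) -> int:
        return self.aligned.shape[1]

    def group_labels(self, level: str) -> np.ndarray:
        if self.labels is None:
            raise ValueError("this ProcrustesResult carries no labels")
        vals = self.labels[level].to_numpy()
        if (vals == "").any():
            raise ValueError(f"some specimens lack a {level!r} label")
        return vals

    def subset(self, mask) -> "ProcrustesResult":
        """Re-superimpose the subset of specimens where ``mask`` is True."""
        mask = np.asarray(mask, bool)
        coords = self.aligned[mask] * self.centroid_sizes[mask, None, None]
        labels = self.labels.iloc[mask].reset_index(drop=True) if self.labels is not None else None
        ids = [sid for sid, m in zip(self.specimen_ids, mask) if m]
        return generalized_procrustes_array(coords, specimen_ids=ids, labels=labels)

    def to_frame(self) -> pd.DataFrame:
        """Aligned coordinates as a tidy table (specimen, landmark, x, y, size)."""
        n, k, _ = self.aligned.shape
        rows = []
        for i in range(n):
            for j in range(k):
                rows.append({
                    "specimen_id": self.specimen_ids[i], "landmark": j + 1,
                    "x": self.aligned[i, j, 0], "y": self.aligned[i, j, 1],
                    "centroid_size": self.centroid_sizes[i],
                })
        return pd.DataFrame(rows)


def _rotate_all(shapes: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Optimally rotate each centred unit-size shape in (n, k, 2) onto target."""
    a = np.einsum("nkd,kd->n", shapes, target)
    b = np.einsum("nk,k->n", shapes[:, :, 0], target[:, 1]) - \
        np.einsum("nk,k->n", shapes[:, :, 1], target[:, 0])
    theta = np.arctan2(b, a)
    c, s = np.cos(theta), np.sin(theta)
    x, y = shapes[:, :, 0], shapes[:, :, 1]
    out = np.empty_like(shapes)
    out[:, :, 0] = c[:, None] * x - s[:, None] * y
    out[:, :, 1] = s[:, None] * x + c[:, None] * y
    return out


def _canonicalize(consensus: np.ndarray) -> np.ndarray:
    """Rotation matrix putting ``consensus`` into a canonical orientation.

    Major principal axis along x; the remaining 180-degree ambiguity is broken
    by requiring a positive third moment along x (falling back to y for shapes
    symmetric about their major axis).
    """
    m = consensus.T @ consensus
    _, vecs = np.linalg.eigh(m)
    major = vecs[:, -1]
    theta = np.arctan2(major[1], major[0])
    c, s = np.cos(-theta), np.sin(-theta)
    rot = np.array([[c, -s], [s, c]])
    cand = consensus @ rot.T
    skew_x = (cand[:, 0] ** 3).sum()
    skew = skew_x if abs(skew_x) > 1e-12 else (cand[:, 1] ** 3).sum()
    if skew < 0:
        rot = -rot  # rotate by an extra pi
    return rot


def generalized_procrustes(dataset: ShapeDataset, tol: float = 1e-10,
                           max_iter: int = 100) -> ProcrustesResult:
    """Generalized Procrustes superimposition of a labelled dataset."""
    return generalized_procrustes_array(
        dataset.coords_array(),
        specimen_ids=dataset.specimen_ids,
        labels=dataset.labels_frame(),
        tol=tol, max_iter=max_iter,
    )


def generalized_procrustes_array(coords: np.ndarray, specimen_ids=None,
                                 labels: pd.DataFrame | None = None,
                                 tol: float = 1e-10,
                                 max_iter: int = 100) -> ProcrustesResult:
    """GPA on a raw (n, k, 2) coordinate array.

    Iterates: scale all configurations to unit centroid size, rotate each onto
    the current consensus, recompute the consensus (renormalized to unit
    centroid size), until the root-summed-squared change in the consensus falls
    below ``tol`` or ``max_iter`` is reached.
    """
    coords = np.asarray(coords, float)
    if coords.ndim != 3 or coords.shape[2] != 2:
        raise ValueError("coords must be (n, k, 2)")
    n, k, _ = coords.shape
    if n < 2:
        raise ValueError("GPA needs at least 2 configurations")
    if specimen_ids is None:
        specimen_ids = [f"spec_{i + 1}" for i in range(n)]

    centred = coords - coords.mean(axis=1, keepdims=True)
    sizes = np.sqrt((centred ** 2).sum(axis=(1, 2)))
    if np.any(sizes <= 0):
        raise ValueError("degenerate configuration (zero centroid size)")
    unit = centred / sizes[:, None, None]

    consensus = unit[0]
    converged = False
    iterations = 0
    aligned = unit
    for iterations in range(1, max_iter + 1):
        aligned = _rotate_all(unit, consensus)
        new = aligned.mean(axis=0)
        new = new - new.mean(axis=0)
        new /= np.sqrt((new ** 2).sum())
        delta = np.sqrt(((new - consensus) ** 2).sum())
        consensus = new
        if delta < tol:
            converged = True
            break
    if not converged:
        logger.warning("GPA did not converge in %d iterations", max_iter)

    rot = _canonicalize(consensus)
    consensus = consensus @ rot.T
    aligned = _rotate_all(unit, consensus)

    # orthogonal tangent projection at the consensus
    flat = aligned.reshape(n, 2 * k)
    c = consensus.reshape(2 * k)
    tangent = c + (flat - np.outer(flat @ c, c))

    return ProcrustesResult(
        consensus=consensus, aligned=aligned, tangent_coords=tangent,
        centroid_sizes=sizes, specimen_ids=list(specimen_ids), labels=labels,
        iterations=iterations, converged=converged,
    )
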