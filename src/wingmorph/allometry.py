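"""Allometry: multivariate regression of shape on centroid size.

The allometric influence of wing size on wing shape is quantified as the
percentage of total tangent-space shape variance predicted by a least-squares
regression of every tangent coordinate on centroid size, and tested with a
permutation null that shuffles the size vector against the shapes.  The
regressor defaults to natural-log centroid size (configurable to linear).

The permutation p-value uses the add-one correction,
``p = (1 + #{permuted >= observed}) / (1 + n_permutations)``, so it is always
positive and its floor is ``1/(n_permutations + 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gpa import ProcrustesResult, generalized_procrustes_array


@dataclass
class AllometryResult:
    """Result of the shape-on-size regression.

    Attributes
    ----------
    percent_predicted : float
        Percentage (0-100) of total shape variance explained by size.
    p_value : float
        Permutation p-value (1.0 when ``n_permutations == 0``).
    coefficients : (2k,) ndarray
        Regression slope of each tangent coordinate on (log) size.
    n_permutations : int
    seed : int or None
    size_scale : str
        'log' or 'linear'.
    n : int
        Number of specimens.
    """

    percent_predicted: float
    p_value: float
    coefficients: np.ndarray
    n_permutations: int
    seed: int | None
    size_scale: str
    n: int


def allometry_regression(proc: ProcrustesResult, n_permutations: int = 10000,
                         seed: int | None = 0,
                         size_scale: str = "log") -> AllometryResult:
    """Regress tangent shape coordinates on centroid size with a permutation test.

    Parameters
    ----------
    proc : ProcrustesResult
        Superimposed sample (>= 3 specimens, sizes not all equal).
    n_permutations : int
        Randomizations for the permutation test; 0 skips the test.
    seed : int
        Seed for the permutation stream; results are reproducible bit-exactly
        for a given (seed, n_permutations).
    size_scale : {'log', 'linear'}
        Whether to regress on natural-log or raw centroid size.
    """
    if proc.n_specimens < 3:
        raise ValueError("allometry regression needs at least 3 specimens")
    sizes = proc.centroid_sizes
    if np.ptp(sizes) == 0:
        raise ValueError("centroid sizes are all equal; size effect undefined")
    if size_scale == "log":
        z = np.log(sizes)
    elif size_scale == "linear":
        z = sizes.astype(float)
    else:
        raise ValueError(f"size_scale must be 'log' or 'linear', got {size_scale!r}")

    x = proc.tangent_coords - proc.tangent_coords.mean(axis=0)
    zc = z - z.mean()
    denom = float(zc @ zc)
    xtz = x.T @ zc                       # (2k,)
    coefficients = xtz / denom
    ss_pred = float((xtz ** 2).sum() / denom)
    ss_tot = float((x ** 2).sum())
    percent = 100.0 * ss_pred / ss_tot

    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        perms = rng.permuted(np.broadcast_to(zc, (n_permutations, len(zc))), axis=1)
        ss_pred_perm = ((perms @ x) ** 2).sum(axis=1) / denom
        p = (1 + int((ss_pred_perm >= ss_pred).sum())) / (1 + n_permutations)
    else:
        p = 1.0

    return AllometryResult(
        percent_predicted=percent, p_value=float(p), coefficients=coefficients,
        n_permutations=n_permutations, seed=seed, size_scale=size_scale,
        n=proc.n_specimens,
    )


def remove_allometry(proc: ProcrustesResult, size_scale: str = "log") -> ProcrustesResult:
    """Return a result with the allometric component regressed out of shape.

    Residuals of the shape-on-size regression are added back onto the
    consensus, and the residual shapes are re-superimposed so all derived
    fields stay consistent.  The main pipeline deliberately does *not* apply
    this: allometric size variation is treated as part of the identification
    signal.
    """
    res = allometry_regression(proc, n_permutations=0, size_scale=size_scale)
    z = np.log(proc.centroid_sizes) if size_scale == "log" else proc.centroid_sizes
    zc = z - z.mean()
    resid = proc.tangent_coords - np.outer(zc, res.coefficients)
    shapes = resid.reshape(proc.n_specimens, proc.landmark_count, 2)
    return generalized_procrustes_array(
        shapes * proc.centroid_sizes[:, None, None],
        specimen_ids=proc.specimen_ids, labels=proc.labels,
    )
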