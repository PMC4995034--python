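"""Thin-plate-spline interpolation between landmark shapes.

The 2-D thin-plate spline with kernel U(r) = r^2 log r^2 interpolates one
landmark configuration onto another exactly while minimizing bending energy,
the standard magnitude of non-affine shape change: it is zero precisely when
the target is an affine image of the source.  Splines are used here to render
deformation grids and wireframes at the extremes of canonical variate axes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cva_classify import CVAResult
from .gpa import ProcrustesResult

#: default wireframe links (1-based) tracing the wing outline and the inner
#: vein intersections of the 18-landmark template; editable per dataset
DEFAULT_LINKS = (
    (1, 2), (2, 3), (3, 4), (4, 5), (5, 6), (6, 7), (7, 8), (8, 9),
    (9, 10), (10, 1),
    (1, 11), (11, 12), (12, 13), (13, 14), (14, 15), (15, 5),
    (11, 18), (18, 17), (17, 16), (16, 6), (17, 14),
)


def _kernel(r2: np.ndarray) -> np.ndarray:
    """U(r) = r^2 log r^2, with U(0) = 0."""
    out = np.zeros_like(r2)
    nz = r2 > 0
    out[nz] = r2[nz] * np.log(r2[nz])
    return out


def _tps_system(source: np.ndarray):
    k = source.shape[0]
    d2 = ((source[:, None, :] - source[None, :, :]) ** 2).sum(-1)
    kk = _kernel(d2)
    p = np.column_stack([np.ones(k), source])
    left = np.zeros((k + 3, k + 3))
    left[:k, :k] = kk
    left[:k, k:] = p
    left[k:, :k] = p.T
    return kk, left


@dataclass
class TPSWarp:
    """A fitted thin-plate-spline deformation mapping source onto target.

    ``affine`` holds the (3, 2) affine coefficients (constant, x, y per output
    dimension); ``weights`` the (k, 2) non-affine kernel coefficients.
    ``bending_energy`` is the value of the bending-energy quadratic form; it is
    direction-dependent (source -> target in general differs from the reverse).
    """

    source: np.ndarray
    target: np.ndarray
    affine: np.ndarray
    weights: np.ndarray
    bending_energy: float

    def __call__(self, points: np.ndarray) -> np.ndarray:
        """Evaluate the warp at arbitrary (m, 2) points."""
        pts = np.atleast_2d(np.asarray(points, float))
        d2 = ((pts[:, None, :] - self.source[None, :, :]) ** 2).sum(-1)
        u = _kernel(d2)
        p = np.column_stack([np.ones(len(pts)), pts])
        return u @ self.weights + p @ self.affine


def fit_tps(source: np.ndarray, target: np.ndarray) -> TPSWarp:
    """Fit the thin-plate spline carrying ``source`` landmarks onto ``target``.

    Raises a linear-algebra error when source landmarks coincide (singular
    interpolation system).
    """
    source = np.asarray(source, float)
    target = np.asarray(target, float)
    if source.shape != target.shape or source.ndim != 2 or source.shape[1] != 2:
        raise ValueError(f"shape mismatch: {source.shape} vs {target.shape}")
    k = source.shape[0]
    if len(np.unique(source, axis=0)) < k:
        raise np.linalg.LinAlgError("coincident source landmarks: singular TPS system")
    kk, left = _tps_system(source)
    rhs = np.zeros((k + 3, 2))
    rhs[:k] = target
    try:
        sol = np.linalg.solve(left, rhs)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(f"singular TPS system: {exc}") from exc
    weights, affine = sol[:k], sol[k:]
    be = float(sum(weights[:, d] @ kk @ weights[:, d] for d in range(2)))
    return TPSWarp(source=source, target=target, affine=affine, weights=weights,
                   bending_energy=max(be, 0.0))


def shape_along_axis(cva_result: CVAResult, proc: ProcrustesResult,
                     axis: int, score: float) -> np.ndarray:
    """Model wing shape at a given score on a canonical axis.

    Tangent coordinates are regressed on the scores of canonical axis ``axis``
    (1-based: CV1 is axis 1); the returned (k, 2) shape is the consensus plus
    slope times ``score``, the wireframe endpoint drawn in morphospace figures.
    At score 0 the consensus itself is returned.
    """
    n_axes = cva_result.scores.shape[1]
    if not (1 <= axis <= n_axes):
        raise ValueError(f"axis {axis} out of range 1..{n_axes}")
    s = cva_result.scores[:, axis - 1]
    sc = s - s.mean()
    x = proc.tangent_coords
    slope = (x - x.mean(axis=0)).T @ sc / (sc @ sc)
    flat = proc.consensus.reshape(-1) + slope * score
    return flat.reshape(-1, 2)


def render_wireframe(shape_a: np.ndarray, shape_b: np.ndarray,
                     links=DEFAULT_LINKS, out=None, grid: bool = False,
                     ax=None):
    """Overlay two wireframes (reference grey, deformed black), optionally on a
    thin-plate-spline deformation grid, and write the figure to ``out``.

    ``links`` are 1-based landmark index pairs.
    """
    import matplotlib.pyplot as plt

    shape_a = np.asarray(shape_a, float)
    shape_b = np.asarray(shape_b, float)
    k = shape_a.shape[0]
    for i, j in links:
        if not (1 <= i <= k and 1 <= j <= k):
            raise ValueError(f"wireframe link ({i},{j}) outside 1..{k}")

    own_fig = ax is None
    if own_fig:
        fig, ax = plt.subplots(figsize=(5, 4))
    else:
        fig = ax.figure

    if grid:
        warp = fit_tps(shape_a, shape_b)
        lo = shape_a.min(axis=0)
        hi = shape_a.max(axis=0)
        pad = 0.1 * (hi - lo)
        xs = np.linspace(lo[0] - pad[0], hi[0] + pad[0], 20)
        ys = np.linspace(lo[1] - pad[1], hi[1] + pad[1], 20)
        dense = np.linspace(0.0, 1.0, 60)
        for x0 in xs:
            line = np.column_stack([np.full_like(dense, x0),
                                    ys[0] + dense * (ys[-1] - ys[0])])
            w = warp(line)
            ax.plot(w[:, 0], w[:, 1], color="0.85", lw=0.5, zorder=0)
        for y0 in ys:
            line = np.column_stack([xs[0] + dense * (xs[-1] - xs[0]),
                                    np.full_like(dense, y0)])
            w = warp(line)
            ax.plot(w[:, 0], w[:, 1], color="0.85", lw=0.5, zorder=0)

    for shape, color, lw in ((shape_a, "0.6", 1.0), (shape_b, "black", 1.5)):
        for i, j in links:
            seg = shape[[i - 1, j - 1]]
            ax.plot(seg[:, 0], seg[:, 1], color=color, lw=lw)
        ax.plot(shape[:, 0], shape[:, 1], "o", color=color, ms=3)
    ax.set_aspect("equal")
    ax.axis("off")

    if out is not None:
        _save_deterministic(fig, out)
    if own_fig:
        plt.close(fig)
    return ax


def _save_deterministic(fig, out):
    """Save a figure with metadata fixed so repeat runs are byte-identical."""
    out = str(out)
    if out.endswith(".svg"):
        fig.savefig(out, metadata={"Date": None})
    elif out.endswith(".png"):
        fig.savefig(out, metadata={"Software": "wingmorph"})
    else:
        fig.savefig(out)
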