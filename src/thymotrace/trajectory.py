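"""Single-lineage principal-curve pseudotime.

A Hastie-Stuetzle-style iteration fits a smooth one-dimensional curve
through the cells' PC coordinates: initialise arc-length positions by
projection on the points' first principal axis, then alternate (i)
smoothing each coordinate against arc length (lowess) and (ii) projecting
every point onto the resulting polyline. Pseudotime is the normalised
arc-length position, oriented to increase with the first input coordinate
(oriented PC1 in the pipeline), so larger pseudotime means more mature.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess


@dataclass
class TrajectoryResult:
    pseudotime: np.ndarray
    curve_points: np.ndarray  # ordered polyline vertices in the input space
    converged: bool
    iterations: int


def _project_to_polyline(
    pts: np.ndarray, verts: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Arc-length position and foot point of each point on a polyline."""
    a = verts[:-1]
    seg = verts[1:] - a
    seg_len2 = (seg**2).sum(axis=1)
    seg_len2 = np.where(seg_len2 == 0, 1e-300, seg_len2)
    seg_len = np.sqrt((seg**2).sum(axis=1))
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    diff = pts[:, None, :] - a[None, :, :]
    t = np.clip((diff * seg[None, :, :]).sum(axis=2) / seg_len2[None, :], 0.0, 1.0)
    foot = a[None, :, :] + t[:, :, None] * seg[None, :, :]
    d2 = ((pts[:, None, :] - foot) ** 2).sum(axis=2)
    k = d2.argmin(axis=1)
    rows = np.arange(pts.shape[0])
    s = cum[k] + t[rows, k] * seg_len[k]
    return s, foot[rows, k]


def principal_curve(
    points: np.ndarray,
    max_iter: int = 20,
    tol: float = 1e-4,
    lowess_frac: float = 0.3,
    n_grid: int = 200,
    seed: int | None = None,
) -> TrajectoryResult:
    """Fit a principal curve and return arc-length pseudotime in [0, 1].

    ``tol`` is relative: iteration stops when the mean squared movement of
    the projected points drops below ``tol`` times the total variance of
    the input. Non-convergence returns the best iterate with
    ``converged=False``. ``seed`` only perturbs exactly tied initial
    positions so orderings are well defined.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] < 2:
        raise ValueError("points must be an n x d array with d >= 2")
    n = pts.shape[0]
    if n < 10:
        raise ValueError("need at least 10 points for a principal curve")

    center = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - center, full_matrices=False)
    lam = (pts - center) @ vt[0]
    if np.unique(lam).size < lam.size:
        jitter_rng = np.random.default_rng(0 if seed is None else seed)
        lam = lam + jitter_rng.normal(0.0, 1e-9 * (lam.std() + 1e-12), size=n)

    scale = pts.var(axis=0).sum()
    if scale == 0:
        raise ValueError("points are all identical")
    prev_foot = None
    converged = False
    iterations = 0
    foot = pts
    verts = None
    for it in range(1, max_iter + 1):
        iterations = it
        grid = np.linspace(lam.min(), lam.max(), min(n, n_grid))
        cols = [
            lowess(pts[:, j], lam, frac=lowess_frac, xvals=grid)
            for j in range(pts.shape[1])
        ]
        verts = np.column_stack(cols)
        keep = np.concatenate(
            [[True], np.any(np.diff(verts, axis=0) != 0, axis=1)]
        )
        verts = verts[keep]
        if verts.shape[0] < 2:
            break
        lam, foot = _project_to_polyline(pts, verts)
        if prev_foot is not None:
            delta = float(((foot - prev_foot) ** 2).mean()) / scale
            if delta < tol:
                converged = True
                prev_foot = foot
                break
        prev_foot = foot

    # orient along the first input coordinate and normalise to [0, 1]
    if np.std(lam) > 0 and np.std(pts[:, 0]) > 0:
        if np.corrcoef(lam, pts[:, 0])[0, 1] < 0:
            lam = lam.max() - lam
    rng_span = lam.max() - lam.min()
    pseudotime = (lam - lam.min()) / (rng_span if rng_span > 0 else 1.0)
    return TrajectoryResult(
        pseudotime=pseudotime,
        curve_points=verts if verts is not None else pts[np.argsort(lam)],
        converged=converged,
        iterations=iterations,
    )
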