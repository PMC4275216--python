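"""Nonmetric multidimensional scaling (Kruskal stress-1), from scratch.

NMDS places samples in a low-dimensional space so that the *ranks* of
the configuration's Euclidean distances reproduce the ranks of the input
dissimilarities.  Goodness of fit is Kruskal's stress-1,

    stress1 = sqrt( sum_(i<j) (dhat_ij - d_ij)^2 / sum_(i<j) d_ij^2 ),

where d are configuration distances and dhat is the best non-decreasing
(least-squares isotonic) fit of d against the dissimilarity order,
computed by pool-adjacent-violators (PAVA).  Because only ranks enter,
stress is invariant under rotation, reflection, translation and uniform
scaling of the configuration, and under any strictly increasing
transform of the dissimilarities.

The optimizer alternates SMACOF-style Guttman majorization steps with
isotonic regression, over multiple restarts: restart 0 starts from
classical (Torgerson) metric scaling, the rest from seeded random
configurations.  A step that would increase stress-1 is rejected and the
restart terminates there, so the recorded per-iteration stress sequence
is non-increasing by construction.  Ties in the dissimilarities are
handled by Kruskal's primary approach (within a tie block the fit may
order distances freely).

The returned configuration is canonicalized — centered, rotated onto its
principal axes, and sign-fixed so the first sample has non-negative
coordinates — which makes runs directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.spatial
from scipy.spatial.distance import pdist, squareform

from .community import SimilarityMatrix

__all__ = [
    "NMDSConfig",
    "NMDSResult",
    "isotonic_fit",
    "stress1",
    "nmds",
    "procrustes_distance",
]


def isotonic_fit(x, y) -> np.ndarray:
    """Least-squares non-decreasing fit of y over positions ordered by x.

    ``x`` must already be sorted ascending; the returned vector minimizes
    sum (fit - y)^2 among all non-decreasing vectors (PAVA: adjacent
    violating blocks are pooled to their mean until monotone).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and the same length")
    if np.any(np.diff(x) < 0):
        raise ValueError("x must be sorted ascending")
    # blocks of (mean, weight), merged while the tail violates monotonicity
    means: list[float] = []
    weights: list[float] = []
    sizes: list[int] = []
    for value in y:
        means.append(float(value))
        weights.append(1.0)
        sizes.append(1)
        while len(means) > 1 and means[-2] > means[-1]:
            m2, w2, s2 = means.pop(), weights.pop(), sizes.pop()
            means[-1] = (means[-1] * weights[-1] + m2 * w2) / (weights[-1] + w2)
            weights[-1] += w2
            sizes[-1] += s2
    return np.repeat(means, sizes)


def _as_dissimilarity_array(dissim) -> tuple[np.ndarray, list[str]]:
    if isinstance(dissim, SimilarityMatrix):
        dissim = dissim.as_dissimilarity().values
    if isinstance(dissim, pd.DataFrame):
        labels = [str(i) for i in dissim.index]
        arr = dissim.values.astype(float)
    else:
        arr = np.asarray(dissim, dtype=float)
        labels = [str(i) for i in range(arr.shape[0])]
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    if not np.allclose(arr, arr.T, atol=1e-10):
        raise ValueError("dissimilarity matrix must be symmetric")
    if np.any(np.abs(np.diag(arr)) > 1e-10):
        raise ValueError("dissimilarity matrix must have a zero diagonal")
    return arr, labels


def _fit_disparities(delta: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Isotonic disparities for condensed distances d against condensed
    dissimilarities delta, with Kruskal's primary tie treatment (within a
    tie block, distances are pre-sorted ascending so the fit is free)."""
    order = np.lexsort((d, delta))
    dhat = np.empty_like(d)
    dhat[order] = isotonic_fit(delta[order], d[order])
    return dhat


def stress1(coords, dissim) -> float:
    """Kruskal stress-1 of a configuration against a dissimilarity matrix."""
    delta, _ = _as_dissimilarity_array(dissim)
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] != delta.shape[0]:
        raise ValueError("coordinate rows must match dissimilarity size")
    d = pdist(coords)
    denom = float((d**2).sum())
    if denom == 0.0:
        raise ValueError("degenerate configuration: all coordinates coincide")
    dhat = _fit_disparities(squareform(delta, checks=False), d)
    return float(np.sqrt(((dhat - d) ** 2).sum() / denom))


def _classical_scaling(delta: np.ndarray, n_dims: int) -> np.ndarray:
    """Torgerson metric scaling: principal coordinates of -J D^2 J / 2."""
    n = delta.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (delta**2) @ j
    eigval, eigvec = np.linalg.eigh(b)
    idx = np.argsort(eigval)[::-1][:n_dims]
    vals = np.clip(eigval[idx], 0.0, None)
    return eigvec[:, idx] * np.sqrt(vals)


def _guttman_step(coords: np.ndarray, dhat: np.ndarray) -> np.ndarray:
    n = coords.shape[0]
    d = squareform(pdist(coords), checks=False)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(d > 0, squareform(dhat, checks=False) / np.where(d > 0, d, 1.0), 0.0)
    b = -ratio
    np.fill_diagonal(b, ratio.sum(axis=1))
    return b @ coords / n


def _canonicalize(coords: np.ndarray) -> np.ndarray:
    coords = coords - coords.mean(axis=0)
    # rotate onto principal axes
    _, _, vt = np.linalg.svd(coords, full_matrices=False)
    coords = coords @ vt.T
    for k in range(coords.shape[1]):
        col = coords[:, k]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            coords[:, k] = -col
    return coords


@dataclass(frozen=True)
class NMDSConfig:
    """Solver settings; defaults suit community matrices of tens of samples."""

    n_dims: int = 2
    n_restarts: int = 20
    max_iter: int = 500
    tol: float = 1e-7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_dims < 1 or self.n_restarts < 1 or self.max_iter < 1:
            raise ValueError("n_dims, n_restarts and max_iter must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


@dataclass(frozen=True)
class NMDSResult:
    coordinates: pd.DataFrame
    stress: float
    converged: bool
    restart_stresses: np.ndarray
    stress_history: np.ndarray = field(repr=False, default=None)  # best restart


def _run_single(
    delta: np.ndarray, init: np.ndarray, max_iter: int, tol: float
) -> tuple[np.ndarray, float, bool, list[float]]:
    coords = init.copy()
    delta_c = squareform(delta, checks=False)
    stress = stress1(coords, delta)
    history = [stress]
    converged = False
    for _ in range(max_iter):
        d = pdist(coords)
        dhat = _fit_disparities(delta_c, d)
        # rescale disparities to the distance scale for a stable Guttman step
        ssd = float((d**2).sum())
        ssdh = float((dhat**2).sum())
        if ssdh == 0.0:
            break
        new_coords = _guttman_step(coords, dhat * np.sqrt(ssd / ssdh))
        if float(pdist(new_coords).max(initial=0.0)) == 0.0:
            break  # configuration collapsed; keep previous iterate
        new_stress = stress1(new_coords, delta)
        if new_stress > stress:
            converged = True  # majorization stalled; reject the move
            break
        coords = new_coords
        improvement = stress - new_stress
        stress = new_stress
        history.append(stress)
        if improvement <= tol * max(stress, 1e-12):
            converged = True
            break
    return coords, stress, converged, history


def nmds(dissim, config: NMDSConfig | None = None, **kwargs) -> NMDSResult:
    """Best-of-restarts 2-D (by default) NMDS of a dissimilarity matrix.

    ``dissim`` may be a :class:`~trflp.community.SimilarityMatrix` (it is
    flipped to dissimilarity automatically), a DataFrame, or an array.
    Keyword arguments are forwarded to :class:`NMDSConfig`.
    """
    if config is None:
        config = NMDSConfig(**kwargs)
    elif kwargs:
        raise TypeError("pass either a config object or keyword settings, not both")
    delta, labels = _as_dissimilarity_array(dissim)
    n = delta.shape[0]
    if n < 3:
        raise ValueError("NMDS needs at least 3 samples")

    rng = np.random.default_rng(config.seed)
    best: Optional[tuple[np.ndarray, float, bool, list[float]]] = None
    restart_stresses = []
    for r in range(config.n_restarts):
        if r == 0:
            init = _classical_scaling(delta, config.n_dims)
            if float(np.abs(init).max(initial=0.0)) == 0.0:
                init = rng.uniform(-1, 1, size=(n, config.n_dims))
        else:
            init = rng.uniform(-1, 1, size=(n, config.n_dims))
        try:
            run = _run_single(delta, init, config.max_iter, config.tol)
        except ValueError:
            continue  # degenerate start (coincident points); try next restart
        restart_stresses.append(run[1])
        if best is None or run[1] < best[1]:
            best = run
    if best is None:
        raise ValueError("all restarts degenerate; cannot ordinate this matrix")

    coords = _canonicalize(best[0])
    final_stress = stress1(coords, delta)
    frame = pd.DataFrame(
        coords,
        index=pd.Index(labels, name="sample_id"),
        columns=[f"NMDS{k + 1}" for k in range(config.n_dims)],
    )
    return NMDSResult(
        coordinates=frame,
        stress=final_stress,
        converged=best[2],
        restart_stresses=np.asarray(restart_stresses),
        stress_history=np.asarray(best[3]),
    )


def procrustes_distance(a, b) -> float:
    """Residual sum of squares after optimal translation/rotation/reflection/
    scaling of one configuration onto the other (0 iff similar shapes)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    _, _, disparity = scipy.spatial.procrustes(a, b)
    return float(disparity)


def plot_nmds(result: NMDSResult, groups=None, path=None):
    """Optional static scatter of a 2-D ordination (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    coords = result.coordinates
    fig, ax = plt.subplots(figsize=(5, 5))
    if groups is None:
        ax.scatter(coords.iloc[:, 0], coords.iloc[:, 1])
    else:
        for g in sorted(set(groups.values())):
            ids = [s for s in coords.index if groups[s] == g]
            sub = coords.loc[ids]
            ax.scatter(sub.iloc[:, 0], sub.iloc[:, 1], label=str(g))
        ax.legend(fontsize=8)
    for sid in coords.index:
        ax.annotate(sid, coords.loc[sid].iloc[:2], fontsize=7)
    ax.set_xlabel(coords.columns[0])
    ax.set_ylabel(coords.columns[1])
    ax.set_title(f"NMDS (stress-1 = {result.stress:.3f})")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
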