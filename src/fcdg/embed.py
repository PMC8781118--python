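"""Metrization of distance bounds and metric-matrix embedding in 4D.

Metrization turns the smoothed bounds matrix into one concrete random distance
matrix: pairs are visited in random order, each distance is drawn uniformly
within its current bounds, fixed, and the remaining bounds are re-tightened so
subsequent draws stay mutually consistent (partial metrization).  The distance
matrix is then embedded by classical metric-matrix (Gram) decomposition, keeping
the four largest eigen-components — the extra dimension gives the subsequent
annealing a barrier-free path for configurational inversions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .moltop import BoundsMatrix, InconsistentBoundsError, smooth_bounds

__all__ = ["EmbeddedStructure", "MetrizationError", "metrize", "embed_4d"]


class MetrizationError(RuntimeError):
    """Bounds became inconsistent during metrization beyond the retry budget."""


@dataclass
class EmbeddedStructure:
    coords: np.ndarray           # (n_atoms, 4) Å
    seed: int | None = None
    pair_order: np.ndarray | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("embedded coordinates must be finite")


def _fix_pair(L: np.ndarray, U: np.ndarray, i: int, j: int, d: float) -> None:
    """Fix d(i,j)=d and propagate the exact-edge triangle relaxations in place.

    Uppers: shortest-path relaxation through the new edge.  Lowers: the
    inverse-triangle consequences of the new exact distance.
    """
    L[i, j] = L[j, i] = d
    U[i, j] = U[j, i] = d
    # upper relaxation through i-j (both orientations)
    for a, b in ((i, j), (j, i)):
        via = U[:, a, None] + d + U[None, b, :]
        np.minimum(U, via, out=U)
    np.fill_diagonal(U, 0.0)
    # lower relaxation: d(x,y) >= d - U(x,a) - U(y,b)
    for a, b in ((i, j), (j, i)):
        via = d - U[:, a, None] - U[None, b, :]
        np.maximum(L, via, out=L)
        # and d(x,a) >= L(x,b) - d ... handled by the generic pass below
    for a, b in ((i, j), (j, i)):
        via = L[:, a, None] - d - U[None, b, :]
        np.maximum(L, via, out=L)
    np.fill_diagonal(L, 0.0)


def metrize(
    bounds: BoundsMatrix,
    rng: np.random.Generator,
    max_retries: int = 5,
) -> np.ndarray:
    """Draw a random distance matrix consistent with the (smoothed) bounds.

    Deterministic given the generator state.  On mid-metrization inconsistency
    the draw restarts with a fresh random pair order, up to ``max_retries``.
    """
    n = bounds.n_atoms
    iu = np.triu_indices(n, 1)
    pairs = np.column_stack(iu)
    base = smooth_bounds(bounds)
    severe = 0.5  # Å: interval inversion beyond this aborts the attempt
    for attempt in range(max_retries):
        L, U = base.lower.copy(), base.upper.copy()
        order = rng.permutation(len(pairs))
        ok = True
        for idx in order:
            i, j = map(int, pairs[idx])
            lo, up = L[i, j], U[i, j]
            if lo > up + severe:
                ok = False
                break
            if lo > up:
                # small inversion from partial (exact-edge) smoothing: take the
                # midpoint, clamped back into the original bounds
                d = float(np.clip(0.5 * (lo + up), base.lower[i, j], base.upper[i, j]))
            else:
                d = rng.uniform(lo, up) if up > lo else lo
            _fix_pair(L, U, i, j, d)
        if ok:
            D = 0.5 * (U + U.T)
            D = np.clip(D, base.lower, base.upper)
            np.fill_diagonal(D, 0.0)
            return D
    raise MetrizationError(
        f"metrization failed after {max_retries} attempts (inconsistent bounds)"
    )


def embed_4d(distances: np.ndarray) -> EmbeddedStructure:
    """Embed a distance matrix into 4D by classical metric-matrix decomposition.

    The Gram matrix is built from centroid-referenced squared distances; the
    four largest eigen-components (negative eigenvalues clamped to zero, since
    bound-derived matrices are generally not exactly embeddable) give the
    coordinates.  Exactly embeddable <=4-dimensional inputs are reproduced to
    numerical precision; the centroid sits at the origin.
    """
    D = np.asarray(distances, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    n = D.shape[0]
    D2 = D ** 2
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ D2 @ J
    evals, evecs = np.linalg.eigh(B)
    idx = np.argsort(evals)[::-1][:4]
    lam = np.clip(evals[idx], 0.0, None)
    X = evecs[:, idx] * np.sqrt(lam)[None, :]
    X -= X.mean(axis=0, keepdims=True)
    return EmbeddedStructure(coords=X)
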