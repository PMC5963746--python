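"""Generalized Procrustes analysis and shape distances.

Full Procrustes superimposition: each configuration is centred, scaled to
unit centroid size, and rotated (rotation only, det = +1; reflections would
collapse genuine left-right anatomy) onto an iteratively updated consensus.
Shape distances are full-Procrustes chord distances between the aligned
coordinates, a close approximation of the Riemannian distance at the small
shape variation typical of within-species facial data.  No tangent-space
projection is applied by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .io import LandmarkDataset

GPA_TOL = 1e-10
GPA_MAX_ITER = 100


class GpaConvergenceError(RuntimeError):
    def __init__(self, iterations: int, trace: list[float]):
        super().__init__(
            f"GPA did not converge in {iterations} iterations; "
            f"objective trace: {trace}"
        )
        self.iterations = iterations
        self.trace = trace


def centroid_size(coords: np.ndarray) -> float:
    """Centroid size: sqrt of summed squared distances from the centroid (mm)."""
    coords = np.asarray(coords, dtype=float)
    cs = float(np.sqrt(((coords - coords.mean(axis=0)) ** 2).sum()))
    if cs <= 1e-12:
        raise ValueError("degenerate configuration: all landmarks coincide")
    return cs


def _optimal_rotation(x: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotation R (det=+1) minimizing ||x @ R - target||_F for centred x."""
    u, _, vt = np.linalg.svd(x.T @ target)
    d = np.sign(np.linalg.det(u @ vt))
    return u @ np.diag([1.0, 1.0, d]) @ vt


@dataclass
class ProcrustesFit:
    """Aligned shape coordinates plus the sizes removed by the superimposition."""

    aligned: np.ndarray  # (n, p, 3), unit centroid size, centred
    centroid_sizes: np.ndarray  # (n,) mm
    mean_shape: np.ndarray  # (p, 3), unit centroid size
    iterations: int
    final_change: float
    objective_trace: tuple[float, ...]
    labels: tuple[str, ...]
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        cent = self.aligned.mean(axis=1)
        if not np.allclose(cent, 0.0, atol=1e-8):
            raise ValueError("aligned configurations are not centred")
        cs = np.sqrt((self.aligned**2).sum(axis=(1, 2)))
        if not np.allclose(cs, 1.0, atol=1e-8):
            raise ValueError("aligned configurations do not have unit centroid size")

    @property
    def n(self) -> int:
        return self.aligned.shape[0]

    @property
    def p(self) -> int:
        return self.aligned.shape[1]

    @property
    def shape_dim(self) -> int:
        """Dimension of the shape space for p 3D landmarks: 3p - 7."""
        return 3 * self.p - 7

    def flattened(self) -> np.ndarray:
        return self.aligned.reshape(self.n, -1)


@dataclass
class ShapeDistanceMatrix:
    labels: tuple[str, ...]
    values: np.ndarray  # (n, n) symmetric, zero diagonal

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape[0] != v.shape[1] or v.shape[0] != len(self.labels):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal is not zero")
        if (v < -1e-12).any():
            raise ValueError("distance matrix has negative entries")
        object.__setattr__(self, "values", v)


def gpa_align(
    data: LandmarkDataset | np.ndarray,
    tol: float = GPA_TOL,
    max_iter: int = GPA_MAX_ITER,
    labels: tuple[str, ...] | None = None,
) -> ProcrustesFit:
    """Iterative full-Procrustes superimposition of all configurations.

    Each round rotates every (centred, unit-size) configuration onto the
    current consensus, re-estimates the consensus as the coordinate-wise mean
    re-normalized to unit centroid size, and stops once the consensus moves
    less than ``tol`` in chord distance.  The first record's orientation seeds
    the initial consensus, making the output deterministic.
    """
    if isinstance(data, LandmarkDataset):
        coords = data.coords_array()
        meta = data.meta()
        labels = data.labels
    else:
        coords = np.asarray(data, dtype=float)
        meta = pd.DataFrame(index=range(coords.shape[0]))
        if labels is None:
            labels = tuple(str(i) for i in range(coords.shape[0]))
    n = coords.shape[0]
    if n < 2:
        raise ValueError("GPA needs at least two configurations")

    centred = coords - coords.mean(axis=1, keepdims=True)
    sizes = np.sqrt((centred**2).sum(axis=(1, 2)))
    if (sizes <= 1e-12).any():
        raise ValueError("degenerate configuration: zero centroid size")
    x = centred / sizes[:, None, None]

    mean = x[0].copy()
    trace: list[float] = []
    change = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        for i in range(n):
            x[i] = x[i] @ _optimal_rotation(x[i], mean)
        new_mean = x.mean(axis=0)
        new_mean /= np.sqrt((new_mean**2).sum())
        trace.append(float(((x - new_mean) ** 2).sum()))
        change = float(np.sqrt(((new_mean - mean) ** 2).sum()))
        mean = new_mean
        if change < tol:
            break
    else:
        raise GpaConvergenceError(max_iter, trace)

    return ProcrustesFit(
        aligned=x,
        centroid_sizes=sizes,
        # the reported consensus is the coordinate-wise mean of the aligned
        # records (the unit-size consensus only steers the iteration)
        mean_shape=x.mean(axis=0),
        iterations=it,
        final_change=change,
        objective_trace=tuple(trace),
        labels=tuple(labels),
        meta=meta,
    )


def shape_distance_matrix(fit: ProcrustesFit) -> ShapeDistanceMatrix:
    """Pairwise Procrustes (chord) distances between aligned records."""
    flat = fit.flattened()
    return ShapeDistanceMatrix(
        labels=fit.labels, values=squareform(pdist(flat, metric="euclidean"))
    )


def distance_to_mean(fit: ProcrustesFit) -> pd.Series:
    """Per-record Procrustes distance to the consensus shape."""
    d = np.sqrt(((fit.aligned - fit.mean_shape) ** 2).sum(axis=(1, 2)))
    return pd.Series(d, index=list(fit.labels), name="distance_to_mean")


def two_configuration_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Closed-form full-Procrustes distance between two configurations.

    Centre and scale both to unit centroid size, rotate b onto a by the
    single SVD solution, and return the chord distance.  Used as the
    independent oracle for the iterative alignment on pairs.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    a = a / np.sqrt((a**2).sum())
    b = b / np.sqrt((b**2).sum())
    r = _optimal_rotation(b, a)
    return float(np.sqrt(((b @ r - a) ** 2).sum()))


def interlandmark_distance(
    dataset: LandmarkDataset, landmark_a: str, landmark_b: str
) -> pd.Series:
    """Euclidean distance (mm) between two named landmarks on raw coordinates."""
    names = dataset.panel.names
    try:
        ia, ib = names.index(landmark_a), names.index(landmark_b)
    except ValueError as exc:
        raise ValueError(
            f"unknown landmark ({landmark_a!r} or {landmark_b!r}); "
            f"panel has {list(names)}"
        ) from exc
    coords = dataset.coords_array()
    d = np.sqrt(((coords[:, ia] - coords[:, ib]) ** 2).sum(axis=1))
    return pd.Series(d, index=list(dataset.labels), name=f"{landmark_a}–{landmark_b}")
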