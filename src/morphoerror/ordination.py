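"""PCA of Procrustes shape coordinates for exploratory group structure.

Covariance (never correlation) PCA of the flattened aligned coordinates —
the universal convention for Procrustes data, where all variables share the
same scale.  At most min(n - 1, 3p - 7) components are retained: the shape
space for p 3D landmarks has 3p - 7 dimensions, so later eigenvalues are
numerically negligible.  Eigenvector signs are fixed by making each
component's largest-magnitude loading positive, so score plots reproduce.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .procrustes import ProcrustesFit


@dataclass
class PcaResult:
    scores: np.ndarray  # (n, m)
    eigenvalues: np.ndarray  # (m,), non-increasing
    percent_variance: np.ndarray  # (m,), sums to 100
    loadings: np.ndarray  # (3p, m)
    total_variance: float  # trace of the full covariance
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        ev = self.eigenvalues
        if (np.diff(ev) > 1e-12).any() or (ev < -1e-12).any():
            raise ValueError("eigenvalues must be non-increasing and >= 0")
        if not np.isclose(self.percent_variance.sum(), 100.0, atol=1e-6):
            raise ValueError("percent_variance must sum to 100")

    @property
    def m(self) -> int:
        return len(self.eigenvalues)


def shape_pca(fit: ProcrustesFit) -> PcaResult:
    """Eigendecomposition of the covariance of the aligned coordinates."""
    n = fit.n
    if n < 3:
        raise ValueError("PCA needs >= 3 records")
    x = fit.flattened()
    xc = x - x.mean(axis=0)
    # SVD route: eigenvalues of cov = s^2 / (n - 1); numerically stable
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    eig = s**2 / (n - 1)
    total = float(eig.sum())
    m = min(n - 1, fit.shape_dim)
    eig = eig[:m]
    loadings = vt[:m].T  # (3p, m)
    scores = xc @ loadings
    # deterministic sign: largest-|loading| entry positive per component
    for j in range(m):
        k = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[k, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    percent = 100.0 * eig / eig.sum()
    return PcaResult(
        scores=scores,
        eigenvalues=eig,
        percent_variance=percent,
        loadings=loadings,
        total_variance=total,
        labels=fit.labels,
    )


def group_scatter_export(
    pca: PcaResult,
    labels_a,
    labels_b,
    axes: tuple[int, int] = (1, 2),
    names: tuple[str, str] = ("sex", "operator"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-record scores on two PCs with two label columns, plus group centroids.

    ``axes`` are 1-based component numbers.  Returns (records, centroids);
    centroids are computed per level of each label column separately.
    """
    la = np.asarray(labels_a)
    lb = np.asarray(labels_b)
    n = pca.scores.shape[0]
    if len(la) != n or len(lb) != n:
        raise ValueError(f"labels must cover all {n} records")
    i, j = axes[0] - 1, axes[1] - 1
    if not (0 <= i < pca.m and 0 <= j < pca.m):
        raise ValueError(f"axes {axes} out of range for {pca.m} components")
    cols = [f"PC{axes[0]}", f"PC{axes[1]}"]
    records = pd.DataFrame(
        {
            "record": list(pca.labels),
            cols[0]: pca.scores[:, i],
            cols[1]: pca.scores[:, j],
            names[0]: la,
            names[1]: lb,
        }
    )
    cent_rows = []
    for col in names:
        for level, grp in records.groupby(col, sort=True):
            cent_rows.append(
                {
                    "factor": col,
                    "level": level,
                    cols[0]: grp[cols[0]].mean(),
                    cols[1]: grp[cols[1]].mean(),
                }
            )
    return records, pd.DataFrame(cent_rows)
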