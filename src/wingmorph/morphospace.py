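"""PCA shape space over normalized EFA coefficients and the theoretical grid.

The empirical morphospace is a centred (covariance-based, unscaled) PCA
of the per-shape coefficient vectors.  A theoretical grid is laid over
the first two axes: the empirical (PC1, PC2) bounding box is extended by
a border fraction of each axis's range on each side, divided into
n_cols x n_rows equidistant cell-center coordinates (26 x 19 = 494 by
default), and each grid point is back-projected to coefficient space
(all other component scores zero) and reconstructed by inverse EFA.
Reconstructions that self-intersect are geometrically non-viable and are
flagged for exclusion from all functional analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull
from sklearn.decomposition import PCA

from wingmorph.efa import efa_inverse, vector_to_coeffs
from wingmorph.outlines import is_self_intersecting

__all__ = [
    "ShapeSpace",
    "TheoreticalGrid",
    "fit_shape_space",
    "project",
    "backproject",
    "build_theoretical_grid",
    "occupation_fraction",
    "hull_area_fraction",
]


@dataclass(frozen=True)
class ShapeSpace:
    """PCA basis over coefficient vectors: shapes <-> component scores."""

    mean_vector: np.ndarray  # (n_coeffs,)
    components: np.ndarray  # (n_components, n_coeffs), orthonormal rows
    explained_variance: np.ndarray  # fraction per component, non-increasing
    scores: np.ndarray  # (n_shapes, n_components)

    @property
    def n_components(self) -> int:
        return self.components.shape[0]


@dataclass(frozen=True)
class TheoreticalGrid:
    """Lattice of back-projected theoretical shapes over (PC1, PC2)."""

    n_cols: int
    n_rows: int
    pc1_values: np.ndarray  # (n_cols,) ascending
    pc2_values: np.ndarray  # (n_rows,) ascending
    cell_scores: np.ndarray  # (n_cells, 2), row-major over (row, col)
    outlines: list  # reconstructed (P, 2) outline per cell
    viable: np.ndarray  # (n_cells,) bool

    @property
    def n_cells(self) -> int:
        return self.n_cols * self.n_rows

    def cell_id(self, row: int, col: int) -> int:
        return row * self.n_cols + col


def fit_shape_space(coeff_matrix: np.ndarray) -> ShapeSpace:
    """Centred PCA of a (shapes x coefficients) matrix.

    No per-column rescaling is applied (covariance PCA): coefficient
    units are commensurable and rescaling would distort shape metrics.
    Constant (pinned) columns are tolerated as zero-variance directions.
    """
    X = np.asarray(coeff_matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("need a 2-D matrix with >= 3 shapes")
    pca = PCA(n_components=min(X.shape[0] - 1, X.shape[1]), svd_solver="full")
    scores = pca.fit_transform(X)
    return ShapeSpace(
        mean_vector=pca.mean_,
        components=pca.components_,
        explained_variance=pca.explained_variance_ratio_,
        scores=scores,
    )


def project(coeff_vectors: np.ndarray, space: ShapeSpace) -> np.ndarray:
    """Map coefficient vectors to component scores."""
    X = np.atleast_2d(np.asarray(coeff_vectors, dtype=float))
    if X.shape[1] != space.mean_vector.shape[0]:
        raise ValueError(
            f"coefficient dimension {X.shape[1]} != space "
            f"dimension {space.mean_vector.shape[0]}"
        )
    out = (X - space.mean_vector) @ space.components.T
    return out[0] if np.asarray(coeff_vectors).ndim == 1 else out


def backproject(
    scores: np.ndarray, space: ShapeSpace, reimpose_pinned: bool = True
) -> np.ndarray:
    """Map component scores back to coefficient vectors.

    Scores with fewer entries than there are components leave the
    remaining scores at 0.  Pinned EFA values (a1=1, b1=0, c1=0) are
    re-imposed by default so back-projections are valid normalized
    coefficient vectors.
    """
    s = np.atleast_2d(np.asarray(scores, dtype=float))
    if s.shape[1] > space.n_components:
        raise ValueError(
            f"got {s.shape[1]} scores but space has {space.n_components} components"
        )
    full = np.zeros((s.shape[0], space.n_components))
    full[:, : s.shape[1]] = s
    X = space.mean_vector + full @ space.components
    if reimpose_pinned:
        X[:, 0], X[:, 1], X[:, 2] = 1.0, 0.0, 0.0
    return X[0] if np.asarray(scores).ndim == 1 else X


def build_theoretical_grid(
    space: ShapeSpace,
    n_cols: int = 26,
    n_rows: int = 19,
    border_frac: float = 0.2,
    P: int = 150,
) -> TheoreticalGrid:
    """Back-project an equidistant (PC1, PC2) lattice to theoretical shapes.

    Each axis spans the empirical score range extended by ``border_frac``
    of that range on each side, inclusive of endpoints.  Every cell is
    reconstructed at P outline points and screened for self-intersection.
    """
    if border_frac < 0:
        raise ValueError("border_frac must be >= 0")
    emp = space.scores[:, :2]
    ranges = emp.max(axis=0) - emp.min(axis=0)
    if np.any(ranges <= 0):
        raise ValueError("degenerate (zero-range) empirical axis")
    lo = emp.min(axis=0) - border_frac * ranges
    hi = emp.max(axis=0) + border_frac * ranges
    pc1_values = np.linspace(lo[0], hi[0], n_cols)
    pc2_values = np.linspace(lo[1], hi[1], n_rows)

    cells = np.array(
        [(p1, p2) for p2 in pc2_values for p1 in pc1_values]
    )  # row-major: row (PC2) outer, col (PC1) inner
    coeff_vectors = backproject(cells, space)
    outlines = []
    viable = np.empty(len(cells), dtype=bool)
    for i, vec in enumerate(coeff_vectors):
        out = efa_inverse(vector_to_coeffs(vec, normalized=True), P=P)
        outlines.append(out)
        viable[i] = not is_self_intersecting(out)
    return TheoreticalGrid(
        n_cols=n_cols,
        n_rows=n_rows,
        pc1_values=pc1_values,
        pc2_values=pc2_values,
        cell_scores=cells,
        outlines=outlines,
        viable=viable,
    )


def occupation_fraction(grid: TheoreticalGrid, scores: np.ndarray) -> float:
    """Fraction of grid cells whose cell region contains >= 1 empirical score.

    Cell regions are the Voronoi rectangles of the lattice (half-spacing
    around each cell center).
    """
    s = np.atleast_2d(np.asarray(scores, dtype=float))[:, :2]
    d1 = np.diff(grid.pc1_values).mean() if grid.n_cols > 1 else np.inf
    d2 = np.diff(grid.pc2_values).mean() if grid.n_rows > 1 else np.inf
    cols = np.clip(np.round((s[:, 0] - grid.pc1_values[0]) / d1), 0, grid.n_cols - 1)
    rows = np.clip(np.round((s[:, 1] - grid.pc2_values[0]) / d2), 0, grid.n_rows - 1)
    occupied = set(zip(rows.astype(int), cols.astype(int)))
    return len(occupied) / grid.n_cells


def hull_area_fraction(grid: TheoreticalGrid, scores: np.ndarray) -> float:
    """Convex-hull area of the scores as a fraction of the grid's bounding box."""
    s = np.atleast_2d(np.asarray(scores, dtype=float))[:, :2]
    if len(s) < 3:
        return 0.0
    hull = ConvexHull(s)
    box = (grid.pc1_values[-1] - grid.pc1_values[0]) * (
        grid.pc2_values[-1] - grid.pc2_values[0]
    )
    return float(hull.volume / box)  # ConvexHull.volume is area in 2-D
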