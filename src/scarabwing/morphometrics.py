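"""Landmark-based geometric morphometrics.

Generalized Procrustes analysis (GPA) removes translation, scale and
rotation from 2D landmark configurations; principal components of the
aligned coordinates span the shape space; squared-loading decompositions
attribute each component's variance to individual landmarks; and
thin-plate-spline (TPS) warps visualize the smooth deformation carrying
one mean shape onto another.

The aligners and decompositions are scikit-learn style estimators
(``fit`` / ``transform``, fitted attributes with trailing underscores) so
they compose with sklearn pipelines; the module-level functions ``gpa``,
``shape_pca`` and ``tps_warp`` are thin wrappers returning plain dataclasses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "ShapeSet",
    "AlignedShapes",
    "ShapeSpace",
    "TPSWarp",
    "GeneralizedProcrustesAnalysis",
    "ShapePCA",
    "ThinPlateSpline",
    "gpa",
    "shape_pca",
    "landmark_contributions",
    "tps_warp",
    "deformation_grid",
    "centroid_size",
]


@dataclass
class ShapeSet:
    """Specimen landmark configurations with identity labels."""

    configurations: np.ndarray  # (n_specimens, k_landmarks, 2)
    specimen_ids: list[str]
    species_labels: list[str]

    def __post_init__(self) -> None:
        self.configurations = np.asarray(self.configurations, float)
        if self.configurations.ndim != 3 or self.configurations.shape[2] != 2:
            raise ValueError("configurations must have shape (n, k, 2)")
        if not np.all(np.isfinite(self.configurations)):
            raise ValueError("configurations contain missing coordinates")
        n = self.configurations.shape[0]
        if len(self.specimen_ids) != n or len(self.species_labels) != n:
            raise ValueError("label lists must match the number of specimens")

    @property
    def n_landmarks(self) -> int:
        return self.configurations.shape[1]


@dataclass
class AlignedShapes:
    aligned: np.ndarray  # (n, k, 2), centred, unit centroid size
    mean_shape: np.ndarray  # (k, 2)
    centroid_sizes: np.ndarray  # (n,) original sizes
    procrustes_distances: np.ndarray  # (n,) distance to mean
    specimen_ids: list[str] = field(default_factory=list)
    species_labels: list[str] = field(default_factory=list)


@dataclass
class ShapeSpace:
    eigenvalues: np.ndarray
    percent_variance: np.ndarray
    scores: np.ndarray  # (n, n_components)
    loadings: np.ndarray  # (n_components, 2k)
    mean: np.ndarray  # (2k,)


@dataclass
class TPSWarp:
    affine_part: np.ndarray  # (2, 3): [b | A] acting on column [1, x, y]
    kernel_weights: np.ndarray  # (k, 2)
    bending_energy: float
    warp: Callable[[np.ndarray], np.ndarray]


def centroid_size(config: np.ndarray) -> float:
    """Root summed squared distance of landmarks from their centroid."""
    c = np.asarray(config, float)
    return float(np.linalg.norm(c - c.mean(axis=0)))


def _optimal_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotation (no reflection) minimizing ||source @ R.T - target||."""
    u, _, vt = np.linalg.svd(target.T @ source)
    d = np.sign(np.linalg.det(u @ vt))
    corr = np.diag([1.0, d])
    return u @ corr @ vt


def _canonical_rotation(mean: np.ndarray) -> np.ndarray:
    """Rotation placing the mean shape's principal axes on the coordinate
    axes (deterministic orientation so GPA output does not depend on the
    arbitrary orientation of the input configurations)."""
    cov = mean.T @ mean
    vals, vecs = np.linalg.eigh(cov)
    vecs = vecs[:, ::-1]  # descending variance
    if np.linalg.det(vecs) < 0:
        vecs[:, 1] = -vecs[:, 1]
    R = vecs.T
    rotated = mean @ R.T
    j = int(np.argmax(np.abs(rotated[:, 0])))
    if rotated[j, 0] < 0:
        R = -R  # half-turn, det stays +1
    return R


class GeneralizedProcrustesAnalysis(TransformerMixin, BaseEstimator):
    """Iterative full GPA: centre, scale to unit centroid size, rotate
    (reflections disallowed) to the evolving mean until the mean shape
    changes by less than ``tol``.

    Fitted attributes: ``mean_shape_`` (k, 2), ``aligned_`` (n, k, 2),
    ``centroid_sizes_``, ``procrustes_distances_``, ``n_iter_``.
    ``transform`` aligns new configurations to the fitted mean.
    """

    def __init__(self, tol: float = 1e-10, max_iter: int = 200):
        self.tol = tol
        self.max_iter = max_iter

    def _normalize(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        centred = X - X.mean(axis=1, keepdims=True)
        sizes = np.linalg.norm(centred, axis=(1, 2))
        if np.any(sizes == 0):
            raise ValueError("degenerate configuration: all landmarks coincident")
        return centred / sizes[:, None, None], sizes

    def fit(self, X, y=None):
        X = np.asarray(X, float)
        if X.ndim != 3 or X.shape[0] < 2 or X.shape[1] < 3:
            raise ValueError("need >= 2 configurations of >= 3 landmarks, shape (n, k, 2)")
        shapes, sizes = self._normalize(X)
        mean = shapes[0].copy()
        for it in range(self.max_iter):
            for i in range(shapes.shape[0]):
                R = _optimal_rotation(shapes[i], mean)
                shapes[i] = shapes[i] @ R.T
            new_mean = shapes.mean(axis=0)
            new_mean /= np.linalg.norm(new_mean)
            if np.linalg.norm(new_mean - mean) < self.tol:
                mean = new_mean
                break
            mean = new_mean
        # deterministic orientation, independent of input orientation
        Rc = _canonical_rotation(mean)
        shapes = shapes @ Rc.T
        self.n_iter_ = it + 1
        self.aligned_ = shapes
        self.mean_shape_ = shapes.mean(axis=0)
        self.centroid_sizes_ = sizes
        self.procrustes_distances_ = np.linalg.norm(
            shapes - self.mean_shape_, axis=(1, 2)
        )
        return self

    def transform(self, X):
        check_is_fitted(self, "mean_shape_")
        X = np.asarray(X, float)
        single = X.ndim == 2
        if single:
            X = X[None]
        shapes, _ = self._normalize(X)
        for i in range(shapes.shape[0]):
            R = _optimal_rotation(shapes[i], self.mean_shape_)
            shapes[i] = shapes[i] @ R.T
        return shapes[0] if single else shapes


def gpa(shapes: "ShapeSet | np.ndarray") -> AlignedShapes:
    """Generalized Procrustes alignment of a shape set."""
    if isinstance(shapes, ShapeSet):
        X = shapes.configurations
        ids, species = shapes.specimen_ids, shapes.species_labels
    else:
        X = np.asarray(shapes, float)
        ids, species = [], []
    est = GeneralizedProcrustesAnalysis().fit(X)
    return AlignedShapes(
        aligned=est.aligned_,
        mean_shape=est.mean_shape_,
        centroid_sizes=est.centroid_sizes_,
        procrustes_distances=est.procrustes_distances_,
        specimen_ids=list(ids),
        species_labels=list(species),
    )


def _fix_signs(components: np.ndarray) -> np.ndarray:
    """Make the largest-magnitude element of each eigenvector positive."""
    out = components.copy()
    for i, v in enumerate(out):
        j = int(np.argmax(np.abs(v)))
        if v[j] < 0:
            out[i] = -v
    return out


class ShapePCA(TransformerMixin, BaseEstimator):
    """PCA of mean-centred aligned landmark coordinates (covariance mode).

    Specimens are rows, flattened (x1, y1, ..., xk, yk) coordinates are
    columns. Eigenvector signs are fixed by making each vector's
    largest-magnitude element positive, for cross-platform determinism.
    Fitted attributes: ``eigenvalues_``, ``percent_variance_``,
    ``components_`` (n_components, 2k), ``scores_``, ``mean_``.
    """

    def __init__(self, n_components: int | None = None):
        self.n_components = n_components

    def fit(self, X, y=None):
        X = np.asarray(X, float)
        if X.ndim == 3:
            X = X.reshape(X.shape[0], -1)
        n, p = X.shape
        if n < 3:
            raise ValueError("need at least three specimens for a shape PCA")
        self.mean_ = X.mean(axis=0)
        Xc = X - self.mean_
        _, s, vt = np.linalg.svd(Xc, full_matrices=False)
        eig = s**2 / (n - 1)
        r = min(n - 1, p) if self.n_components is None else self.n_components
        eig = eig[:r]
        components = _fix_signs(vt[:r])
        total = eig.sum()
        self.eigenvalues_ = eig
        self.percent_variance_ = (
            100 * eig / total if total > 0 else np.zeros_like(eig)
        )
        self.components_ = components
        self.scores_ = Xc @ components.T
        return self

    def transform(self, X):
        check_is_fitted(self, "components_")
        X = np.asarray(X, float)
        if X.ndim == 3:
            X = X.reshape(X.shape[0], -1)
        return (X - self.mean_) @ self.components_.T


def shape_pca(aligned: "AlignedShapes | np.ndarray") -> ShapeSpace:
    """Eigen-decomposition of the covariance of aligned coordinates."""
    X = aligned.aligned if isinstance(aligned, AlignedShapes) else np.asarray(aligned)
    est = ShapePCA().fit(X)
    return ShapeSpace(
        eigenvalues=est.eigenvalues_,
        percent_variance=est.percent_variance_,
        scores=est.scores_,
        loadings=est.components_,
        mean=est.mean_,
    )


def landmark_contributions(loading_vector: np.ndarray) -> np.ndarray:
    """Percent of a component's variance attributable to each landmark.

    The squared x and y loadings of each landmark are summed and
    normalized: ``100 * (vx_i^2 + vy_i^2) / sum_j (vx_j^2 + vy_j^2)``.
    """
    v = np.asarray(loading_vector, float).reshape(-1)
    if v.size % 2:
        raise ValueError("loading vector length must be even (x, y per landmark)")
    total = float(v @ v)
    if total == 0:
        raise ValueError("zero loading vector has no landmark decomposition")
    per = v.reshape(-1, 2)
    return 100.0 * np.sum(per**2, axis=1) / total


def _tps_kernel(r: np.ndarray) -> np.ndarray:
    """U(r) = r^2 log r with U(0) = 0."""
    out = np.zeros_like(r)
    nz = r > 0
    out[nz] = r[nz] ** 2 * np.log(r[nz])
    return out


class ThinPlateSpline(TransformerMixin, BaseEstimator):
    """2D thin-plate-spline interpolating map between landmark sets.

    ``fit(source, target)`` solves the standard TPS system with kernel
    U(r) = r^2 log r and side conditions annihilating affine terms, giving
    exact interpolation at the landmarks; ``transform(points)`` evaluates
    the warp. Fitted attributes: ``kernel_weights_`` (k, 2),
    ``affine_part_`` (2, 3) and ``bending_energy_`` = tr(W' K W) >= 0,
    zero exactly when the map is affine.
    """

    def fit(self, X, y):
        source = np.asarray(X, float)
        target = np.asarray(y, float)
        if source.shape != target.shape or source.ndim != 2 or source.shape[1] != 2:
            raise ValueError("source and target must both be (k, 2)")
        k = source.shape[0]
        d = np.linalg.norm(source[:, None, :] - source[None, :, :], axis=2)
        off_diag = d[~np.eye(k, dtype=bool)]
        if off_diag.size and off_diag.min() == 0:
            raise ValueError("singular kernel system: coincident source landmarks")
        K = _tps_kernel(d)
        P = np.column_stack([np.ones(k), source])
        L = np.zeros((k + 3, k + 3))
        L[:k, :k] = K
        L[:k, k:] = P
        L[k:, :k] = P.T
        rhs = np.zeros((k + 3, 2))
        rhs[:k] = target
        sol = np.linalg.solve(L, rhs)
        self.source_ = source
        self.kernel_weights_ = sol[:k]
        self.affine_coeffs_ = sol[k:]  # (3, 2) acting on [1, x, y]
        self.affine_part_ = sol[k:].T  # (2, 3)
        self.bending_energy_ = float(
            np.trace(self.kernel_weights_.T @ K @ self.kernel_weights_)
        )
        return self

    def transform(self, X):
        check_is_fitted(self, "kernel_weights_")
        pts = np.atleast_2d(np.asarray(X, float))
        d = np.linalg.norm(pts[:, None, :] - self.source_[None, :, :], axis=2)
        U = _tps_kernel(d)
        P = np.column_stack([np.ones(pts.shape[0]), pts])
        return U @ self.kernel_weights_ + P @ self.affine_coeffs_


def tps_warp(source: np.ndarray, target: np.ndarray) -> TPSWarp:
    """Thin-plate-spline warp carrying source landmarks onto target."""
    est = ThinPlateSpline().fit(source, target)
    return TPSWarp(
        affine_part=est.affine_part_,
        kernel_weights=est.kernel_weights_,
        bending_energy=max(est.bending_energy_, 0.0),
        warp=est.transform,
    )


def deformation_grid(
    warp: "TPSWarp | ThinPlateSpline",
    bounds: tuple[float, float, float, float],
    n_grid: int = 20,
    n_samples: int = 50,
) -> dict:
    """Regular grid mapped through a warp, serialized as polylines.

    Returns ``{"horizontal": [...], "vertical": [...]}`` where each entry is
    a list of [x, y] vertices of one warped grid line, ready for JSON
    serialization or plotting; contracted and expanded cells visualize local
    shape change.
    """
    fn = warp.warp if isinstance(warp, TPSWarp) else warp.transform
    xmin, xmax, ymin, ymax = bounds
    xs = np.linspace(xmin, xmax, n_grid)
    ys = np.linspace(ymin, ymax, n_grid)
    dense_x = np.linspace(xmin, xmax, n_samples)
    dense_y = np.linspace(ymin, ymax, n_samples)
    horizontal = [
        fn(np.column_stack([dense_x, np.full_like(dense_x, y)])).tolist() for y in ys
    ]
    vertical = [
        fn(np.column_stack([np.full_like(dense_y, x), dense_y])).tolist() for x in xs
    ]
    return {"horizontal": horizontal, "vertical": vertical}
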