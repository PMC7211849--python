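"""Phylogenetic comparative machinery for species mean shapes.

Under Brownian-motion (BM) trait evolution on a tree, the expected
covariance of two tips is the shared path length from the root to their
most recent common ancestor; stacking those for all tip pairs gives the
n x n matrix C. Phylogenetically corrected PCA replaces the arithmetic
mean and sample covariance with their generalized-least-squares
counterparts under C:

    a = (1' C^-1 1)^-1 1' C^-1 X          (GLS root state)
    R = (X - 1a)' C^-1 (X - 1a) / (n - 1) (evolutionary covariance)

and eigen-decomposes R; scores are the GLS-centred data projected onto the
eigenvectors (covariance mode, untransformed projection — the convention
of the standard phylogenetic-PCA implementations).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .morphometrics import AlignedShapes, _fix_signs

__all__ = [
    "load_tree",
    "bm_covariance",
    "PhylogeneticPCA",
    "PhyloShapeSpace",
    "phylo_pca",
    "species_mean_shapes",
]


@dataclass
class PhyloShapeSpace:
    C: np.ndarray
    phylo_mean_a: np.ndarray
    evolutionary_covariance_R: np.ndarray
    eigenvalues: np.ndarray
    percent_variance: np.ndarray
    scores: np.ndarray
    loadings: np.ndarray
    tip_labels: list[str]


def load_tree(source: "str | Path | dendropy.Tree") -> dendropy.Tree:
    """Read a newick tree (path or string). Branch lengths are required by
    the downstream BM machinery; the seed node is treated as the root."""
    if isinstance(source, dendropy.Tree):
        return source
    p = Path(str(source))
    try:
        is_file = p.exists()
    except OSError:  # e.g. a newick string too long to be a path
        is_file = False
    text = p.read_text() if is_file else str(source)
    tree = dendropy.Tree.get(data=text, schema="newick")
    return tree


def bm_covariance(
    tree: "dendropy.Tree | str | Path", taxon_order: list[str] | None = None
) -> tuple[np.ndarray, list[str]]:
    """Brownian-motion covariance matrix of the tips of a tree.

    ``C[i, j]`` is the path length from the root to the most recent common
    ancestor of tips i and j; ``C[i, i]`` is the root-to-tip depth. Returns
    ``(C, labels)`` with rows ordered by ``taxon_order`` if given, else by
    the tree's leaf order.
    """
    tree = load_tree(tree)
    leaves = [lf for lf in tree.leaf_node_iter()]
    labels = [lf.taxon.label if lf.taxon else None for lf in leaves]
    if any(l is None for l in labels):
        raise ValueError("all tips must be labelled")
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate tip labels")
    if taxon_order is not None:
        missing = sorted(set(taxon_order) - set(labels))
        extra = sorted(set(labels) - set(taxon_order))
        if missing or extra:
            raise ValueError(
                f"tip labels do not match data: missing from tree {missing}, "
                f"absent from data {extra}"
            )
        labels_out = list(taxon_order)
    else:
        labels_out = labels

    depth: dict[dendropy.Node, float] = {}
    tip_sets: dict[dendropy.Node, list[int]] = {}
    index = {lab: i for i, lab in enumerate(labels_out)}
    n = len(labels_out)
    C = np.zeros((n, n))
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depth[node] = 0.0
        else:
            if node.edge.length is None:
                raise ValueError("tree has a branch without a length")
            if node.edge.length < 0:
                raise ValueError("negative branch length")
            depth[node] = depth[node.parent_node] + float(node.edge.length)
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = index[node.taxon.label]
            tip_sets[node] = [i]
            C[i, i] = depth[node]
        else:
            children = [tip_sets[ch] for ch in node.child_nodes()]
            d = depth[node]
            for a in range(len(children)):
                for b in range(a + 1, len(children)):
                    for i in children[a]:
                        for j in children[b]:
                            C[i, j] = C[j, i] = d
            tip_sets[node] = [i for sub in children for i in sub]
    return C, labels_out


class PhylogeneticPCA(TransformerMixin, BaseEstimator):
    """PCA of the evolutionary covariance of tip traits under BM on a tree.

    ``fit(X)`` needs either ``tree`` (with ``taxon_order`` naming the rows
    of X) or a precomputed covariance ``C``. Fitted attributes:
    ``C_``, ``ancestral_mean_``, ``evolutionary_covariance_``,
    ``eigenvalues_``, ``percent_variance_``, ``components_``, ``scores_``.
    Reduces exactly to ordinary covariance PCA when C is proportional to
    the identity (a star phylogeny with equal branch lengths).
    """

    def __init__(self, tree=None, taxon_order: list[str] | None = None):
        self.tree = tree
        self.taxon_order = taxon_order

    def fit(self, X, y=None, C: np.ndarray | None = None):
        X = np.asarray(X, float)
        if X.ndim == 3:
            X = X.reshape(X.shape[0], -1)
        n, p = X.shape
        if n < 3:
            raise ValueError("need at least three species")
        if C is None:
            if self.tree is None:
                raise ValueError("provide a tree or a covariance matrix C")
            C, labels = bm_covariance(self.tree, self.taxon_order)
            self.tip_labels_ = labels
        else:
            C = np.asarray(C, float)
            self.tip_labels_ = list(self.taxon_order) if self.taxon_order else []
        if C.shape != (n, n):
            raise ValueError("C must be n x n matching the data rows")
        try:
            chol = np.linalg.cholesky(C)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "singular BM covariance (duplicate tips or zero-length branches?); "
                "repair the tree or add a small ridge to C"
            ) from exc
        ones = np.ones((n, 1))
        Ci1 = np.linalg.solve(C, ones) # C^-1 1 via Cholesky-backed solve
        a = (Ci1.T @ X) / float((ones.T @ Ci1)[0, 0])
        Xc = X - a
        R = Xc.T @ np.linalg.solve(C, Xc) / (n - 1)
        R = 0.5 * (R + R.T)
        vals, vecs = np.linalg.eigh(R)
        order = np.argsort(vals)[::-1]
        r = min(n - 1, p)
        vals = vals[order][:r]
        comps = _fix_signs(vecs[:, order].T[:r])
        total = vals.sum()
        self.C_ = C
        self.cholesky_ = chol
        self.ancestral_mean_ = a.ravel()
        self.evolutionary_covariance_ = R
        self.eigenvalues_ = vals
        self.percent_variance_ = 100 * vals / total if total > 0 else np.zeros_like(vals)
        self.components_ = comps
        self.scores_ = Xc @ comps.T
        return self

    def transform(self, X):
        check_is_fitted(self, "components_")
        X = np.asarray(X, float)
        if X.ndim == 3:
            X = X.reshape(X.shape[0], -1)
        return (X - self.ancestral_mean_) @ self.components_.T


def phylo_pca(
    species_means: np.ndarray,
    tree,
    taxon_order: list[str] | None = None,
) -> PhyloShapeSpace:
    """Phylogenetically corrected PCA of species mean shapes."""
    est = PhylogeneticPCA(tree=tree, taxon_order=taxon_order).fit(species_means)
    return PhyloShapeSpace(
        C=est.C_,
        phylo_mean_a=est.ancestral_mean_,
        evolutionary_covariance_R=est.evolutionary_covariance_,
        eigenvalues=est.eigenvalues_,
        percent_variance=est.percent_variance_,
        scores=est.scores_,
        loadings=est.components_,
        tip_labels=est.tip_labels_,
    )


def species_mean_shapes(
    aligned: "AlignedShapes | np.ndarray", species_labels: list[str] | None = None
) -> tuple[np.ndarray, list[str]]:
    """Per-species arithmetic mean of aligned coordinates.

    Returns a ``(n_species, 2k)`` matrix and the species labels in sorted
    order (deterministic under relabeling/reordering of specimens).
    """
    if isinstance(aligned, AlignedShapes):
        X = aligned.aligned
        if species_labels is None:
            species_labels = aligned.species_labels
    else:
        X = np.asarray(aligned, float)
    if species_labels is None or len(species_labels) != X.shape[0]:
        raise ValueError("species_labels must name every specimen")
    X = X.reshape(X.shape[0], -1)
    labels = sorted(set(species_labels))
    arr = np.asarray(species_labels)
    means = []
    for lab in labels:
        mask = arr == lab
        if not mask.any():
            raise ValueError(f"species {lab!r} has zero specimens")
        means.append(X[mask].mean(axis=0))
    return np.vstack(means), labels
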