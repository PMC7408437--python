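"""Bipartite spectral co-clustering.

Samples and genes are treated as the two node sets of a bipartite graph whose
edge weights are the (nonnegative) expression values. The normalized-cut
relaxation is solved on two independent paths:

* :func:`spectral_cocluster` — the efficient route: normalize
  ``Xn = R^{-1/2} X C^{-1/2}``, take the singular vectors after the trivial
  pair, embed rows and columns as ``Z = [R^{-1/2} U_p ; C^{-1/2} V_p]`` and
  run k-means on the rows of ``Z``.
* :func:`laplacian_cocluster_oracle` — the direct route: build the full
  ``(m+n) x (m+n)`` adjacency, solve the generalized eigenproblem
  ``L z = lambda D z`` of the graph Laplacian ``L = D - A``, and cluster the
  embedding. Restricted to small instances; used to cross-validate the SVD
  path.

With ``k`` biclusters, ``p = ceil(log2 k)`` singular-vector pairs are kept.
Internally samples are the rows of ``X``; callers holding the genes x samples
on-disk orientation should transpose first.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
from sklearn.cluster import KMeans

from .errors import ValidationError

__all__ = [
    "NormalizationFactors",
    "BiclusterModel",
    "normalize_bipartite",
    "spectral_cocluster",
    "laplacian_cocluster_oracle",
    "reorder_checkerboard",
]

_TRIVIAL_SV_TOL = 1e-8
_DEFAULT_N_INIT = 50
_ORACLE_SIZE_BOUND = 400


@dataclass
class NormalizationFactors:
    """Diagonals of the row-sum (R) and column-sum (C) normalizers."""

    row_sums: np.ndarray
    col_sums: np.ndarray


@dataclass
class BiclusterModel:
    """A fitted co-clustering of an m x n (samples x genes) matrix."""

    k: int
    p: int
    sample_labels: np.ndarray
    gene_labels: np.ndarray
    U: np.ndarray
    V: np.ndarray
    singular_values: np.ndarray
    Z: np.ndarray
    factors: NormalizationFactors | None
    inertia: float
    shift: float = 0.0
    seed: int | None = None
    sample_ids: np.ndarray | None = None
    gene_ids: np.ndarray | None = None
    method: str = "svd"
    meta: dict = field(default_factory=dict)

    @property
    def m(self) -> int:
        return self.sample_labels.size

    @property
    def n(self) -> int:
        return self.gene_labels.size


def _as_array(X) -> tuple[np.ndarray, np.ndarray | None, np.ndarray | None]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), X.index.to_numpy(), X.columns.to_numpy()
    return np.asarray(X, dtype=float), None, None


def normalize_bipartite(X) -> tuple[np.ndarray, NormalizationFactors]:
    """Degree-normalize: ``Xn_ij = X_ij / sqrt(rowsum_i * colsum_j)``.

    Requires a nonnegative matrix with no all-zero row or column; the largest
    singular value of the result is 1 (the trivial pair of the bipartite
    graph).
    """
    A, rows, cols = _as_array(X)
    if A.ndim != 2:
        raise ValidationError("expected a 2-D matrix")
    if (A < 0).any():
        i, j = np.argwhere(A < 0)[0]
        ri = rows[i] if rows is not None else i
        cj = cols[j] if cols is not None else j
        raise ValidationError(
            f"negative entry at ({ri}, {cj}); shift the matrix to be nonnegative first"
        )
    r = A.sum(axis=1)
    c = A.sum(axis=0)
    if (r == 0).any():
        i = int(np.argmax(r == 0))
        raise ValidationError(f"all-zero row: {rows[i] if rows is not None else i}")
    if (c == 0).any():
        j = int(np.argmax(c == 0))
        raise ValidationError(f"all-zero column: {cols[j] if cols is not None else j}")
    Xn = A / np.sqrt(np.outer(r, c))
    return Xn, NormalizationFactors(row_sums=r, col_sums=c)


def _kmeans(Z: np.ndarray, k: int, seed: int | None, n_init: int) -> tuple[np.ndarray, float]:
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=n_init,
        max_iter=300,
        tol=1e-6,
        random_state=seed,
    ).fit(Z)
    return km.labels_.astype(int), float(km.inertia_)


def n_informative_vectors(k: int) -> int:
    """Number of singular-vector pairs retained for k biclusters."""
    return math.ceil(math.log2(k))


def spectral_cocluster(
    X,
    k: int = 3,
    seed: int | None = None,
    n_init: int = _DEFAULT_N_INIT,
    shift: bool = True,
) -> BiclusterModel:
    """Co-cluster an m x n samples x genes matrix into k biclusters (SVD path).

    When ``shift`` is true the matrix minimum is subtracted first so that log2
    data become nonnegative; the applied shift is recorded on the model. The
    trivial first singular pair (singular value 1, constant embedding) is
    asserted and discarded; k-means with ``n_init`` seeded restarts clusters
    the stacked embedding, the first m rows labelling samples and the rest
    labelling genes.
    """
    A, sample_ids, gene_ids = _as_array(X)
    m, n = A.shape
    if k < 2:
        raise ValidationError(f"k must be >= 2, got {k}")
    if k > min(m, n):
        raise ValidationError(f"k={k} exceeds min(m, n)={min(m, n)}")

    applied_shift = 0.0
    if shift:
        lo = A.min()
        if lo != 0.0:
            applied_shift = float(lo)
            A = A - lo

    Xn, factors = normalize_bipartite(A)
    U, s, Vt = np.linalg.svd(Xn, full_matrices=False)
    if abs(s[0] - 1.0) > 1e-6:
        raise ValidationError(
            f"top singular value {s[0]:.6g} != 1; normalization precondition violated"
        )
    p = n_informative_vectors(k)
    if p + 1 > s.size:
        raise ValidationError(f"matrix too small for p={p} informative vectors")
    Up = U[:, 1 : p + 1]
    Vp = Vt[1 : p + 1, :].T

    Z = np.vstack(
        [
            Up / np.sqrt(factors.row_sums)[:, None],
            Vp / np.sqrt(factors.col_sums)[:, None],
        ]
    )
    if not np.isfinite(Z).all():
        raise ValidationError("non-finite embedding; check input scaling")

    labels, inertia = _kmeans(Z, k, seed, n_init)
    return BiclusterModel(
        k=k,
        p=p,
        sample_labels=labels[:m],
        gene_labels=labels[m:],
        U=Up,
        V=Vp,
        singular_values=s,
        Z=Z,
        factors=factors,
        inertia=inertia,
        shift=applied_shift,
        seed=seed,
        sample_ids=sample_ids,
        gene_ids=gene_ids,
        method="svd",
    )


def laplacian_cocluster_oracle(
    X,
    k: int = 3,
    seed: int | None = None,
    n_init: int = _DEFAULT_N_INIT,
    shift: bool = True,
    size_bound: int = _ORACLE_SIZE_BOUND,
) -> BiclusterModel:
    """Independent solution path via the generalized eigenproblem of L = D - A.

    Builds the dense bipartite adjacency, solves ``L z = lambda D z``, drops
    the constant eigenvector at lambda = 0 and clusters the next ``p``
    eigenvectors with k-means. Refuses instances with ``m + n`` above
    ``size_bound`` — this path exists to cross-check the SVD route on small
    problems, not to scale.
    """
    M, sample_ids, gene_ids = _as_array(X)
    m, n = M.shape
    if m + n > size_bound:
        raise ValidationError(f"oracle limited to m+n <= {size_bound}, got {m + n}")
    if k < 2:
        raise ValidationError(f"k must be >= 2, got {k}")
    if k > min(m, n):
        raise ValidationError(f"k={k} exceeds min(m, n)={min(m, n)}")

    applied_shift = 0.0
    if shift:
        lo = M.min()
        if lo != 0.0:
            applied_shift = float(lo)
            M = M - lo
    if (M < 0).any():
        raise ValidationError("adjacency must be nonnegative")

    A = np.zeros((m + n, m + n))
    A[:m, m:] = M
    A[m:, :m] = M.T
    d = A.sum(axis=1)
    if (d == 0).any():
        raise ValidationError("graph has an isolated node (zero row/column)")
    D = np.diag(d)
    L = D - A

    # generalized symmetric eigenproblem; eigenvalues ascend from 0
    w, vecs = scipy.linalg.eigh(L, D)
    p = n_informative_vectors(k)
    emb = vecs[:, 1 : p + 1]
    labels, inertia = _kmeans(emb, k, seed, n_init)

    return BiclusterModel(
        k=k,
        p=p,
        sample_labels=labels[:m],
        gene_labels=labels[m:],
        U=emb[:m],
        V=emb[m:],
        singular_values=1.0 - w[: min(m, n)],
        Z=emb,
        factors=None,
        inertia=inertia,
        shift=applied_shift,
        seed=seed,
        sample_ids=sample_ids,
        gene_ids=gene_ids,
        method="laplacian",
    )


def reorder_checkerboard(X, model: BiclusterModel):
    """Permute rows/columns so same-cluster samples and genes are contiguous.

    ``X`` is samples x genes with the dimensions the model was fitted on.
    Rows are sorted by sample label then original index; columns by gene label
    then original index; values are untouched. Returns the permuted matrix and
    the ``(row_order, col_order)`` index arrays.
    """
    A, _, _ = _as_array(X)
    if A.shape != (model.m, model.n):
        raise ValidationError(
            f"matrix shape {A.shape} does not match model ({model.m}, {model.n})"
        )
    row_order = np.lexsort((np.arange(model.m), model.sample_labels))
    col_order = np.lexsort((np.arange(model.n), model.gene_labels))
    if isinstance(X, pd.DataFrame):
        permuted = X.iloc[row_order, col_order]
    else:
        permuted = A[np.ix_(row_order, col_order)]
    return permuted, (row_order, col_order)
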