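"""Relationship and SNP-set kernels.

The polygenic background uses the VanRaden method-1 additive genomic
relationship matrix (GRM).  Each SNP-set gets its own Gram matrix from a
linear, Gaussian, or exponential kernel on the member-marker codes.
Population structure is corrected with the top eigenvectors of the GRM
entered as fixed effects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)

_PSD_TOL = 1e-8


@dataclass
class KernelSpec:
    """Which Gram-matrix kernel to use for SNP-sets.

    bandwidth=None means the median heuristic: the median of the nonzero
    pairwise Euclidean distances between genotype rows.
    """

    kind: str = "linear"
    bandwidth: float | None = None
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "gaussian", "exponential"):
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        if self.bandwidth is not None and self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")


@dataclass
class GramMatrix:
    """A symmetric PSD similarity matrix over genotypes."""

    values: np.ndarray
    ids: list[str]

    def validate(self, tol: float = _PSD_TOL) -> None:
        K = self.values
        if not np.allclose(K, K.T, atol=1e-10):
            raise ValueError("Gram matrix not symmetric")
        w = np.linalg.eigvalsh(K)
        if w.min() < -tol * max(1.0, np.abs(w).max()):
            raise ValueError(f"Gram matrix not PSD: min eigenvalue {w.min():.3g}")

    def to_tsv(self, path: str) -> None:
        import pandas as pd

        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(path, sep="\t")


def _psd_repair(K: np.ndarray) -> np.ndarray:
    """Add a diagonal jitter if round-off pushed the smallest eigenvalue negative."""
    scale = max(np.trace(K) / K.shape[0], 1e-12)
    wmin = np.linalg.eigvalsh(K).min()
    if wmin < -_PSD_TOL * scale:
        logger.info("PSD repair: min eigenvalue %.3g, adding jitter", wmin)
        K = K + np.eye(K.shape[0]) * (_PSD_TOL * scale - wmin)
    return K


def additive_grm(W: np.ndarray, ids: list[str] | None = None) -> GramMatrix:
    """VanRaden method-1 additive GRM from an n x m matrix of {-1, 0, 1} codes.

    Columns are centered at twice the deviation of the alt-allele frequency
    p_j from 1/2 (equivalently, the column mean on this coding) and the
    cross-product is scaled by 2 * sum_j p_j (1 - p_j) over polymorphic
    columns.
    """
    W = np.asarray(W, dtype=float)
    n, m = W.shape
    if m < 1:
        raise ValueError("need at least one marker")
    p = (W + 1.0).sum(axis=0) / (2.0 * n)  # alt-allele frequency
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("all markers monomorphic: GRM denominator is zero")
    Wc = W - 2.0 * (p - 0.5)
    denom = 2.0 * np.sum(p[poly] * (1.0 - p[poly]))
    K = (Wc @ Wc.T) / denom
    if ids is None:
        ids = [f"s{i}" for i in range(n)]
    return GramMatrix(values=_psd_repair(K), ids=list(ids))


def median_bandwidth(W: np.ndarray) -> float:
    """Median of nonzero pairwise Euclidean distances between rows ('median heuristic')."""
    d = pdist(np.asarray(W, dtype=float))
    d = d[d > 0]
    if d.size == 0:
        return 1.0
    return float(np.median(d))


def gram_matrix(W: np.ndarray, spec: KernelSpec, ids: list[str] | None = None) -> GramMatrix:
    """SNP-set Gram matrix from a q x s code matrix.

    linear:       K = W W^T / s
    gaussian:     K_ij = exp(-d_ij^2 / (2 h^2))
    exponential:  K_ij = exp(-d_ij / h)

    with d_ij the Euclidean distance between genotype rows and h the
    bandwidth.  With ``normalize`` the matrix is rescaled to mean diagonal 1
    so weight estimates are comparable across set sizes.
    """
    W = np.asarray(W, dtype=float)
    q, s = W.shape
    if s < 1:
        raise ValueError("need at least one marker in the set")
    if spec.kind == "linear":
        K = (W @ W.T) / s
    else:
        h = spec.bandwidth if spec.bandwidth is not None else median_bandwidth(W)
        if h <= 0:
            raise ValueError("bandwidth must be positive")
        D = squareform(pdist(W))
        if spec.kind == "gaussian":
            K = np.exp(-(D**2) / (2.0 * h**2))
        else:
            K = np.exp(-D / h)
    if spec.normalize:
        md = np.mean(np.diag(K))
        if md > 0:
            K = K / md
    if ids is None:
        ids = [f"s{i}" for i in range(q)]
    return GramMatrix(values=_psd_repair(K), ids=list(ids))


def structure_eigenvectors(K: GramMatrix, k: int = 2) -> np.ndarray:
    """Top-k unit-norm eigenvectors of K, columns ordered by decreasing eigenvalue.

    The default k=2 follows common GWAS practice of correcting structure with
    the two leading axes of the relationship matrix.  Sign convention: the
    largest-magnitude entry of each column is positive.
    """
    n = K.values.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    w, V = np.linalg.eigh(K.values)
    V = V[:, ::-1][:, :k]
    for j in range(k):
        i = np.argmax(np.abs(V[:, j]))
        if V[i, j] < 0:
            V[:, j] = -V[:, j]
    return V
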