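"""Low-dimensional "genome map" coordinates: classical (Torgerson) metric
MDS on distance matrices and allele-frequency-standardised PCA on
genotype matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .distances import DistanceMatrix
from .matrix import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


class ProjectionError(ValueError):
    pass


@dataclass
class EmbeddingResult:
    sample_ids: np.ndarray
    coordinates: np.ndarray  # N x k
    eigenvalues: np.ndarray  # k, non-increasing
    method: str  # "MDS" or "PCA"
    variance_explained: np.ndarray  # k fractions


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Deterministic axis orientation: the largest-magnitude loading of
    each axis is made positive (ties resolved by the first extreme)."""
    out = vectors.copy()
    for j in range(out.shape[1]):
        col = out[:, j]
        if col.any():
            i = int(np.argmax(np.abs(col)))
            if col[i] < 0:
                out[:, j] = -col
    return out


def classical_mds(dist: DistanceMatrix, k: int) -> EmbeddingResult:
    """Torgerson scaling: eigendecompose B = -1/2 J D^2 J and scale the
    top-k eigenvectors by sqrt(eigenvalue).  Negative eigenvalues (the
    distance matrix being non-Euclidean) zero their axes with a warning.
    """
    n = dist.n
    if k < 1:
        raise ProjectionError("k must be >= 1")
    if k >= n:
        raise ProjectionError(f"k={k} must be below the sample count {n}")
    d2 = np.asarray(dist.values, dtype=float) ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(evals)[::-1][:k]
    lam = evals[order]
    vec = evecs[:, order]
    neg = lam < 0
    if neg.any():
        logger.warning(
            "classical_mds: %d of top-%d eigenvalues negative; axes zeroed", neg.sum(), k
        )
    coords = vec * np.sqrt(np.where(neg, 0.0, lam))
    coords[:, neg] = 0.0
    coords = _fix_signs(coords)
    pos_total = evals[evals > 0].sum()
    var_exp = np.where(neg, 0.0, lam) / pos_total if pos_total > 0 else np.zeros(k)
    if pos_total == 0:
        logger.warning("classical_mds: all-zero distance matrix")
    return EmbeddingResult(
        sample_ids=dist.sample_ids.copy(),
        coordinates=coords,
        eigenvalues=lam,
        method="MDS",
        variance_explained=var_exp,
    )


def snp_pca(matrix: GenotypeMatrix, k: int) -> EmbeddingResult:
    """PCA on 0/1/2 dosages, column-centred at twice the allele frequency
    and scaled by sqrt(p(1-p)); missing entries are mean-imputed (zero
    after centring).  Overall-monomorphic markers are excluded."""
    n = matrix.n_samples
    if n < 2:
        raise ProjectionError("need at least two samples")
    if k < 1 or k >= n:
        raise ProjectionError(f"k must be in [1, {n - 1}]")
    dos = matrix.dosage.astype(float)
    dos[matrix.dosage == MISSING] = np.nan
    p_hat = np.nanmean(dos, axis=0) / 2.0
    poly = ~np.isnan(p_hat) & (p_hat > 0) & (p_hat < 1)
    if (~poly).sum():
        logger.info("snp_pca: excluding %d monomorphic/uncalled markers", int((~poly).sum()))
    x = dos[:, poly]
    p = p_hat[poly]
    x = (x - 2 * p) / np.sqrt(p * (1 - p))
    x = np.where(np.isnan(x), 0.0, x)
    cov = x @ x.T / x.shape[1]
    evals, evecs = np.linalg.eigh((cov + cov.T) / 2)
    order = np.argsort(evals)[::-1][:k]
    lam = evals[order]
    coords = _fix_signs(evecs[:, order] * np.sqrt(np.maximum(lam, 0.0)))
    total = evals[evals > 0].sum()
    return EmbeddingResult(
        sample_ids=matrix.sample_ids.copy(),
        coordinates=coords,
        eigenvalues=lam,
        method="PCA",
        variance_explained=np.maximum(lam, 0.0) / total if total > 0 else np.zeros(k),
    )


def embedding_separation(
    coordinates: np.ndarray, pop_labels, n_axes: int = 2
) -> float:
    """Between/within separation in an embedding: mean pairwise distance
    between population centroids divided by the mean RMS spread of the
    populations around their centroids, using the first ``n_axes`` axes."""
    x = np.asarray(coordinates)[:, :n_axes]
    labels = np.asarray(pop_labels, dtype=object)
    pops = list(dict.fromkeys(labels))
    if len(pops) < 2:
        raise ProjectionError("need at least two populations")
    centroids = np.vstack([x[labels == p].mean(axis=0) for p in pops])
    spreads = [
        float(np.sqrt(((x[labels == p] - centroids[i]) ** 2).sum(axis=1).mean()))
        for i, p in enumerate(pops)
    ]
    pair_d = [
        float(np.linalg.norm(centroids[a] - centroids[b]))
        for a in range(len(pops))
        for b in range(a + 1, len(pops))
    ]
    return float(np.mean(pair_d) / np.mean(spreads))


def procrustes_error(x: np.ndarray, y: np.ndarray) -> float:
    """Residual sum of squares after optimally translating, rotating and
    scaling ``y`` onto ``x`` (orthogonal Procrustes with scaling),
    normalised by the total variance of ``x``."""
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    nx = np.linalg.norm(xc)
    ny = np.linalg.norm(yc)
    if nx == 0 or ny == 0:
        raise ProjectionError("degenerate configuration")
    xc /= nx
    yc /= ny
    u, s, vt = np.linalg.svd(xc.T @ yc)
    return float(max(0.0, 1.0 - s.sum() ** 2))
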