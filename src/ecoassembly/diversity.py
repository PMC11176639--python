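"""Alpha diversity, dissimilarity matrices, and principal-coordinates analysis."""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .io import CommunityTable

logger = logging.getLogger(__name__)

__all__ = ["OrdinationResult", "shannon", "bray_curtis", "euclidean", "pcoa"]


@dataclass
class OrdinationResult:
    """Principal-coordinate scores with eigenvalue bookkeeping.

    ``samples`` holds per-sample axis scores (columns PC1, PC2, ... ordered
    by decreasing eigenvalue, scaled by sqrt(eigenvalue)); only
    positive-eigenvalue axes are kept.  The summed magnitude of any negative
    eigenvalues is retained so users can judge how non-Euclidean the input
    distance was.
    """

    samples: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray
    negative_eigenvalue_magnitude: float = 0.0


def shannon(table: CommunityTable) -> pd.Series:
    """Shannon diversity H = -sum p ln p per sample (natural log).

    Conventionally computed on rarefied counts so depth does not bias
    richness; a warning is emitted for other kinds.
    """
    if table.kind != "rarefied":
        logger.warning("shannon: table kind is %r, not 'rarefied'", table.kind)
    mat = table.matrix
    sums = mat.sum(axis=1)
    if (sums == 0).any():
        raise ValueError("shannon undefined for all-zero samples")
    p = mat / sums[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    return pd.Series(-terms.sum(axis=1), index=table.data.index, name="shannon")


def bray_curtis(table: CommunityTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity, BC = sum|x-y| / sum(x+y)."""
    mat = table.matrix
    if (mat.sum(axis=1) == 0).any():
        raise ValueError("bray_curtis undefined for all-zero samples")
    return DistanceMatrix(squareform(pdist(mat, metric="braycurtis")),
                          ids=table.sample_ids)


def euclidean(matrix: pd.DataFrame, standardize: bool = False) -> DistanceMatrix:
    """Pairwise Euclidean distance, optionally after per-column z-scoring."""
    values = matrix.to_numpy(dtype=float)
    if standardize:
        sd = values.std(axis=0, ddof=1)
        if (sd == 0).any():
            bad = [matrix.columns[i] for i in np.flatnonzero(sd == 0)]
            raise ValueError(f"zero-variance columns cannot be standardized: {bad}")
        values = (values - values.mean(axis=0)) / sd
    return DistanceMatrix(squareform(pdist(values, metric="euclidean")),
                          ids=[str(i) for i in matrix.index])


def gower_center(d: np.ndarray) -> np.ndarray:
    """Gower-centered inner-product matrix G = (I - 11'/n)(-D^2/2)(I - 11'/n)."""
    n = d.shape[0]
    a = -0.5 * d ** 2
    centering = np.eye(n) - np.full((n, n), 1.0 / n)
    return centering @ a @ centering


def pcoa(dist: DistanceMatrix, eps: float = 1e-9) -> OrdinationResult:
    """Classical metric scaling of a distance matrix.

    Eigendecomposes the Gower-centered matrix; axes with eigenvalues below
    ``eps`` (relative to the largest) are dropped and the magnitude of
    negative eigenvalues is logged rather than corrected.
    """
    n = dist.shape[0]
    if n < 3:
        raise ValueError("pcoa needs at least 3 samples")
    g = gower_center(np.asarray(dist.data, dtype=float))
    eigvals, eigvecs = np.linalg.eigh(g)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = eps * max(abs(eigvals[0]), 1.0)
    pos = eigvals > tol
    neg_mag = float(-eigvals[eigvals < -tol].sum()) if (eigvals < -tol).any() else 0.0
    if neg_mag:
        logger.info("pcoa: dropped negative eigenvalues with summed magnitude %.4g",
                    neg_mag)
    lam = eigvals[pos]
    scores = eigvecs[:, pos] * np.sqrt(lam)
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    samples = pd.DataFrame(scores, index=list(dist.ids), columns=cols)
    return OrdinationResult(
        samples=samples,
        eigenvalues=lam,
        proportion_explained=lam / lam.sum(),
        negative_eigenvalue_magnitude=neg_mag,
    )
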