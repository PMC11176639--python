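"""Moran's eigenvector maps and environment/space variance partitioning.

Distance-based MEMs (dbMEM) provide an orthogonal spatial basis from sample
coordinates: the geographic distance matrix is truncated at the longest
minimum-spanning-tree edge (distances beyond it set to four times the
threshold), the truncated matrix is eigendecomposed, and the
positive-eigenvalue eigenvectors model spatial structure from broad to fine
scale.  Variance partitioning then splits the (adjusted) explained
variation of a community distance matrix into pure-environment, shared,
pure-space, and residual fractions via partial distance-based RDA.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from ._rng import derive_seed
from .diversity import gower_center
from .multivariate import bh_adjust

logger = logging.getLogger(__name__)

__all__ = ["MemBasis", "VariancePartition", "build_dbmem", "select_mems",
           "varpart_env_space"]


@dataclass
class MemBasis:
    """Orthonormal spatial eigenvectors (columns MEM1, MEM2, ... by
    decreasing eigenvalue; positive-eigenvalue vectors only)."""

    vectors: pd.DataFrame
    eigenvalues: np.ndarray
    truncation: float

    @property
    def n_vectors(self) -> int:
        return self.vectors.shape[1]

    def select(self, names) -> "MemBasis":
        names = list(names)
        keep = [self.vectors.columns.get_loc(c) for c in names]
        return MemBasis(self.vectors.loc[:, names],
                        self.eigenvalues[keep], self.truncation)


@dataclass
class VariancePartition:
    """Adjusted-R2 fractions: a (environment only), b (shared), c (space
    only), d (residual).  a and c can be slightly negative because of the
    adjustment; values below -0.05 are flagged."""

    fraction_env_only: float
    fraction_shared: float
    fraction_space_only: float
    fraction_residual: float
    r2_env: float
    r2_space: float
    r2_both: float
    r2adj_env: float
    r2adj_space: float
    r2adj_both: float
    mem_names: tuple[str, ...] = ()

    def as_series(self) -> pd.Series:
        return pd.Series({
            "a_env_only": self.fraction_env_only,
            "b_shared": self.fraction_shared,
            "c_space_only": self.fraction_space_only,
            "d_residual": self.fraction_residual,
        })


def build_dbmem(coordinates: np.ndarray | pd.DataFrame,
                ids=None) -> MemBasis:
    """Distance-based Moran's eigenvector maps from sample coordinates."""
    if isinstance(coordinates, pd.DataFrame):
        if ids is None:
            ids = [str(i) for i in coordinates.index]
        coordinates = coordinates.to_numpy(dtype=float)
    coords = np.asarray(coordinates, dtype=float)
    n = coords.shape[0]
    if n < 4:
        raise ValueError("need at least 4 samples for dbMEM")
    if ids is None:
        ids = [str(i) for i in range(n)]
    d = squareform(pdist(coords))
    if d.max() == 0:
        raise ValueError("all coordinates identical; no spatial structure")
    mst = minimum_spanning_tree(d).toarray()
    trunc = float(mst.max())
    d_trunc = np.where(d > trunc, 4.0 * trunc, d)
    np.fill_diagonal(d_trunc, 0.0)
    g = gower_center(d_trunc)
    eigvals, eigvecs = np.linalg.eigh(g)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos = eigvals > 1e-9 * max(abs(eigvals).max(), 1.0)
    lam, vec = eigvals[pos], eigvecs[:, pos]
    cols = [f"MEM{i + 1}" for i in range(vec.shape[1])]
    logger.info("build_dbmem: truncation %.4g m, %d positive eigenvectors",
                trunc, len(cols))
    return MemBasis(pd.DataFrame(vec, index=ids, columns=cols), lam, trunc)


def _marginal_pseudo_f(g: np.ndarray, v: np.ndarray) -> float:
    """Single-predictor dbRDA pseudo-F (intercept + one column)."""
    n = g.shape[0]
    x = np.column_stack([np.ones(n), v])
    q, _ = np.linalg.qr(x)
    h = q @ q.T
    ss_x = float(np.sum(h * g))
    ss_res = float(np.trace(g)) - ss_x
    return ss_x / (ss_res / (n - 2))


def select_mems(basis: MemBasis, dist: DistanceMatrix, n_perm: int = 999,
                alpha: float = 0.05, seed: int = 0) -> MemBasis:
    """Retain MEMs that significantly correlate with the community distances.

    Each eigenvector is tested marginally with a single-variable dbRDA
    pseudo-F and a free-permutation p-value; Benjamini-Hochberg correction
    is applied across eigenvectors and those with adjusted p < alpha are
    kept (possibly none).
    """
    ids = list(dist.ids)
    vec = basis.vectors.loc[ids]
    g = gower_center(np.asarray(dist.data, dtype=float))
    n = len(ids)
    rng = np.random.default_rng(derive_seed(seed, "select_mems"))
    pvals = []
    for col in vec.columns:
        v = vec[col].to_numpy()
        f_obs = _marginal_pseudo_f(g, v)
        hits = 0
        for _ in range(n_perm):
            p = rng.permutation(n)
            if _marginal_pseudo_f(g[np.ix_(p, p)], v) >= f_obs - 1e-12:
                hits += 1
        pvals.append((hits + 1) / (n_perm + 1))
    adj = bh_adjust(pvals)
    keep = [c for c, q in zip(vec.columns, adj) if q < alpha]
    logger.info("select_mems: retained %d of %d MEMs: %s",
                len(keep), basis.n_vectors, keep)
    return basis.select(keep)


def _r2_adj(r2: float, n: int, p: int) -> float:
    """Ezekiel's adjustment, 1 - (1 - R2)(n - 1)/(n - p - 1)."""
    if p == 0:
        return 0.0
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def varpart_env_space(dist: DistanceMatrix, chemistry: pd.DataFrame,
                      mem_selected: MemBasis) -> VariancePartition:
    """Partition community variation between environment and space.

    Fits three dbRDA models on the Gower-centered community distances --
    environment (standardized chemistry), space (selected MEMs), and their
    union -- and decomposes adjusted R2 into pure and shared fractions.
    """
    ids = list(dist.ids)
    n = len(ids)
    g = gower_center(np.asarray(dist.data, dtype=float))
    ss_total = float(np.trace(g))

    chem = chemistry.loc[ids].to_numpy(dtype=float)
    sd = chem.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise ValueError("zero-variance chemistry column")
    env = (chem - chem.mean(axis=0)) / sd
    space = mem_selected.vectors.loc[ids].to_numpy(dtype=float) \
        if mem_selected.n_vectors else np.empty((n, 0))

    def _r2(x: np.ndarray) -> float:
        if x.shape[1] == 0:
            return 0.0
        u, s, _ = np.linalg.svd(np.column_stack([np.ones(n), x]),
                                full_matrices=False)
        u = u[:, s > max(n, x.shape[1] + 1) * np.finfo(float).eps * s[0]]
        return float(np.sum((u @ u.T) * g)) / ss_total

    p_env, p_spc = env.shape[1], space.shape[1]
    for label, p in (("environment", p_env), ("space", p_spc),
                     ("union", p_env + p_spc)):
        if p >= n - 1:
            raise ValueError(f"{label} model saturated: {p} predictors, n={n}")

    r2_e, r2_s = _r2(env), _r2(space)
    r2_es = _r2(np.hstack([env, space]))
    adj_e = _r2_adj(r2_e, n, p_env)
    adj_s = _r2_adj(r2_s, n, p_spc)
    adj_es = _r2_adj(r2_es, n, p_env + p_spc)

    if p_spc == 0:
        a, b, c = adj_e, 0.0, 0.0
    else:
        a = adj_es - adj_s
        c = adj_es - adj_e
        b = adj_e - a
    d = 1.0 - (a + b + c)
    for name, frac in (("a", a), ("c", c)):
        if frac < -0.05:
            logger.warning("varpart: fraction %s strongly negative (%.3f)",
                           name, frac)
    return VariancePartition(
        fraction_env_only=a, fraction_shared=b, fraction_space_only=c,
        fraction_residual=d, r2_env=r2_e, r2_space=r2_s, r2_both=r2_es,
        r2adj_env=adj_e, r2adj_space=adj_s, r2adj_both=adj_es,
        mem_names=tuple(mem_selected.vectors.columns),
    )
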