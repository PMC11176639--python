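"""Permutation-based multivariate inference on distance matrices.

PERMANOVA with sequential (Type-I) terms, Mantel tests and distance-decay
fits, symmetric Procrustes congruence with a permutation test, and
distance-based linear model (DistLM) forward selection.  All sums of
squares are computed directly from the Gower-centered distance matrix
(McArdle-Anderson), so non-Euclidean dissimilarities such as Bray-Curtis
are handled without embedding loss.  Permutation p-values use the
(b+1)/(m+1) estimator, so p = 0 is impossible; exhaustive enumeration of
all relabelings is available for small n.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform
from scipy.stats import false_discovery_control
from skbio import DistanceMatrix

from ._rng import derive_seed
from .diversity import gower_center

__all__ = [
    "permanova",
    "mantel",
    "MantelResult",
    "distance_decay",
    "DistanceDecayResult",
    "procrustes_test",
    "ProcrustesResult",
    "distlm_forward",
    "DistlmResult",
    "bh_adjust",
]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    return false_discovery_control(np.asarray(pvalues, dtype=float), method="bh")


def _hat(x: np.ndarray) -> np.ndarray:
    """Orthogonal projector onto the column space of ``x`` (rank-safe)."""
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    tol = max(x.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    u = u[:, s > tol]
    return u @ u.T


def _dummies(series: pd.Series) -> np.ndarray:
    return pd.get_dummies(series.astype(str), drop_first=False).to_numpy(float)


def _iter_perms(n: int, n_perm: int, rng: np.random.Generator | None,
                exhaustive: bool):
    if exhaustive:
        if math.factorial(n) > 500_000:
            raise ValueError("exhaustive enumeration infeasible for n > 9")
        return [np.array(p) for p in itertools.permutations(range(n))]
    return [rng.permutation(n) for _ in range(n_perm)]


def permanova(dist: DistanceMatrix, metadata: pd.DataFrame, terms: list[str],
              n_perm: int = 999, seed: int = 0,
              exhaustive: bool = False) -> pd.DataFrame:
    """Sequential (Type-I) PERMANOVA of a distance matrix on categorical terms.

    Terms are fitted in the order given; each term's sum of squares is the
    increment in explained SS over the preceding terms, computed from the
    Gower-centered matrix.  Significance is by free permutation of sample
    labels.  With ``exhaustive=True`` every relabeling is enumerated and the
    p-value is the exact proportion (identity included).

    Returns a frame with one row per term plus Residual and Total rows:
    columns df, SS, R2, F, p.
    """
    ids = list(dist.ids)
    meta = metadata.loc[ids]
    n = len(ids)
    g = gower_center(np.asarray(dist.data, dtype=float))
    ss_total = float(np.trace(g))

    designs = [np.ones((n, 1))]
    for term in terms:
        col = meta[term]
        if col.nunique() < 2:
            raise ValueError(f"term {term!r} has a single level")
        designs.append(np.hstack([designs[-1], _dummies(col)]))
    hats = [_hat(x) for x in designs]
    ranks = [int(round(np.trace(h))) for h in hats]
    dfs = [ranks[k + 1] - ranks[k] for k in range(len(terms))]
    df_res = n - ranks[-1]
    if df_res <= 0:
        raise ValueError("model saturated: no residual degrees of freedom")
    # increment projectors; tr(H G) gives each cumulative model's explained SS
    deltas = [hats[k + 1] - hats[k] for k in range(len(terms))]
    resid = np.eye(n) - hats[-1]

    def _stats(gm: np.ndarray):
        ss_terms = np.array([float(np.sum(d * gm)) for d in deltas])
        ss_res = float(np.sum(resid * gm))
        f = (ss_terms / np.array(dfs)) / (ss_res / df_res)
        return ss_terms, ss_res, f

    ss_terms, ss_res, f_obs = _stats(g)

    rng = None if exhaustive else np.random.default_rng(
        derive_seed(seed, "permanova"))
    perms = _iter_perms(n, n_perm, rng, exhaustive)
    hits = np.zeros(len(terms))
    m = 0
    for p in perms:
        if not exhaustive and np.array_equal(p, np.arange(n)):
            pass  # random identity draws are legitimate permutations
        gp = g[np.ix_(p, p)]
        _, _, f_perm = _stats(gp)
        hits += f_perm >= f_obs - 1e-12
        m += 1
    if exhaustive:
        pvals = hits / m
    else:
        pvals = (hits + 1) / (m + 1)

    rows = []
    for k, term in enumerate(terms):
        rows.append({"term": term, "df": dfs[k], "SS": ss_terms[k],
                     "R2": ss_terms[k] / ss_total, "F": f_obs[k],
                     "p": pvals[k]})
    rows.append({"term": "Residual", "df": df_res, "SS": ss_res,
                 "R2": ss_res / ss_total, "F": np.nan, "p": np.nan})
    rows.append({"term": "Total", "df": n - 1, "SS": ss_total, "R2": 1.0,
                 "F": np.nan, "p": np.nan})
    return pd.DataFrame(rows)


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int


def _check_same_ids(a: DistanceMatrix, b: DistanceMatrix) -> None:
    if list(a.ids) != list(b.ids):
        raise ValueError("distance matrices must share labels in the same order")


def mantel(dist_a: DistanceMatrix, dist_b: DistanceMatrix, n_perm: int = 999,
           seed: int = 0, alternative: str = "greater",
           exhaustive: bool = False) -> MantelResult:
    """Mantel correlation between two distance matrices.

    Pearson r over the n(n-1)/2 off-diagonal entries; the one-tailed
    ("greater") p-value is the fraction of row/column relabelings of the
    second matrix with r_perm >= r_obs.
    """
    _check_same_ids(dist_a, dist_b)
    a = np.asarray(dist_a.data, float)
    b = np.asarray(dist_b.data, float)
    n = a.shape[0]
    va = squareform(a, checks=False)
    if va.std() == 0 or squareform(b, checks=False).std() == 0:
        raise ValueError("mantel undefined for constant distance matrices")
    va_c = (va - va.mean()) / (va.std() * va.size)

    def _r(bm: np.ndarray) -> float:
        vb = squareform(bm, checks=False)
        return float(va_c @ ((vb - vb.mean()) / vb.std()))

    r_obs = _r(b)
    rng = None if exhaustive else np.random.default_rng(derive_seed(seed, "mantel"))
    perms = _iter_perms(n, n_perm, rng, exhaustive)
    stat = (lambda r: abs(r)) if alternative == "two-sided" else (lambda r: r)
    hits = sum(stat(_r(b[np.ix_(p, p)])) >= stat(r_obs) - 1e-12 for p in perms)
    m = len(perms)
    p = hits / m if exhaustive else (hits + 1) / (m + 1)
    return MantelResult(r=r_obs, p=float(p), n_perm=m)


@dataclass
class DistanceDecayResult:
    """Distance-decay of similarity: Mantel effect size plus fitted slope.

    ``r`` is the Pearson correlation between similarity (1 - dissimilarity)
    and distance (negative under decay); ``p`` is the one-tailed Mantel
    p-value for turnover increasing with distance; ``slope``/``intercept``
    are the least-squares fit of similarity on distance for plotting.
    """

    r: float
    p: float
    slope: float
    intercept: float
    n_perm: int


def distance_decay(dissimilarity: DistanceMatrix, dist: DistanceMatrix,
                   n_perm: int = 999, seed: int = 0) -> DistanceDecayResult:
    """Test and fit the decay of community similarity with distance."""
    _check_same_ids(dissimilarity, dist)
    res = mantel(dissimilarity, dist, n_perm=n_perm, seed=seed,
                 alternative="greater")
    sim = 1.0 - squareform(np.asarray(dissimilarity.data, float), checks=False)
    d = squareform(np.asarray(dist.data, float), checks=False)
    slope, intercept = np.polyfit(d, sim, 1)
    return DistanceDecayResult(r=-res.r, p=res.p, slope=float(slope),
                               intercept=float(intercept), n_perm=res.n_perm)


@dataclass
class ProcrustesResult:
    m12_squared: float
    r: float
    p: float
    n_perm: int


def _procrustes_m2(x: np.ndarray, y: np.ndarray) -> float:
    """Symmetric Procrustes residual after optimal translation, scaling and
    rotation/reflection: m12^2 = 1 - (sum of singular values of X'Y)^2 for
    centered, unit-norm configurations."""
    s = np.linalg.svd(x.T @ y, compute_uv=False)
    return float(max(0.0, 1.0 - s.sum() ** 2))


def procrustes_test(scores_x, scores_y, n_perm: int = 999,
                    seed: int = 0) -> ProcrustesResult:
    """Symmetric Procrustes congruence of two sample configurations with a
    permutation test (rows of the second configuration are permuted)."""
    x = np.asarray(scores_x, dtype=float)
    y = np.asarray(scores_y, dtype=float)
    if x.shape[0] != y.shape[0]:
        raise ValueError("configurations must have the same samples")
    k = min(x.shape[1], y.shape[1])
    if k < 2:
        raise ValueError("need at least 2 axes per configuration")
    x, y = x[:, :k].copy(), y[:, :k].copy()
    for arr in (x, y):
        arr -= arr.mean(axis=0)
        norm = np.linalg.norm(arr)
        if norm == 0:
            raise ValueError("degenerate (all-identical) configuration")
        arr /= norm
    m2_obs = _procrustes_m2(x, y)
    r_obs = math.sqrt(1.0 - m2_obs)
    rng = np.random.default_rng(derive_seed(seed, "procrustes"))
    hits = 0
    for _ in range(n_perm):
        yp = y[rng.permutation(y.shape[0])]
        yp = yp - yp.mean(axis=0)
        yp /= np.linalg.norm(yp)
        if _procrustes_m2(x, yp) <= m2_obs + 1e-12:
            hits += 1
    return ProcrustesResult(m12_squared=m2_obs, r=r_obs,
                            p=(hits + 1) / (n_perm + 1), n_perm=n_perm)


@dataclass
class DistlmResult:
    """Forward-selection trace plus marginal (single-variable) fits."""

    selected: pd.DataFrame  # step, variable, added_R2, cumulative_R2, F, p
    marginal: pd.DataFrame  # variable, R2


def distlm_forward(dist: DistanceMatrix, chemistry: pd.DataFrame,
                   n_perm: int = 999, alpha: float = 0.05,
                   seed: int = 0) -> DistlmResult:
    """Distance-based multivariate regression with forward selection.

    Explained SS is computed directly from the Gower-centered distance
    matrix, so negative-eigenvalue components are handled exactly.  At each
    step the predictor with the largest added R2 enters, its pseudo-F is
    tested by free permutation, and selection stops when the best candidate
    is not significant at ``alpha``.
    """
    if chemistry.shape[1] == 0:
        raise ValueError("no predictor variables")
    ids = list(dist.ids)
    chem = chemistry.loc[ids]
    x_all = chem.to_numpy(dtype=float)
    x_all = (x_all - x_all.mean(axis=0)) / x_all.std(axis=0, ddof=1)
    n = len(ids)
    g = gower_center(np.asarray(dist.data, dtype=float))
    ss_total = float(np.trace(g))
    ones = np.ones((n, 1))

    def _r2(cols: list[int]) -> float:
        h = _hat(np.hstack([ones] + [x_all[:, [c]] for c in cols]))
        return float(np.sum(h * g)) / ss_total

    variables = list(chem.columns)
    marginal = pd.DataFrame({
        "variable": variables,
        "R2": [_r2([c]) for c in range(len(variables))],
    })

    rng = np.random.default_rng(derive_seed(seed, "distlm"))
    selected: list[int] = []
    rows = []
    r2_sel = 0.0
    while len(selected) < len(variables):
        candidates = [c for c in range(len(variables)) if c not in selected]
        r2_full = {c: _r2(selected + [c]) for c in candidates}
        best = max(candidates, key=lambda c: r2_full[c])
        added = r2_full[best] - r2_sel
        p_model = len(selected) + 1
        df_res = n - p_model - 1
        if df_res <= 0:
            break
        h_sel = _hat(np.hstack([ones] + [x_all[:, [c]] for c in selected]))
        h_full = _hat(np.hstack([ones] + [x_all[:, [c]]
                                          for c in selected + [best]]))
        delta, resid = h_full - h_sel, np.eye(n) - h_full

        def _f(gm: np.ndarray) -> float:
            return (float(np.sum(delta * gm)) /
                    (float(np.sum(resid * gm)) / df_res))

        f_obs = _f(g)
        hits = 0
        for _ in range(n_perm):
            p = rng.permutation(n)
            if _f(g[np.ix_(p, p)]) >= f_obs - 1e-12:
                hits += 1
        pval = (hits + 1) / (n_perm + 1)
        if pval > alpha:
            break
        selected.append(best)
        r2_sel = r2_full[best]
        rows.append({"step": len(selected), "variable": variables[best],
                     "added_R2": added, "cumulative_R2": r2_sel,
                     "F": f_obs, "p": pval})
    cols = ["step", "variable", "added_R2", "cumulative_R2", "F", "p"]
    return DistlmResult(selected=pd.DataFrame(rows, columns=cols),
                        marginal=marginal)
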