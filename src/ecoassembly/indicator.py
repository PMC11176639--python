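"""Indicator value (IndVal) analysis.

For each feature (taxon or functional category) and group, specificity A
is the feature's (group-equalized) mean relative abundance concentration in
that group and fidelity B is the fraction of the group's samples that
contain it; IndVal = max over groups of A*B*100.  Significance is assessed
by permuting group labels, with Benjamini-Hochberg correction across
features.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import derive_seed
from .io import CommunityTable
from .multivariate import bh_adjust

__all__ = ["IndvalResult", "indval"]


@dataclass
class IndvalResult:
    """Per-feature indicator statistics.

    ``table`` columns: feature, group (argmax group), A, B, indval, p,
    p_adjusted.  ``significant(alpha)`` returns the features whose adjusted
    p is below alpha.
    """

    table: pd.DataFrame
    n_perm: int

    def significant(self, alpha: float = 0.05,
                    adjusted: bool = True) -> pd.DataFrame:
        col = "p_adjusted" if adjusted else "p"
        return self.table[self.table[col] < alpha]


def _indval_components(mat: np.ndarray, group_codes: np.ndarray,
                       n_groups: int, group_equalized: bool):
    """A (specificity), B (fidelity) matrices of shape (n_groups, n_features)."""
    means = np.empty((n_groups, mat.shape[1]))
    sums = np.empty((n_groups, mat.shape[1]))
    occ = np.empty((n_groups, mat.shape[1]))
    for gix in range(n_groups):
        sub = mat[group_codes == gix]
        means[gix] = sub.mean(axis=0)
        sums[gix] = sub.sum(axis=0)
        occ[gix] = (sub > 0).mean(axis=0)
    # group-equalized (Dufrene-Legendre): share of per-group mean abundance;
    # raw variant: share of pooled abundance, sensitive to group sizes
    num = means if group_equalized else sums
    denom = num.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = np.where(denom > 0, num / denom, 0.0)
    return a, occ


def indval(table: CommunityTable, groups: pd.Series | dict,
           n_perm: int = 999, seed: int = 0,
           group_equalized: bool = True) -> IndvalResult:
    """IndVal analysis of features against a sample grouping.

    ``table`` must hold relative or CSS-normalized abundances (IndVal's
    specificity is only meaningful when rows are on a common scale).
    ``groups`` maps sample ids to group labels; every group needs at least
    two samples.  ``group_equalized`` uses the Dufrene-Legendre correction
    (specificity from group means rather than pooled sums), removing
    group-size bias.
    """
    if table.kind not in ("relative", "css"):
        raise ValueError(
            "indval requires kind='relative' or 'css'; normalize first")
    groups = pd.Series(groups)
    groups = groups.loc[table.sample_ids]
    levels = sorted(groups.unique())
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    sizes = groups.value_counts()
    if (sizes < 2).any():
        raise ValueError(f"every group needs >= 2 samples; got {dict(sizes)}")
    mat = table.matrix
    absent = mat.sum(axis=0) == 0
    if absent.any():
        bad = [table.taxon_ids[i] for i in np.flatnonzero(absent)][:5]
        raise ValueError(f"features absent from every sample: {bad}")
    codes = groups.map({lvl: i for i, lvl in enumerate(levels)}).to_numpy()
    n_groups = len(levels)

    a, b = _indval_components(mat, codes, n_groups, group_equalized)
    stat = a * b
    best = stat.argmax(axis=0)
    obs = stat.max(axis=0)

    rng = np.random.default_rng(derive_seed(seed, "indval"))
    hits = np.zeros(mat.shape[1])
    for _ in range(n_perm):
        perm_codes = codes[rng.permutation(codes.size)]
        ap, bp = _indval_components(mat, perm_codes, n_groups, group_equalized)
        hits += (ap * bp).max(axis=0) >= obs - 1e-12
    pvals = (hits + 1) / (n_perm + 1)
    result = pd.DataFrame({
        "feature": table.taxon_ids,
        "group": [levels[g] for g in best],
        "A": a[best, np.arange(mat.shape[1])],
        "B": b[best, np.arange(mat.shape[1])],
        "indval": obs * 100.0,
        "p": pvals,
        "p_adjusted": bh_adjust(pvals),
    })
    return IndvalResult(table=result, n_perm=n_perm)


def aggregate_by_category(result: IndvalResult, category_map: pd.Series | dict,
                          alpha: float = 0.05) -> pd.DataFrame:
    """Proportion of significant indicator features per higher-level category,
    split by indicator group (e.g. level-4 functions rolled up to level 1)."""
    cat = pd.Series(category_map)
    sig = result.significant(alpha).copy()
    if sig.empty:
        return pd.DataFrame(columns=["group", "category", "n", "proportion"])
    sig["category"] = sig["feature"].map(cat)
    out = (sig.groupby(["group", "category"]).size()
           .rename("n").reset_index())
    totals = out.groupby("group")["n"].transform("sum")
    out["proportion"] = out["n"] / totals
    return out
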