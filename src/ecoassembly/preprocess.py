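"""Count-table and covariate preparation.

Implements the survey's preprocessing rules: removal of shallow samples,
rarefaction to even depth (without-replacement subsampling), cumulative sum
scaling (CSS) normalization, conversion to relative abundance, and greedy
pruning of collinear soil-chemistry variables.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._rng import derive_seed
from .io import CommunityTable, SampleFrame

logger = logging.getLogger(__name__)

__all__ = [
    "PreprocessConfig",
    "filter_low_depth",
    "rarefy",
    "css_normalize",
    "to_relative",
    "prune_collinear",
    "CollinearityReport",
]


@dataclass
class PreprocessConfig:
    """Knobs of the preparation stage.

    rarefaction_depth
        Even depth each sample is subsampled to (reads).
    min_sample_reads
        Samples with fewer total reads are discarded before any
        beta-diversity analysis (strict ``<`` rule).
    css_quantile, css_scale
        Quantile of a sample's nonzero count distribution up to which counts
        are summed for the CSS scaling factor, and the constant the scaled
        values are multiplied by.
    collinearity_cutoff
        Absolute Pearson correlation above which one of a pair of chemistry
        variables is dropped.
    """

    rarefaction_depth: int = 6500
    min_sample_reads: int = 1000
    css_quantile: float = 0.5
    css_scale: float = 1000.0
    collinearity_cutoff: float = 0.65
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.rarefaction_depth < 1:
            raise ValueError("rarefaction_depth must be >= 1")
        if not 0 < self.css_quantile < 1:
            raise ValueError("css_quantile must be in (0, 1)")
        if not 0 < self.collinearity_cutoff < 1:
            raise ValueError("collinearity_cutoff must be in (0, 1)")
        if self.css_scale <= 0:
            raise ValueError("css_scale must be positive")


def filter_low_depth(table: CommunityTable, min_sample_reads: int) -> CommunityTable:
    """Drop samples whose total count is strictly below ``min_sample_reads``;
    taxa left with all-zero columns are dropped too."""
    if table.kind != "counts":
        raise ValueError("filter_low_depth expects kind='counts'")
    sums = table.row_sums()
    keep = sums >= min_sample_reads
    if not keep.any():
        raise ValueError("depth filter removed every sample")
    dropped = sums.index[~keep].tolist()
    if dropped:
        logger.info("filter_low_depth: removed %d samples below %d reads: %s",
                    len(dropped), min_sample_reads, dropped)
    return CommunityTable(table.data.loc[keep], kind="counts").drop_empty_taxa()


def rarefy(table: CommunityTable, depth: int, seed: int = 0) -> CommunityTable:
    """Subsample every sample to ``depth`` reads without replacement.

    Each sample's subsample is an exact multivariate-hypergeometric draw.
    Per-sample streams are derived from ``seed`` and the sample id, so
    results do not depend on sample order.  Samples shallower than ``depth``
    are dropped with a warning.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    if table.kind != "counts":
        raise ValueError("rarefy expects kind='counts'")
    sums = table.row_sums()
    shallow = sums.index[sums < depth].tolist()
    if shallow:
        logger.warning("rarefy: dropping %d samples shallower than %d: %s",
                       len(shallow), depth, shallow)
    keep = sums.index[sums >= depth]
    out = {}
    for sid in keep:
        counts = table.data.loc[sid].to_numpy(dtype=np.int64)
        if counts.sum() == depth:
            out[sid] = counts
            continue
        rng = np.random.default_rng(derive_seed(seed, "rarefy", sid))
        out[sid] = rng.multivariate_hypergeometric(counts, depth, method="marginals")
    rare = pd.DataFrame.from_dict(out, orient="index", columns=table.data.columns)
    rare = rare.loc[keep]
    return CommunityTable(rare, kind="rarefied").drop_empty_taxa()


def _css_factor(counts: np.ndarray, quantile: float) -> float:
    """CSS scaling factor: the cumulative sum of a sample's smallest nonzero
    counts up to the quantile *position* ceil(q * n) of its sorted nonzero
    count distribution (so four equal counts at q=0.5 sum the lowest two)."""
    nz = np.sort(counts[counts > 0])
    if nz.size == 0:
        return 0.0
    k = max(1, int(np.ceil(quantile * nz.size)))
    return float(nz[:k].sum())


def css_normalize(table: CommunityTable, quantile: float = 0.5,
                  scale: float = 1000.0) -> CommunityTable:
    """Cumulative sum scaling: divide each sample by the cumulative count of
    its lower-quantile taxa, times ``scale``.  Dampens the influence of a
    few dominant taxa relative to total-sum scaling."""
    if table.kind != "counts":
        raise ValueError("css_normalize expects kind='counts'")
    if not 0 < quantile < 1:
        raise ValueError("quantile must be in (0, 1)")
    mat = table.matrix
    factors = np.array([_css_factor(row, quantile) for row in mat])
    zero = factors == 0
    if zero.any():
        bad = [table.sample_ids[i] for i in np.flatnonzero(zero)]
        raise ValueError(f"CSS scaling factor is zero for samples: {bad}")
    data = pd.DataFrame(mat * scale / factors[:, None],
                        index=table.data.index, columns=table.data.columns)
    return CommunityTable(data, kind="css")


def to_relative(table: CommunityTable) -> CommunityTable:
    """Row-normalize to relative abundances (idempotent)."""
    sums = table.matrix.sum(axis=1)
    if (sums == 0).any():
        bad = [table.sample_ids[i] for i in np.flatnonzero(sums == 0)]
        raise ValueError(f"cannot normalize all-zero samples: {bad}")
    data = pd.DataFrame(table.matrix / sums[:, None],
                        index=table.data.index, columns=table.data.columns)
    return CommunityTable(data, kind="relative")


@dataclass
class CollinearityReport:
    """What the greedy pruning dropped and why."""

    dropped: list[str] = field(default_factory=list)
    triggers: list[tuple[str, str, float]] = field(default_factory=list)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.triggers,
                            columns=["dropped", "against", "pearson_r"])


def prune_collinear(frame: SampleFrame, cutoff: float = 0.65
                    ) -> tuple[SampleFrame, CollinearityReport]:
    """Greedily drop chemistry variables until no pair has ``|r| > cutoff``.

    At each step the worst-offending pair (largest ``|r|``) is found and the
    member with the larger mean ``|r|`` against all remaining variables is
    dropped; ties break lexicographically.  Samples with missing chemistry
    are excluded from the correlation computation.
    """
    chem_vars = list(frame.chemistry_vars)
    if len(chem_vars) < 2:
        raise ValueError("need at least 2 chemistry variables")
    chem = frame.chemistry().dropna(axis=0)
    if chem.shape[0] < 3:
        raise ValueError("need at least 3 complete samples")
    report = CollinearityReport()
    remaining = list(chem_vars)
    while len(remaining) > 1:
        corr = chem[remaining].corr(method="pearson").abs()
        np.fill_diagonal(corr.values, 0.0)
        worst = float(corr.values.max())
        if worst <= cutoff:
            break
        i, j = np.unravel_index(np.argmax(corr.values), corr.shape)
        a, b = corr.index[i], corr.columns[j]
        mean_a, mean_b = corr[a].mean(), corr[b].mean()
        if mean_a > mean_b:
            drop, keep = a, b
        elif mean_b > mean_a:
            drop, keep = b, a
        else:
            drop, keep = max(a, b), min(a, b)
        report.dropped.append(str(drop))
        report.triggers.append((str(drop), str(keep), float(chem[a].corr(chem[b]))))
        remaining.remove(drop)
    logger.info("prune_collinear: retained %d of %d variables (dropped %s)",
                len(remaining), len(chem_vars), report.dropped)
    kept_order = [v for v in chem_vars if v in set(remaining)]
    pruned = frame.drop_chemistry([v for v in chem_vars if v not in set(remaining)])
    pruned = SampleFrame(pruned.data, tuple(kept_order))
    return pruned, report
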