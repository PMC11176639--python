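"""Two-step null-model classification of pairwise community assembly processes.

For every pair of communities the classifier first measures phylogenetic
turnover (beta mean nearest taxon distance, betaMNTD) and standardizes it
against a taxon-shuffling null to obtain the beta nearest taxon index
(betaNTI).  Pairs with |betaNTI| > 2 are attributed to deterministic
selection: consistently low turnover (betaNTI < -2) to homogeneous
selection, consistently high turnover (betaNTI > +2) to heterogeneous
selection.  Remaining pairs are assessed with the Raup-Crick metric on
Bray-Curtis dissimilarity (RCBray), which compares observed compositional
turnover against a stochastic assembly null that preserves each sample's
richness and abundance while drawing taxa from the regional pool.
RCBray > +0.95 indicates dispersal limitation (plus drift), RCBray < -0.95
homogenizing dispersal, and anything else is left undominated.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import derive_seed
from .io import CommunityTable, Phylogeny
from .preprocess import to_relative

logger = logging.getLogger(__name__)

PROCESSES = (
    "homogeneous_selection",
    "heterogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "undominated",
)

__all__ = [
    "NullModelConfig",
    "BntiResult",
    "PROCESSES",
    "beta_mntd",
    "beta_mntd_matrix",
    "bnti",
    "rc_bray",
    "sample_null_communities",
    "raup_crick_score",
    "classify_pair",
    "classify_assembly",
    "summarize_processes",
]


@dataclass
class NullModelConfig:
    """Null-model settings for the two-step classifier."""

    n_null: int = 999
    bnti_threshold: float = 2.0
    rc_threshold: float = 0.95
    abundance_weighted: bool = True
    equality_tolerance: float = 1e-12
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_null < 1:
            raise ValueError("n_null must be >= 1")
        if self.bnti_threshold <= 0 or self.rc_threshold <= 0:
            raise ValueError("thresholds must be positive")


# ---------------------------------------------------------------------------
# betaMNTD / betaNTI


def _weights(mat: np.ndarray, abundance_weighted: bool) -> np.ndarray:
    """Per-sample taxon weights: relative abundances, or 1/richness over the
    occupied taxa for the unweighted variant."""
    if abundance_weighted:
        return mat / mat.sum(axis=1, keepdims=True)
    pres = (mat > 0).astype(float)
    return pres / pres.sum(axis=1, keepdims=True)


def _bmntd_from_arrays(weights: np.ndarray, supports: list[np.ndarray],
                       dist: np.ndarray) -> np.ndarray:
    """All-pairs betaMNTD given per-sample weights/supports and a taxon
    distance matrix.  For each sample k, dmin_k(i) is the distance from
    taxon i to its nearest neighbor among k's taxa; betaMNTD(j,k) averages
    the weighted dmin in both directions."""
    n = weights.shape[0]
    dmin = np.empty((n, dist.shape[0]))
    for k, idx in enumerate(supports):
        dmin[k] = dist[:, idx].min(axis=1)
    m = weights @ dmin.T
    return 0.5 * (m + m.T)


def beta_mntd_matrix(table: CommunityTable, phylogeny: Phylogeny,
                     abundance_weighted: bool = True) -> pd.DataFrame:
    """Observed betaMNTD for every sample pair."""
    mat = table.matrix
    if (mat.sum(axis=1) == 0).any():
        raise ValueError("betaMNTD undefined for all-zero samples")
    dist = phylogeny.patristic(table.taxon_ids).to_numpy()
    weights = _weights(mat, abundance_weighted)
    supports = [np.flatnonzero(row > 0) for row in mat]
    bm = _bmntd_from_arrays(weights, supports, dist)
    return pd.DataFrame(bm, index=table.data.index, columns=table.data.index)


def beta_mntd(table: CommunityTable, phylogeny: Phylogeny,
              pair: tuple[str, str], abundance_weighted: bool = True) -> float:
    """betaMNTD between one pair of samples."""
    sub = table.select_samples(list(pair))
    return float(beta_mntd_matrix(sub, phylogeny, abundance_weighted).iloc[0, 1])


@dataclass
class BntiResult:
    """Observed betaMNTD, null moments, and the betaNTI z-score per pair."""

    beta_mntd_obs: pd.DataFrame
    null_mean: pd.DataFrame
    null_sd: pd.DataFrame
    bnti: pd.DataFrame  # NaN where the null SD vanished
    n_undefined_pairs: int = 0


def bnti(table: CommunityTable, phylogeny: Phylogeny,
         config: NullModelConfig | None = None,
         permutations: list[np.ndarray] | None = None) -> BntiResult:
    """betaNTI for every pair: (betaMNTD_obs - mean_null) / sd_null.

    Each null replicate shuffles tip labels uniformly at random across all
    taxa of the aligned table (one shuffle shared by all pairs).  An
    explicit list of taxon ``permutations`` may be supplied instead of
    random shuffles, e.g. the full factorial for exhaustive enumeration.
    Pairs whose null SD vanishes (e.g. a star phylogeny) are flagged NaN.
    """
    config = config or NullModelConfig()
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples")
    mat = table.matrix
    dist = phylogeny.patristic(table.taxon_ids).to_numpy()
    weights = _weights(mat, config.abundance_weighted)
    supports = [np.flatnonzero(row > 0) for row in mat]
    obs = _bmntd_from_arrays(weights, supports, dist)

    if permutations is None:
        rng = np.random.default_rng(derive_seed(config.rng_seed, "bnti"))
        permutations = [rng.permutation(dist.shape[0]) for _ in range(config.n_null)]
    n_null = len(permutations)
    total = np.zeros_like(obs)
    total_sq = np.zeros_like(obs)
    for perm in permutations:
        null = _bmntd_from_arrays(weights, supports, dist[np.ix_(perm, perm)])
        total += null
        total_sq += null * null
    mean = total / n_null
    # sample SD over null replicates (ddof=1), guarded for n_null == 1
    var = (total_sq - n_null * mean ** 2) / max(n_null - 1, 1)
    sd = np.sqrt(np.maximum(var, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 1e-12, (obs - mean) / sd, np.nan)
    np.fill_diagonal(z, 0.0)
    ids = table.data.index
    n = table.n_samples
    undefined = int(np.isnan(z[np.triu_indices(n, k=1)]).sum())
    if undefined:
        logger.info("bnti: %d pairs undefined (null SD = 0)", undefined)
    wrap = lambda a: pd.DataFrame(a, index=ids, columns=ids)
    return BntiResult(wrap(obs), wrap(mean), wrap(sd), wrap(z), undefined)


# ---------------------------------------------------------------------------
# Raup-Crick on Bray-Curtis


def _pool_weights(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Regional-pool weights: occurrence frequency across samples, and summed
    within-sample relative abundance."""
    occ = (mat > 0).sum(axis=0).astype(float)
    rel = mat / mat.sum(axis=1, keepdims=True)
    ab = rel.sum(axis=0)
    return occ, ab


def sample_null_communities(rng: np.random.Generator, n_draws: int,
                            richness: int, total: int,
                            occ_weights: np.ndarray,
                            ab_weights: np.ndarray) -> np.ndarray:
    """Draw ``n_draws`` null communities of fixed richness and total count.

    Taxa are drawn without replacement with probability proportional to
    ``occ_weights`` (sequential weighted sampling via the Gumbel top-k
    trick); the ``total`` individuals are then distributed multinomially
    over the drawn taxa with probability proportional to ``ab_weights``
    renormalized over the drawn set.
    """
    n_taxa = occ_weights.size
    n_avail = int((occ_weights > 0).sum())
    if richness > n_avail:
        raise ValueError(
            f"sample richness {richness} exceeds regional pool size {n_avail}")
    with np.errstate(divide="ignore"):
        log_w = np.where(occ_weights > 0, np.log(occ_weights), -np.inf)
    keys = log_w + rng.gumbel(size=(n_draws, n_taxa))
    top = np.argpartition(-keys, richness - 1, axis=1)[:, :richness]
    probs = np.zeros((n_draws, n_taxa))
    rows = np.arange(n_draws)[:, None]
    probs[rows, top] = np.maximum(ab_weights[top], 1e-300)
    probs /= probs.sum(axis=1, keepdims=True)
    return rng.multinomial(total, probs)


def raup_crick_score(obs: float, nulls: np.ndarray, tol: float = 1e-12) -> float:
    """Rescale an observed dissimilarity against its null distribution to
    [-1, +1]: RC = 2*[(#(null < obs) + 0.5*#(null ~ obs)) / n] - 1."""
    nulls = np.asarray(nulls, dtype=float)
    less = int((nulls < obs - tol).sum())
    equal = int((np.abs(nulls - obs) <= tol).sum())
    return 2.0 * (less + 0.5 * equal) / nulls.size - 1.0


def rc_bray(table: CommunityTable, pair: tuple[str, str],
            config: NullModelConfig | None = None,
            pool: tuple[np.ndarray, np.ndarray] | None = None) -> float:
    """RCBray for one sample pair against the stochastic assembly null.

    The regional pool spans every taxon of ``table`` (which should already
    be restricted to the comparison group of interest); ``pool`` may
    override the (occurrence, abundance) weight vectors.  Requires integer
    (ideally rarefied) counts because the null distributes individuals.
    """
    config = config or NullModelConfig()
    if table.kind not in ("counts", "rarefied"):
        raise ValueError("rc_bray requires integer counts (kind=counts|rarefied)")
    mat = table.matrix
    idx = [table.sample_ids.index(s) for s in pair]
    x, y = mat[idx[0]], mat[idx[1]]
    if x.sum() == 0 or y.sum() == 0:
        raise ValueError("rc_bray undefined for all-zero samples")
    occ, ab = pool if pool is not None else _pool_weights(mat)
    obs = float(np.abs(x - y).sum() / (x + y).sum())
    rng = np.random.default_rng(
        derive_seed(config.rng_seed, "rc_bray", pair[0], pair[1]))
    null_x = sample_null_communities(
        rng, config.n_null, int((x > 0).sum()), int(x.sum()), occ, ab)
    null_y = sample_null_communities(
        rng, config.n_null, int((y > 0).sum()), int(y.sum()), occ, ab)
    null_bc = np.abs(null_x - null_y).sum(axis=1) / (null_x + null_y).sum(axis=1)
    return raup_crick_score(obs, null_bc, config.equality_tolerance)


# ---------------------------------------------------------------------------
# classification


def classify_pair(bnti_value: float, rc_value: float | None,
                  config: NullModelConfig | None = None) -> str:
    """Map a (betaNTI, RCBray) pair to one of the five assembly processes.

    Thresholds are strict inequalities; values exactly on a threshold fall
    through to the next test.  ``rc_value`` is only consulted (and then
    required) when |betaNTI| does not exceed its threshold.
    """
    config = config or NullModelConfig()
    if bnti_value is None or np.isnan(bnti_value):
        raise ValueError("betaNTI undefined; pair cannot be classified")
    if bnti_value < -config.bnti_threshold:
        return "homogeneous_selection"
    if bnti_value > config.bnti_threshold:
        return "heterogeneous_selection"
    if rc_value is None or np.isnan(rc_value):
        raise ValueError("RCBray required when |betaNTI| <= threshold")
    if rc_value > config.rc_threshold:
        return "dispersal_limitation"
    if rc_value < -config.rc_threshold:
        return "homogenizing_dispersal"
    return "undominated"


def classify_assembly(table: CommunityTable, phylogeny: Phylogeny,
                      config: NullModelConfig | None = None,
                      compute_all_rc: bool = False) -> pd.DataFrame:
    """Run the full two-step classifier over every sample pair.

    ``table`` must hold integer (rarefied) counts over the regional pool of
    interest; relative abundances for betaMNTD are derived internally.
    RCBray is only computed for pairs the selection step leaves unresolved,
    unless ``compute_all_rc`` is set.  Returns a long-format frame with one
    row per unordered pair: betaMNTD_obs, betaNTI, RCBray (NaN when not
    computed) and the process label ("undefined" when the betaNTI null SD
    vanished).
    """
    config = config or NullModelConfig()
    if table.kind not in ("counts", "rarefied"):
        raise ValueError("classify_assembly requires integer counts")
    rel = to_relative(table)
    bres = bnti(rel, phylogeny, config)
    pool = _pool_weights(table.matrix)
    ids = table.sample_ids
    rows = []
    for i, j in itertools.combinations(range(len(ids)), 2):
        si, sj = ids[i], ids[j]
        z = float(bres.bnti.iloc[i, j])
        rc = np.nan
        if np.isnan(z):
            process = "undefined"
        else:
            needs_rc = abs(z) <= config.bnti_threshold
            if needs_rc or compute_all_rc:
                rc = rc_bray(table, (si, sj), config, pool=pool)
            process = classify_pair(z, rc if needs_rc else None, config)
        rows.append({
            "sample_i": si, "sample_j": sj,
            "beta_mntd_obs": float(bres.beta_mntd_obs.iloc[i, j]),
            "bnti": z, "rc_bray": rc, "process": process,
        })
    return pd.DataFrame(rows)


def summarize_processes(pair_results: pd.DataFrame,
                        grouping: pd.Series | dict | None = None) -> pd.DataFrame:
    """Percentage of classified pairs per assembly process.

    Pairs with undefined betaNTI are excluded from the percentage
    denominator and reported in the ``n_undefined`` column.  ``grouping``
    optionally maps sample ids to groups; only within-group pairs are then
    summarized, one row per group (plus an "all" row).
    """
    if pair_results.empty:
        raise ValueError("no classified pairs to summarize")
    if grouping is not None:
        grouping = pd.Series(grouping)

    def _one(sub: pd.DataFrame, label: str) -> dict:
        defined = sub[sub["process"] != "undefined"]
        row = {"group": label, "n_pairs": len(defined),
               "n_undefined": int((sub["process"] == "undefined").sum())}
        counts = defined["process"].value_counts()
        for proc in PROCESSES:
            row[proc] = 100.0 * counts.get(proc, 0) / max(len(defined), 1)
        return row

    rows = [_one(pair_results, "all")]
    if grouping is not None:
        gi = pair_results["sample_i"].map(grouping)
        gj = pair_results["sample_j"].map(grouping)
        within = pair_results[gi == gj]
        for grp, sub in within.groupby(gi[gi == gj]):
            rows.append(_one(sub, str(grp)))
    return pd.DataFrame(rows)
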