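"""Synthetic metacommunities assembled under known ecological processes.

The generator is the test substrate for the whole pipeline: it produces a
Yule phylogeny, a Brownian niche trait with phylogenetic signal, a spatial
layout of plots along a riparian strip, soil chemistry with a planted
collinear block, and count tables assembled under one of five processes
(homogeneous/heterogeneous selection, dispersal limitation, homogenizing
dispersal, drift).  Selection acts through a single Brownian trait: a
sample's taxon weights are the regional-pool abundances filtered by a
Gaussian kernel around the site's environmental optimum, so phylogenetic
turnover carries the signal the betaNTI null model is designed to detect.
"""
from __future__ import annotations

import logging
import math
import random
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from dendropy.simulate import treesim
from skbio import TreeNode

from ._rng import derive_seed
from .io import CommunityTable, Phylogeny, SampleFrame

logger = logging.getLogger(__name__)

SCENARIOS = (
    "homogeneous_selection",
    "heterogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "drift",
)

#: the assembly process each scenario should be classified as
SCENARIO_EXPECTED_PROCESS = {
    "homogeneous_selection": "homogeneous_selection",
    "heterogeneous_selection": "heterogeneous_selection",
    "dispersal_limitation": "dispersal_limitation",
    "homogenizing_dispersal": "homogenizing_dispersal",
    "drift": "undominated",
}

#: plot types tiling the strip (8 plots: 3 monoculture, 3 mixed, 2 grass)
_PLOT_TYPE_CYCLE = ("monoculture", "mixed", "grass")

_BASE_CHEM = ("pH", "water_content", "total_C", "total_N", "exch_K",
              "exch_Ca", "olsen_P", "exch_Mg", "exch_Na")
_NUISANCE_CHEM = ("CEC", "EC", "NH4_N", "NO3_N", "total_S", "exch_Fe",
                  "exch_Mn")

__all__ = [
    "ScenarioConfig",
    "SyntheticDataset",
    "SCENARIOS",
    "SCENARIO_EXPECTED_PROCESS",
    "simulate_phylogeny",
    "evolve_trait",
    "assemble_communities",
    "simulate_study_dataset",
    "simulate_spatial_gradient",
    "simulate_functional_table",
]


@dataclass
class ScenarioConfig:
    """Parameters of one simulated assembly scenario.

    sigma_sel
        Gaussian niche width in units of the trait's across-tip standard
        deviation; small values mean strong environmental filtering.
    lambda_disp
        Dispersal-kernel decay length in meters (dispersal limitation).
    sigma_bm
        Brownian-motion rate of the niche trait per unit branch length.
    depth_log_mean / depth_log_sigma
        Lognormal parameters of per-sample sequencing depth, so rarefaction
        is nontrivial.
    n_shallow
        Samples whose depth is forced below 1000 reads to exercise the
        depth filter.
    """

    scenario: str = "homogeneous_selection"
    n_taxa: int = 2000
    n_samples: int = 24
    n_plots: int = 8
    extent: tuple[float, float] = (272.0, 30.0)
    sigma_sel: float = 0.15
    lambda_disp: float = 30.0
    sigma_bm: float = 1.0
    trait_rate_decay: float = 0.5
    sigma_drift: float = 1.0
    p_extinction: float = 0.6
    migration_rate: float = 0.1
    pool_lognormal_sigma: float = 2.0
    depth_log_mean: float = math.log(6000.0)
    depth_log_sigma: float = 0.5
    n_shallow: int = 0
    n_chem_nuisance: int = 7
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.n_samples < 4:
            raise ValueError("n_samples must be >= 4")
        for name in ("n_taxa", "sigma_sel", "lambda_disp", "sigma_bm",
                     "pool_lognormal_sigma", "depth_log_sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.sigma_drift < 0:
            raise ValueError("sigma_drift must be nonnegative")
        if not 0 <= self.migration_rate < 1:
            raise ValueError("migration_rate must be in [0, 1)")
        if not 0 <= self.p_extinction < 1:
            raise ValueError("p_extinction must be in [0, 1)")
        if self.trait_rate_decay < 0:
            raise ValueError("trait_rate_decay must be nonnegative")
        if not 0 <= self.n_chem_nuisance <= len(_NUISANCE_CHEM):
            raise ValueError("n_chem_nuisance out of range")


@dataclass
class SyntheticDataset:
    """Internally aligned community table, phylogeny, metadata, and truth."""

    table: CommunityTable
    phylogeny: Phylogeny
    frame: SampleFrame
    truth: dict = field(default_factory=dict)


def simulate_phylogeny(n_taxa: int, seed: int = 0) -> Phylogeny:
    """Pure-birth (Yule) ultrametric tree with unit birth rate; tips are
    labeled T0001, T0002, ..."""
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    tree = treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_taxa,
        rng=random.Random(derive_seed(seed, "yule")))
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"T{i + 1:04d}"
    newick = tree.as_string(schema="newick", suppress_rooting=True,
                            suppress_internal_node_labels=True)
    return Phylogeny(TreeNode.read([newick.strip()]))


def evolve_trait(phylogeny: Phylogeny, sigma_bm: float = 1.0,
                 root_value: float = 0.0, seed: int = 0,
                 rate_decay: float = 0.0) -> pd.Series:
    """Trait evolved along the tree by (optionally early-burst) Brownian motion.

    With ``rate_decay = 0`` this is plain Brownian motion: tip covariance
    equals sigma_bm^2 times the shared root-to-tip path length.  A positive
    ``rate_decay`` r shrinks the instantaneous rate as exp(-r t) with time
    from the root, concentrating divergence in deep branches.  That yields
    clade-conserved traits (niche conservatism): whole clades share similar
    values, which is the regime in which nearest-taxon turnover metrics
    carry a phylogenetic signal.
    """
    rng = np.random.default_rng(derive_seed(seed, "trait"))
    # per-node (value, depth); variance over a branch [d0, d1] integrates
    # the decayed rate: sigma^2 * (exp(-r d0) - exp(-r d1)) / r
    state: dict[int, tuple[float, float]] = {id(phylogeny.tree): (root_value, 0.0)}
    tips: dict[str, float] = {}
    for node in phylogeny.tree.preorder(include_self=False):
        length = node.length or 0.0
        val, d0 = state[id(node.parent)]
        if length > 0:
            if rate_decay > 0:
                var = (math.exp(-rate_decay * d0)
                       - math.exp(-rate_decay * (d0 + length))) / rate_decay
            else:
                var = length
            val = val + rng.normal(0.0, sigma_bm * math.sqrt(var))
        state[id(node)] = (val, d0 + length)
        if node.is_tip():
            tips[node.name] = val
    return pd.Series(tips, name="trait")


def _layout(config: ScenarioConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Plots tile the strip along x; samples are spread round-robin over the
    plots with uniform within-plot scatter."""
    width = config.extent[0] / config.n_plots
    rows = []
    for s in range(config.n_samples):
        plot = s % config.n_plots
        rows.append({
            "plot_id": plot + 1,
            "plot_type": _PLOT_TYPE_CYCLE[plot % len(_PLOT_TYPE_CYCLE)],
            "x": plot * width + rng.uniform(0.05, 0.95) * width,
            "y": rng.uniform(0.0, config.extent[1]),
        })
    frame = pd.DataFrame(rows, index=[f"S{s + 1:03d}"
                                      for s in range(config.n_samples)])
    frame["host_species"] = np.where(frame["plot_type"] == "grass",
                                     "grass", "focal_tree")
    return frame


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=1)
    return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)


def _log_pool_abundance(phylogeny: Phylogeny, taxa: list[str],
                        config: ScenarioConfig, seed: int) -> np.ndarray:
    """Lognormal regional-pool abundances.

    Under the selection scenarios, log abundance is a second, independent
    Brownian field on the same tree (standardized, scaled by
    ``pool_lognormal_sigma``): whole clades are coherently common or rare,
    as in surveys where abundance tracks conserved traits.  Clade-level
    coherence matters for the nearest-taxon machinery -- a taxon's close
    relatives must stand a realistic chance of being sampled in other
    communities.  Under the neutral scenarios (dispersal limitation,
    homogenizing dispersal, drift) abundances are i.i.d. lognormal:
    phylogenetically conserved abundance is itself a signature of selection
    and would contaminate scenarios meant to carry none.
    """
    if config.scenario in ("homogeneous_selection", "heterogeneous_selection"):
        pool_trait = evolve_trait(phylogeny, 1.0,
                                  seed=derive_seed(seed, "pool"),
                                  rate_decay=config.trait_rate_decay)
        field = _zscore(pool_trait.loc[taxa].to_numpy())
    else:
        rng = np.random.default_rng(derive_seed(seed, "pool"))
        field = rng.normal(size=len(taxa))
    return config.pool_lognormal_sigma * field


def _selection_kernel(env: np.ndarray, trait_z: np.ndarray,
                      log_pool: np.ndarray,
                      config: ScenarioConfig) -> np.ndarray:
    """Gaussian niche filtering of the pool around per-site optima."""
    return log_pool[None, :] - (trait_z[None, :] - env[:, None]) ** 2 \
        / (2 * config.sigma_sel ** 2)


def _clade_optima(phylogeny: Phylogeny, taxa: list[str], trait_z: np.ndarray,
                  n_bands: int = 3, cut_fraction: float = 0.25) -> np.ndarray:
    """Environmental optima for heterogeneous selection, anchored on clades.

    Contrasting environments select deeply divergent lineages: the tree is
    cut at ``cut_fraction`` of its depth, the ``n_bands`` largest resulting
    clades are taken as the locally adapted lineages, and each environment's
    optimum is its clade's mean niche trait.  Anchoring optima on real
    clades (rather than arbitrary trait values) guarantees that differently
    selected communities are phylogenetically, not just phenotypically,
    distinct.
    """
    index = {name: i for i, name in enumerate(taxa)}
    depths = {id(phylogeny.tree): 0.0}
    max_depth = 0.0
    for node in phylogeny.tree.preorder(include_self=False):
        d = depths[id(node.parent)] + (node.length or 0.0)
        depths[id(node)] = d
        if node.is_tip():
            max_depth = max(max_depth, d)
    cut = cut_fraction * max_depth
    clades = []
    stack = list(phylogeny.tree.children)
    while stack:
        node = stack.pop()
        if depths[id(node)] >= cut or node.is_tip():
            tips = [t.name for t in ([node] if node.is_tip() else node.tips())]
            idx = [index[t] for t in tips if t in index]
            if idx:
                clades.append(idx)
        else:
            stack.extend(node.children)
    big = [idx for idx in clades if len(idx) >= max(10, 0.03 * len(taxa))]
    if len(big) < n_bands:  # degenerate topology: fall back to quantiles
        qs = np.linspace(0.1, 0.9, n_bands)
        return np.quantile(trait_z, qs)
    means = np.sort(np.array([trait_z[idx].mean() for idx in big]))
    # most-contrasting clades: extremes plus evenly spaced interior means
    picks = np.linspace(0, len(means) - 1, n_bands).round().astype(int)
    return means[picks]


def _site_log_kernels(config: ScenarioConfig, layout: pd.DataFrame,
                      trait_z: np.ndarray, log_pool: np.ndarray,
                      phylogeny: Phylogeny, taxa: list[str],
                      rng: np.random.Generator
                      ) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """Scenario-specific deterministic log taxon weights per sample.

    Returns (log kernel, per-site environment, local-drift scale,
    migration flag).  Local drift -- random per-sample extinctions plus
    lognormal abundance fluctuations -- operates in every scenario; under
    homogenizing dispersal mass effects rescue local extinctions and damp
    the fluctuations (scale 0.1), and under pure drift the fluctuations are
    kept mild (scale 0.3) so drift expresses itself through taxon turnover
    rather than systematic abundance distortion.  Background immigration
    (the ``migration_rate`` pool admixture) applies to the selection
    scenarios; for the dispersal scenarios migration is the very process
    being modeled, so no extra admixture is layered on top.
    """
    n = config.n_samples
    x = layout["x"].to_numpy()
    env = np.zeros(n)
    if config.scenario == "homogeneous_selection":
        return _selection_kernel(env, trait_z, log_pool, config), env, 1.0, True
    if config.scenario == "heterogeneous_selection":
        # three contrasting clade-anchored optima in thirds along the strip,
        # so pairs that straddle environments (the heterogeneous-selection
        # signal) are the majority of all pairs
        band = np.digitize(x, [config.extent[0] / 3, 2 * config.extent[0] / 3])
        env = _clade_optima(phylogeny, taxa, trait_z)[band]
        # no pool admixture here: the cross-band contrast IS the signal, and
        # a scattered immigrant tail would hand every taxon a close relative
        # in the partner community
        return _selection_kernel(env, trait_z, log_pool, config), env, 1.0, False
    if config.scenario == "dispersal_limitation":
        homes = np.column_stack([
            rng.uniform(0, config.extent[0], trait_z.size),
            rng.uniform(0, config.extent[1], trait_z.size),
        ])
        sites = layout[["x", "y"]].to_numpy()
        d = np.linalg.norm(sites[:, None, :] - homes[None, :, :], axis=2)
        return log_pool[None, :] - d / config.lambda_disp, env, 1.0, False
    if config.scenario == "homogenizing_dispersal":
        # one realized regional draw shared by every site: the observable
        # signature of mass effects, without modeling explicit migration.
        # Mass effects also average abundances across sites, so the realized
        # metacommunity is flatter than the pool (exponent 0.5) with a broad
        # mid-occurrence tail.
        pool = np.exp(0.5 * (log_pool - log_pool.max()))
        pool /= pool.sum()
        shared = rng.multinomial(3 * config.n_taxa, pool).astype(float)
        shared = np.maximum(shared, 1e-12)
        return np.tile(np.log(shared), (n, 1)), env, 0.1, False
    # drift: every site samples the regional pool independently
    return np.tile(log_pool, (n, 1)), env, 0.3, False


def _apply_local_drift(log_kernel: np.ndarray, log_pool: np.ndarray,
                       config: ScenarioConfig, drift_scale: float,
                       migration: bool,
                       rng: np.random.Generator) -> np.ndarray:
    """Overlay local drift and background immigration on a log kernel.

    Drift has two components, both per sample and per taxon: random local
    extinction with probability ``p_extinction`` (a taxon simply failed to
    establish at that site) and lognormal abundance fluctuation of scale
    ``sigma_drift``.  When ``migration`` is set, the drifted community is
    mixed with a ``migration_rate`` share of the unfiltered regional pool
    -- the trickle of propagules arriving regardless of local fit, which
    spreads observed taxa over the whole tree.
    """
    shape = log_kernel.shape
    logw = log_kernel.copy()
    sd = config.sigma_drift * drift_scale
    if sd > 0:
        logw += rng.normal(0.0, sd, size=shape)
    q = config.p_extinction * drift_scale
    if q > 0:
        extinct = rng.random(shape) < q
        # never extirpate an entire sample
        empty = extinct.all(axis=1)
        extinct[empty] = False
        logw = np.where(extinct, -np.inf, logw)
    logw -= logw.max(axis=1, keepdims=True)
    p = np.exp(logw)
    p /= p.sum(axis=1, keepdims=True)
    if migration and config.migration_rate > 0:
        pool = np.exp(log_pool - log_pool.max())
        pool /= pool.sum()
        p = (1 - config.migration_rate) * p \
            + config.migration_rate * pool[None, :]
    return np.log(np.maximum(p, 1e-300))


def _chemistry(config: ScenarioConfig, layout: pd.DataFrame, env: np.ndarray,
               rng: np.random.Generator) -> tuple[pd.DataFrame, list[str]]:
    """Nine quasi-independent base variables (pH tracks the site environment,
    water content tracks position) plus a planted collinear block.

    Each nuisance variable loads 0.85 on one base variable (pairwise
    |r| ~ 0.85, safely above the 0.65 cutoff) plus 0.18 on every other base
    variable (|r| ~ 0.18 each, well below the cutoff).  The diffuse
    secondary loadings keep a nuisance variable's mean |r| well above its
    parent's at every stage of the greedy pruning (which drops the member
    of an offending pair with the larger mean correlation), so exactly the
    nuisance block is removed."""
    n = config.n_samples
    env_z = _zscore(env)
    x_z = _zscore(layout["x"].to_numpy())
    base = {}
    base["pH"] = 0.80 * env_z + 0.60 * rng.normal(size=n)
    base["water_content"] = 0.65 * x_z + 0.76 * rng.normal(size=n)
    for name in _BASE_CHEM[2:]:
        base[name] = rng.normal(size=n)
    chem = pd.DataFrame(base, index=layout.index)
    nuisance = list(_NUISANCE_CHEM[: config.n_chem_nuisance])
    base_z = np.column_stack([_zscore(chem[b].to_numpy()) for b in _BASE_CHEM])
    for k, name in enumerate(nuisance):
        others = base_z[:, [j for j in range(len(_BASE_CHEM)) if j != k]]
        chem[name] = (0.85 * base_z[:, k] + 0.18 * others.sum(axis=1)
                      + 0.17 * rng.normal(size=n))
    # shift/scale to loosely realistic units (affine; correlations unchanged)
    chem["pH"] = 5.6 + 0.4 * chem["pH"]
    chem["water_content"] = 35.0 + 6.0 * chem["water_content"]
    return chem, nuisance


def _draw_counts(config: ScenarioConfig, log_weights: np.ndarray,
                 rng: np.random.Generator) -> tuple[np.ndarray, list[int]]:
    n = config.n_samples
    depths = np.maximum(
        rng.lognormal(config.depth_log_mean, config.depth_log_sigma, n), 1200
    ).astype(np.int64)
    shallow_idx = sorted(rng.choice(n, size=config.n_shallow, replace=False)
                         .tolist()) if config.n_shallow else []
    for i in shallow_idx:
        depths[i] = rng.integers(200, 950)
    counts = np.empty((n, config.n_taxa), dtype=np.int64)
    for s in range(n):
        logw = log_weights[s] - log_weights[s].max()
        p = np.exp(logw)
        p /= p.sum()
        counts[s] = rng.multinomial(depths[s], p)
    return counts, shallow_idx


def assemble_communities(config: ScenarioConfig) -> SyntheticDataset:
    """Generate a full synthetic dataset under the configured scenario."""
    seed = config.rng_seed
    phylogeny = simulate_phylogeny(config.n_taxa, derive_seed(seed, "tree"))
    trait = evolve_trait(phylogeny, config.sigma_bm,
                         seed=derive_seed(seed, "bm"),
                         rate_decay=config.trait_rate_decay)
    taxa = sorted(phylogeny.taxa)
    trait_z = _zscore(trait.loc[taxa].to_numpy())

    rng = np.random.default_rng(derive_seed(seed, "assemble"))
    log_pool = _log_pool_abundance(phylogeny, taxa, config, seed)
    layout = _layout(config, rng)
    kernel, env, drift_scale, migration = _site_log_kernels(
        config, layout, trait_z, log_pool, phylogeny, taxa, rng)
    log_weights = _apply_local_drift(kernel, log_pool, config, drift_scale,
                                     migration, rng)
    counts, shallow_idx = _draw_counts(config, log_weights, rng)
    chem, nuisance = _chemistry(config, layout, env, rng)

    table = CommunityTable(
        pd.DataFrame(counts, index=layout.index, columns=taxa), kind="counts")
    frame_data = layout.join(chem)
    frame = SampleFrame(frame_data, tuple(chem.columns))
    truth = {
        "scenario": config.scenario,
        "expected_process": SCENARIO_EXPECTED_PROCESS[config.scenario],
        "seed": seed,
        "site_environment": {s: float(e) for s, e in zip(layout.index, env)},
        "shallow_samples": [layout.index[i] for i in shallow_idx],
        "nuisance_chemistry": nuisance,
        "params": {
            "n_taxa": config.n_taxa, "n_samples": config.n_samples,
            "sigma_sel": config.sigma_sel, "lambda_disp": config.lambda_disp,
            "sigma_bm": config.sigma_bm,
        },
    }
    return SyntheticDataset(table, phylogeny, frame, truth)


def simulate_study_dataset(seed: int = 0, n_taxa: int = 400,
                           n_samples: int = 64,
                           n_shallow: int = 3) -> SyntheticDataset:
    """Dataset with the structure of the field survey the pipeline targets:
    64 samples over 8 plots on a 272 m x 30 m strip, uneven lognormal
    depths with 3 planted shallow samples, and a 16-variable chemistry
    block of which 9 survive collinearity pruning."""
    config = ScenarioConfig(scenario="homogeneous_selection", n_taxa=n_taxa,
                            n_samples=n_samples, n_shallow=n_shallow,
                            rng_seed=seed)
    return assemble_communities(config)


def simulate_spatial_gradient(seed: int = 0, n_taxa: int = 200,
                              n_samples: int = 32,
                              sigma_sel: float = 0.5) -> SyntheticDataset:
    """Composition driven by a smooth environmental gradient along the strip.

    The site optimum is a deterministic function of the x coordinate and pH
    tracks it almost exactly, so the chemistry is spatially structured:
    environment and space then share most of the explainable community
    variation, the regime in which variance partitioning should put the
    bulk of explained variance into the shared fraction.  Local drift is
    kept mild so the gradient, not noise, dominates turnover.
    """
    config = ScenarioConfig(scenario="heterogeneous_selection", n_taxa=n_taxa,
                            n_samples=n_samples, sigma_sel=sigma_sel,
                            sigma_drift=0.5, p_extinction=0.3,
                            rng_seed=seed)
    phylogeny = simulate_phylogeny(config.n_taxa, derive_seed(seed, "tree"))
    trait = evolve_trait(phylogeny, config.sigma_bm,
                         seed=derive_seed(seed, "bm"),
                         rate_decay=config.trait_rate_decay)
    taxa = sorted(phylogeny.taxa)
    trait_z = _zscore(trait.loc[taxa].to_numpy())
    rng = np.random.default_rng(derive_seed(seed, "assemble"))
    log_pool = _log_pool_abundance(phylogeny, taxa, config, seed)
    layout = _layout(config, rng)
    x = layout["x"].to_numpy()
    env = 2.4 * (x / config.extent[0] - 0.5)  # smooth optimum along the strip
    kernel = _selection_kernel(env, trait_z, log_pool, config)
    logw = _apply_local_drift(kernel, log_pool, config, 1.0, True, rng)
    counts, _ = _draw_counts(config, logw, rng)
    chem, nuisance = _chemistry(config, layout, env, rng)
    # pH follows the gradient nearly deterministically here
    chem["pH"] = 5.6 + 0.4 * (_zscore(env) + 0.15 * rng.normal(size=len(env)))
    table = CommunityTable(
        pd.DataFrame(counts, index=layout.index, columns=taxa), kind="counts")
    frame = SampleFrame(layout.join(chem), tuple(chem.columns))
    truth = {"scenario": "spatial_gradient_selection",
             "nuisance_chemistry": nuisance, "seed": seed}
    return SyntheticDataset(table, phylogeny, frame, truth)


def simulate_functional_table(n_categories: int = 200, n_level1: int = 6,
                              enriched_per_group: int = 30,
                              effect_size: float = 3.0,
                              n_samples: int = 24, depth: int = 50000,
                              overdispersion: float = 2000.0,
                              seed: int = 0):
    """Dirichlet-multinomial functional-category counts with planted
    group-enriched categories.

    Samples split evenly into 'monoculture' and 'mixed' groups; for each
    group, ``enriched_per_group`` disjoint categories have their Dirichlet
    concentration multiplied by ``effect_size``.  Returns
    (CommunityTable counts, feature -> level-1 category map, group labels,
    truth dict).
    """
    if 2 * enriched_per_group > n_categories:
        raise ValueError("enriched_per_group too large for n_categories")
    rng = np.random.default_rng(derive_seed(seed, "functional"))
    features = [f"K{i + 1:05d}" for i in range(n_categories)]
    samples = [f"S{i + 1:03d}" for i in range(n_samples)]
    groups = pd.Series(["monoculture"] * (n_samples // 2)
                       + ["mixed"] * (n_samples - n_samples // 2),
                       index=samples, name="plot_type")
    base = rng.lognormal(0.0, 1.0, n_categories)
    base /= base.sum()
    chosen = rng.choice(n_categories, size=2 * enriched_per_group,
                        replace=False)
    enriched = {"monoculture": chosen[:enriched_per_group],
                "mixed": chosen[enriched_per_group:]}
    counts = np.empty((n_samples, n_categories), dtype=np.int64)
    for i, sid in enumerate(samples):
        alpha = base.copy()
        alpha[enriched[groups[sid]]] *= effect_size
        alpha = alpha / alpha.sum() * overdispersion
        p = rng.dirichlet(alpha)
        counts[i] = rng.multinomial(depth, p)
    table = CommunityTable(pd.DataFrame(counts, index=samples,
                                        columns=features), kind="counts")
    level1 = [f"L1_{rng.integers(1, n_level1 + 1):02d}"
              for _ in range(n_categories)]
    category_map = pd.Series(level1, index=features, name="level1")
    truth = {
        "enriched": {g: [features[i] for i in idx]
                     for g, idx in enriched.items()},
        "effect_size": effect_size,
    }
    return table, category_map, groups, truth
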