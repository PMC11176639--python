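"""End-to-end orchestration: preprocess -> diversity -> assembly nulls ->
multivariate stats -> variance partitioning -> indicators, with a
reproducibility manifest.

A single global seed deterministically derives per-stage seeds (hashes of
the stage name), so toggling one stage never shifts another stage's random
stream and a rerun with an identical config is bit-identical.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from ._rng import derive_seed
from .assembly import NullModelConfig, classify_assembly, summarize_processes
from .diversity import bray_curtis, euclidean, pcoa, shannon
from .indicator import indval
from .io import (align_inputs, read_community_table, read_phylogeny,
                 read_sample_frame, write_distance_matrix)
from .multivariate import distance_decay, distlm_forward, permanova, procrustes_test
from .preprocess import (PreprocessConfig, css_normalize, filter_low_depth,
                         prune_collinear, rarefy, to_relative)
from .spatial import build_dbmem, select_mems, varpart_env_space

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Paths, stage toggles, and sub-configurations of a pipeline run."""

    table_path: str
    tree_path: str
    frame_path: str
    output_dir: str
    seed: int = 0
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    null_model: NullModelConfig = field(default_factory=NullModelConfig)
    n_perm: int = 999
    run_assembly: bool = True
    run_multivar: bool = True
    run_varpart: bool = True
    run_indval: bool = True
    # the survey's assembly question concerns the planted plots only
    assembly_exclude_plot_types: tuple[str, ...] = ("grass",)
    indval_groups: str = "plot_type"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        pre = PreprocessConfig(**raw.pop("preprocess", {}))
        null = NullModelConfig(**raw.pop("null_model", {}))
        if "assembly_exclude_plot_types" in raw:
            raw["assembly_exclude_plot_types"] = tuple(
                raw["assembly_exclude_plot_types"])
        return cls(preprocess=pre, null_model=null, **raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["assembly_exclude_plot_types"] = list(
            self.assembly_exclude_plot_types)
        return d


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _write(df: pd.DataFrame, path: Path, **kwargs) -> None:
    df.to_csv(path, sep="\t", float_format="%.10g", **kwargs)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the toggled stages and return the manifest (also written to
    ``manifest.json`` in the output directory)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    from . import __version__ as _version
    manifest: dict = {
        "version": _version,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "stages": {},
        "outputs": [],
    }

    def _record(stage: str, **info) -> None:
        manifest["stages"][stage] = info

    def _emit(df: pd.DataFrame, name: str, **kwargs) -> None:
        _write(df, out / name, **kwargs)
        manifest["outputs"].append(name)

    try:
        table = read_community_table(config.table_path)
        tree = read_phylogeny(config.tree_path)
        frame = read_sample_frame(config.frame_path)
        table, tree, frame = align_inputs(table, tree, frame)
        _record("load", n_samples=table.n_samples, n_taxa=table.n_taxa)
    except Exception as exc:
        raise RuntimeError(f"stage 'load' failed: {exc}") from exc

    try:
        pre = config.preprocess
        filtered = filter_low_depth(table, pre.min_sample_reads)
        depth = min(pre.rarefaction_depth, int(filtered.row_sums().min()))
        rarefied = rarefy(filtered, depth,
                          seed=derive_seed(config.seed, "rarefy"))
        css = css_normalize(filtered, pre.css_quantile, pre.css_scale)
        frame_f = frame.select_samples(filtered.sample_ids)
        tree_f = tree.prune(filtered.taxon_ids)
        pruned_frame, colreport = prune_collinear(frame_f,
                                                  pre.collinearity_cutoff)
        _emit(colreport.as_frame(), "collinearity_report.tsv", index=False)
        _record("preprocess", n_samples=filtered.n_samples,
                n_taxa=filtered.n_taxa, rarefaction_depth=depth,
                chemistry_retained=list(pruned_frame.chemistry_vars))
    except Exception as exc:
        raise RuntimeError(f"stage 'preprocess' failed: {exc}") from exc

    try:
        alpha = shannon(rarefied)
        _emit(alpha.to_frame(), "shannon.tsv")
        bc = bray_curtis(css)
        write_distance_matrix(bc, out / "bray_curtis.tsv")
        manifest["outputs"].append("bray_curtis.tsv")
        _record("diversity", n_samples=len(bc.ids))
    except Exception as exc:
        raise RuntimeError(f"stage 'diversity' failed: {exc}") from exc

    if config.run_assembly:
        try:
            keep = [s for s in rarefied.sample_ids
                    if frame.data.loc[s, "plot_type"]
                    not in config.assembly_exclude_plot_types]
            sub = rarefied.select_samples(keep).drop_empty_taxa()
            null_cfg = NullModelConfig(
                **{**asdict(config.null_model),
                   "rng_seed": derive_seed(config.seed, "assembly")})
            pairs = classify_assembly(sub, tree_f.prune(sub.taxon_ids),
                                      null_cfg)
            grouping = frame.data.loc[keep, "plot_type"]
            summary = summarize_processes(pairs, grouping)
            _emit(pairs, "assembly_pairs.tsv", index=False)
            _emit(summary, "assembly_summary.tsv", index=False)
            _record("assembly", n_samples=len(keep), n_pairs=len(pairs))
        except Exception as exc:
            raise RuntimeError(f"stage 'assembly' failed: {exc}") from exc

    if config.run_multivar:
        try:
            seed = derive_seed(config.seed, "multivar")
            perm = permanova(bc, frame_f.data, ["plot_type", "plot_id"],
                             n_perm=config.n_perm, seed=seed)
            _emit(perm, "permanova.tsv", index=False)
            geo = euclidean(frame_f.data[["x", "y"]])
            env = euclidean(pruned_frame.chemistry(), standardize=True)
            decay_geo = distance_decay(bc, geo, n_perm=config.n_perm,
                                       seed=seed)
            decay_env = distance_decay(bc, env, n_perm=config.n_perm,
                                       seed=seed)
            decay = pd.DataFrame([
                {"distance": "geographic", **vars(decay_geo)},
                {"distance": "environmental", **vars(decay_env)},
            ])
            _emit(decay, "distance_decay.tsv", index=False)
            comm_ord = pcoa(bc)
            chem_ord = pcoa(env)
            proc = procrustes_test(chem_ord.samples.to_numpy(),
                                   comm_ord.samples.to_numpy(),
                                   n_perm=config.n_perm, seed=seed)
            _emit(pd.DataFrame([vars(proc)]), "procrustes.tsv", index=False)
            dlm = distlm_forward(bc, pruned_frame.chemistry(),
                                 n_perm=config.n_perm, seed=seed)
            _emit(dlm.selected, "distlm_selected.tsv", index=False)
            _emit(dlm.marginal, "distlm_marginal.tsv", index=False)
            _record("multivar", n_perm=config.n_perm)
        except Exception as exc:
            raise RuntimeError(f"stage 'multivar' failed: {exc}") from exc

    if config.run_varpart:
        try:
            seed = derive_seed(config.seed, "varpart")
            basis = build_dbmem(frame_f.data[["x", "y"]])
            selected = select_mems(basis, bc, n_perm=config.n_perm,
                                   alpha=0.05, seed=seed)
            vp = varpart_env_space(bc, pruned_frame.chemistry(), selected)
            row = {**vp.as_series().to_dict(), "r2adj_env": vp.r2adj_env,
                   "r2adj_space": vp.r2adj_space, "r2adj_both": vp.r2adj_both,
                   "mems": ",".join(vp.mem_names)}
            _emit(pd.DataFrame([row]), "varpart.tsv", index=False)
            _record("varpart", n_mems_built=basis.n_vectors,
                    n_mems_selected=selected.n_vectors)
        except Exception as exc:
            raise RuntimeError(f"stage 'varpart' failed: {exc}") from exc

    if config.run_indval:
        try:
            seed = derive_seed(config.seed, "indval")
            groups = frame_f.data[config.indval_groups]
            keep = groups.index[~groups.isin(["grass"])]
            sub = to_relative(
                filtered.select_samples(list(keep)).drop_empty_taxa())
            res = indval(sub, groups.loc[keep], n_perm=config.n_perm,
                         seed=seed)
            _emit(res.table, "indval.tsv", index=False)
            _record("indval", n_features=len(res.table),
                    n_significant=len(res.significant()))
        except Exception as exc:
            raise RuntimeError(f"stage 'indval' failed: {exc}") from exc

    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
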