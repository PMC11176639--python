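"""Input/output and cross-file alignment for community surveys.

Three coupled inputs drive every downstream analysis: a samples-by-taxa
abundance table, a rooted phylogeny with branch lengths over the table's
taxa, and a per-sample metadata frame (plot membership, coordinates, soil
chemistry).  This module reads and writes the plain-text formats for each
(wide or sparse-triplet TSV, newick, CSV), validates their invariants, and
reconciles them onto a shared, deterministically ordered sample/taxon set.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

logger = logging.getLogger(__name__)

KINDS = ("counts", "rarefied", "css", "relative")
PLOT_TYPES = ("monoculture", "mixed", "grass")

__all__ = [
    "CommunityTable",
    "Phylogeny",
    "SampleFrame",
    "FormatError",
    "read_community_table",
    "write_community_table",
    "read_phylogeny",
    "read_sample_frame",
    "write_sample_frame",
    "align_inputs",
    "read_distance_matrix",
    "write_distance_matrix",
]


class FormatError(ValueError):
    """Raised when an input file violates the format contract."""


def _check_unique(ids, what: str) -> None:
    ids = pd.Index(ids)
    if ids.has_duplicates:
        dupes = ids[ids.duplicated()].unique().tolist()
        raise FormatError(f"duplicate {what}: {dupes}")


@dataclass
class CommunityTable:
    """Samples-by-taxa abundance matrix with a normalization state flag.

    ``kind`` tracks what the values mean: raw ``counts``, ``rarefied``
    integer counts at even depth, ``css`` (cumulative-sum-scaled) values, or
    ``relative`` abundances whose rows sum to one.
    """

    data: pd.DataFrame
    kind: str = "counts"

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        _check_unique(self.data.index, "sample ids")
        _check_unique(self.data.columns, "taxon ids")
        values = self.data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise FormatError("non-finite abundance value")
        if (values < 0).any():
            raise FormatError("negative abundance value")
        if self.kind in ("counts", "rarefied"):
            if not np.allclose(values, np.rint(values), atol=1e-9):
                raise FormatError(f"kind={self.kind} requires integer values")
            self.data = self.data.round().astype(np.int64)
        if self.kind == "relative":
            sums = values.sum(axis=1)
            if (sums == 0).any():
                bad = self.data.index[sums == 0].tolist()
                raise FormatError(f"relative table has all-zero rows: {bad}")
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise FormatError("relative table rows must sum to 1")

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.index]

    @property
    def taxon_ids(self) -> list[str]:
        return [str(t) for t in self.data.columns]

    @property
    def matrix(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.data.shape[1]

    def select_samples(self, sample_ids) -> "CommunityTable":
        return replace(self, data=self.data.loc[list(sample_ids)])

    def select_taxa(self, taxon_ids) -> "CommunityTable":
        return replace(self, data=self.data.loc[:, list(taxon_ids)])

    def drop_empty_taxa(self) -> "CommunityTable":
        keep = self.data.sum(axis=0) > 0
        return replace(self, data=self.data.loc[:, keep])

    def row_sums(self) -> pd.Series:
        return self.data.sum(axis=1)


@dataclass
class Phylogeny:
    """Rooted tree with nonnegative branch lengths; supplies patristic distances."""

    tree: TreeNode
    _dist_cache: pd.DataFrame | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        tips = [t.name for t in self.tree.tips()]
        if any(name is None for name in tips):
            raise FormatError("tree has unlabeled tips")
        _check_unique(tips, "tip labels")
        for node in self.tree.traverse(include_self=False):
            if node.length is None:
                raise FormatError(
                    "tree has branches without lengths; branch lengths are "
                    "required for phylogenetic turnover"
                )
            if node.length < 0:
                raise FormatError(f"negative branch length on node {node.name!r}")
        if self.tree.length is None:
            self.tree.length = 0.0

    @property
    def taxa(self) -> list[str]:
        return [t.name for t in self.tree.tips()]

    def patristic(self, taxa: list[str] | None = None) -> pd.DataFrame:
        """Patristic (path-length) distance matrix over ``taxa`` (default: all tips)."""
        if self._dist_cache is None:
            dm = self.tree.tip_tip_distances()
            self._dist_cache = pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids)
        if taxa is None:
            return self._dist_cache
        missing = [t for t in taxa if t not in self._dist_cache.index]
        if missing:
            raise KeyError(f"taxa not in tree: {missing}")
        return self._dist_cache.loc[taxa, taxa]

    def prune(self, taxa) -> "Phylogeny":
        """Restrict the tree to ``taxa`` (patristic distances are preserved)."""
        taxa = list(taxa)
        tip_set = set(self.taxa)
        missing = sorted(set(taxa) - tip_set)
        if missing:
            raise KeyError(f"taxa not in tree: {missing}")
        if set(taxa) == tip_set:
            return self
        return Phylogeny(self.tree.shear(taxa))

    def write(self, path) -> None:
        self.tree.write(str(path), format="newick")


@dataclass
class SampleFrame:
    """Per-sample metadata: plot design, coordinates (m), soil chemistry."""

    data: pd.DataFrame
    chemistry_vars: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample ids")
        self.chemistry_vars = tuple(self.chemistry_vars)
        for col in ("x", "y"):
            if col not in self.data.columns:
                raise FormatError(f"sample frame missing coordinate column {col!r}")
            if not np.isfinite(self.data[col].to_numpy(dtype=float)).all():
                raise FormatError(f"non-finite coordinate in column {col!r}")
        for col in self.chemistry_vars:
            if col not in self.data.columns:
                raise FormatError(f"chemistry variable {col!r} not in frame")
            if not pd.api.types.is_numeric_dtype(self.data[col]):
                raise FormatError(f"chemistry variable {col!r} is non-numeric")

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.index]

    def chemistry(self) -> pd.DataFrame:
        return self.data.loc[:, list(self.chemistry_vars)]

    def coords(self) -> np.ndarray:
        return self.data[["x", "y"]].to_numpy(dtype=float)

    def missing_chemistry(self) -> list[str]:
        """Sample ids with any missing chemistry value (excluded from
        environmental analyses rather than imputed)."""
        chem = self.chemistry()
        if chem.empty:
            return []
        mask = chem.isna().any(axis=1)
        return [str(s) for s in chem.index[mask]]

    def select_samples(self, sample_ids) -> "SampleFrame":
        return SampleFrame(self.data.loc[list(sample_ids)].copy(), self.chemistry_vars)

    def drop_chemistry(self, variables) -> "SampleFrame":
        drop = set(variables)
        keep = tuple(v for v in self.chemistry_vars if v not in drop)
        return SampleFrame(self.data.drop(columns=list(drop)), keep)


def read_community_table(path, orientation: str = "samples", fmt: str | None = None,
                         kind: str = "counts") -> CommunityTable:
    """Read a wide TSV (header row + id column) or sparse triplet TSV.

    ``orientation`` declares what the wide file's rows are ("samples" or
    "taxa"); the returned table is always samples-as-rows.  Triplet files
    have columns (sample_id, taxon_id, value).
    """
    if orientation not in ("samples", "taxa"):
        raise ValueError("orientation must be 'samples' or 'taxa'")
    path = Path(path)
    if fmt is None:
        with open(path, "r", encoding="utf-8") as fh:
            header = [h.lower() for h in fh.readline().rstrip("\n").split("\t")]
        # sparse triplets announce themselves through their column names
        fmt = "triplet" if (
            len(header) == 3 and header[0].startswith("sample")
            and header[1].startswith("taxon")
        ) else "wide"
    if fmt == "triplet":
        df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
        if df.shape[1] != 3:
            raise FormatError("triplet table must have exactly 3 columns")
        df.columns = ["sample_id", "taxon_id", "value"]
        if df.duplicated(["sample_id", "taxon_id"]).any():
            raise FormatError("duplicate (sample, taxon) entries in triplet table")
        wide = df.pivot(index="sample_id", columns="taxon_id", values="value").fillna(0.0)
        wide = wide.sort_index(axis=0).sort_index(axis=1)
        return CommunityTable(wide, kind=kind)
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise FormatError(f"non-numeric cell in column {col!r}")
    if orientation == "taxa":
        _check_unique(df.index, "taxon ids")
        df = df.T
    return CommunityTable(df, kind=kind)


def _is_number(token: str) -> bool:
    try:
        float(token)
    except ValueError:
        return False
    return True


def write_community_table(table: CommunityTable, path) -> None:
    if table.kind in ("counts", "rarefied"):
        table.data.to_csv(path, sep="\t")
    else:
        table.data.to_csv(path, sep="\t", float_format="%.17g")


def read_phylogeny(path) -> Phylogeny:
    """Parse a rooted newick tree with branch lengths."""
    tree = TreeNode.read(str(path), format="newick")
    return Phylogeny(tree)


def read_sample_frame(path, chemistry_vars=None) -> SampleFrame:
    """Read sample metadata CSV.  Chemistry variables default to every
    numeric column other than the design/coordinate columns."""
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    if chemistry_vars is None:
        reserved = {"plot_id", "plot_type", "host_species", "x", "y"}
        chemistry_vars = [
            c for c in df.columns
            if c not in reserved and pd.api.types.is_numeric_dtype(df[c])
        ]
    return SampleFrame(df, tuple(chemistry_vars))


def write_sample_frame(frame: SampleFrame, path) -> None:
    frame.data.to_csv(path, float_format="%.17g")


def align_inputs(table: CommunityTable, tree: Phylogeny | None,
                 frame: SampleFrame) -> tuple[CommunityTable, Phylogeny | None, SampleFrame]:
    """Reconcile table, tree and metadata onto one sample/taxon universe.

    Samples are restricted to the table∩frame intersection and sorted
    lexicographically, as are taxa.  Tips absent from the table are pruned
    from the tree (logged); table taxa missing from the tree raise, because
    phylogenetic turnover is undefined for them.  Idempotent.
    """
    shared = sorted(set(table.sample_ids) & set(frame.sample_ids))
    if not shared:
        raise ValueError("no samples shared between table and sample frame")
    dropped_t = sorted(set(table.sample_ids) - set(shared))
    dropped_f = sorted(set(frame.sample_ids) - set(shared))
    if dropped_t:
        logger.info("align_inputs: dropping %d table-only samples: %s",
                    len(dropped_t), dropped_t)
    if dropped_f:
        logger.info("align_inputs: dropping %d frame-only samples: %s",
                    len(dropped_f), dropped_f)
    taxa = sorted(table.taxon_ids)
    table = table.select_samples(shared).select_taxa(taxa)
    frame = frame.select_samples(shared)
    if tree is not None:
        tip_set = set(tree.taxa)
        missing = sorted(set(taxa) - tip_set)
        if missing:
            raise KeyError(
                f"table taxa absent from the tree: {missing[:10]}"
                + ("..." if len(missing) > 10 else "")
            )
        extra = sorted(tip_set - set(taxa))
        if extra:
            logger.info("align_inputs: pruning %d tree-only tips", len(extra))
        tree = tree.prune(taxa)
    return table, tree, frame


def read_distance_matrix(path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(df.to_numpy(dtype=float), ids=[str(i) for i in df.index])


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(
        path, sep="\t", float_format="%.17g"
    )
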