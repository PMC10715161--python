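"""Readers, writers and table transforms at the pipeline boundary.

All feature tables are tab-delimited UTF-8 text with one header row of IDs
and an ID column; orientation is normalised to samples x taxa exactly once,
here. Trees are Newick. Metadata is a TSV with required columns
``sample_id``, ``season``, ``altitude_m`` plus optional host physiology.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import skbio

from .containers import AbundanceTable, ConfigError, FormatError, SchemaError

logger = logging.getLogger(__name__)

__all__ = [
    "read_feature_table",
    "write_feature_table",
    "aggregate_taxa",
    "rarefy",
    "to_relative",
    "read_tree",
    "cophenetic_matrix",
    "read_metadata",
    "derive_metadata",
    "write_metadata",
    "read_taxonomy",
    "HIGH_ALTITUDE_M",
    "RANKS",
]

#: samples strictly above this altitude (metres) are classed ``high``
HIGH_ALTITUDE_M = 3900.0

#: default lineage rank order for ';'-separated taxonomy strings
RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

_SEASONS = {"warm", "cold"}
_SEXES = {"F", "M", "unknown"}


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------

def read_feature_table(path, orientation: str = "samples_as_rows",
                       taxonomy=None) -> AbundanceTable:
    """Read a TSV feature table into a counts :class:`AbundanceTable`.

    ``orientation`` declares how the file is laid out; the returned table
    is always samples x taxa.
    """
    if orientation not in ("samples_as_rows", "taxa_as_rows"):
        raise ConfigError(f"unknown orientation {orientation!r}")
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    col_ids = header[1:]
    if len(set(col_ids)) != len(col_ids):
        dups = sorted({c for c in col_ids if col_ids.count(c) > 1})
        raise FormatError(f"{path.name}: duplicate column ids {dups} (line 1)")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, header=0)
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path.name}: ragged or malformed rows ({exc})") from exc
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].tolist()
        raise FormatError(f"{path.name}: duplicate row ids {dups}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~df.isna()
    if bad.to_numpy().any() or df.isna().to_numpy().any():
        mask = numeric.isna().to_numpy()
        r, c = np.argwhere(mask)[0]
        # +2: one header line, 1-based numbering
        raise FormatError(
            f"{path.name}: non-numeric cell at row id {df.index[r]!r}, "
            f"column {df.columns[c]!r} (line {r + 2})"
        )
    if orientation == "taxa_as_rows":
        numeric = numeric.T
    numeric.index.name = None
    numeric.columns.name = None
    return AbundanceTable(numeric, kind="counts", taxonomy=taxonomy)


def write_feature_table(table: AbundanceTable, path,
                        orientation: str = "samples_as_rows") -> None:
    """Write a table as TSV, mirroring :func:`read_feature_table` bit-exactly."""
    df = table.data if orientation == "samples_as_rows" else table.data.T
    df.to_csv(path, sep="\t", index_label="id")


def read_taxonomy(path) -> dict[str, str]:
    """Read a two-column TSV ``taxon_id<TAB>lineage`` into a dict."""
    df = pd.read_csv(path, sep="\t", index_col=0, header=0)
    return df.iloc[:, 0].astype(str).to_dict()


# ---------------------------------------------------------------------------
# taxonomy aggregation
# ---------------------------------------------------------------------------

_UNINFORMATIVE = {"", "norank", "unclassified", "unidentified", "uncultured", "na"}


def _rank_label(lineage: str, rank_idx: int) -> str:
    """Resolve the label of one lineage string at ``rank_idx``.

    Uninformative tokens (empty, 'norank', 'unclassified', ...) are pooled
    under the nearest informative ancestor, prefixed 'norank_' when the
    token said norank and 'unclassified_' otherwise — mirroring the naming
    convention of amplicon taxonomy tables (e.g. 'norank_Muribaculaceae').
    """
    tokens = [t.strip() for t in lineage.split(";")]
    token = tokens[rank_idx] if rank_idx < len(tokens) else ""
    if token.lower() not in _UNINFORMATIVE:
        return token
    prefix = "norank_" if token.lower() == "norank" else "unclassified_"
    for j in range(min(rank_idx, len(tokens)) - 1, -1, -1):
        anc = tokens[j]
        if anc.lower() not in _UNINFORMATIVE:
            return prefix + anc
    return prefix + "root"


def aggregate_taxa(table: AbundanceTable, rank: str = "genus",
                   ranks=RANKS) -> AbundanceTable:
    """Sum taxa sharing the same label at ``rank``; matrix total is conserved."""
    if table.taxonomy is None:
        raise ConfigError("aggregate_taxa requires a taxonomy map on the table")
    missing = [t for t in table.taxon_ids if t not in table.taxonomy]
    if missing:
        raise ConfigError(f"taxa missing from the taxonomy map: {missing[:5]}")
    if rank not in ranks:
        raise ConfigError(f"unknown rank {rank!r}; expected one of {list(ranks)}")
    rank_idx = list(ranks).index(rank)
    labels = [_rank_label(str(table.taxonomy[t]), rank_idx) for t in table.taxon_ids]
    grouped = table.data.T.groupby(pd.Index(labels, name=rank), sort=True).sum().T
    return AbundanceTable(grouped, kind=table.kind, taxonomy=None)


# ---------------------------------------------------------------------------
# rarefaction and normalisation
# ---------------------------------------------------------------------------

def rarefy(table: AbundanceTable, depth: int | None = None,
           seed: int = 0) -> AbundanceTable:
    """Subsample every sample without replacement to exactly ``depth`` reads.

    ``depth`` defaults to the minimum sample sum. Samples with fewer reads
    than ``depth`` are dropped with a logged warning. Reproducible for a
    fixed seed.
    """
    if table.kind != "counts":
        raise SchemaError("rarefy requires a counts table")
    counts = np.rint(table.values).astype(np.int64)
    sums = counts.sum(axis=1)
    if depth is None:
        depth = int(sums.min())
    depth = int(depth)
    if depth < 1:
        raise ConfigError(f"rarefaction depth must be >= 1, got {depth}")
    keep = sums >= depth
    if not keep.any():
        raise ConfigError(
            f"rarefaction depth {depth} exceeds every sample sum (max {sums.max()})"
        )
    dropped = [s for s, k in zip(table.sample_ids, keep) if not k]
    if dropped:
        logger.warning("rarefy: dropping %d samples below depth %d: %s",
                       len(dropped), depth, dropped)
    rng = np.random.default_rng(seed)
    out = np.empty((int(keep.sum()), counts.shape[1]), dtype=np.int64)
    row = 0
    for i in range(counts.shape[0]):
        if not keep[i]:
            continue
        if sums[i] == depth:
            out[row] = counts[i]
        else:
            out[row] = rng.multivariate_hypergeometric(counts[i], depth)
        row += 1
    df = pd.DataFrame(out, index=table.data.index[keep], columns=table.data.columns)
    return AbundanceTable(df, kind="counts", taxonomy=table.taxonomy)


def to_relative(table: AbundanceTable) -> AbundanceTable:
    """Divide each row by its sum. Idempotent; all-zero rows are an error."""
    sums = table.data.sum(axis=1)
    zero = sums[sums == 0]
    if len(zero):
        raise SchemaError(f"cannot normalise all-zero samples: {zero.index.tolist()}")
    rel = table.data.div(sums, axis=0)
    return AbundanceTable(rel, kind="relative", taxonomy=table.taxonomy)


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

def read_tree(path) -> skbio.TreeNode:
    """Read a Newick tree; missing branch lengths become 0 with a warning."""
    try:
        tree = skbio.TreeNode.read(str(path), format="newick")
    except Exception as exc:  # skbio raises several parser error types
        raise FormatError(f"unparseable Newick file {path}: {exc}") from exc
    tips = [t.name for t in tree.tips()]
    if len(set(tips)) != len(tips):
        dups = sorted({t for t in tips if tips.count(t) > 1})
        raise FormatError(f"duplicate tip labels in tree: {dups}")
    n_missing = 0
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
            n_missing += 1
        elif node.length < 0:
            raise FormatError(f"negative branch length at node {node.name!r}")
    if n_missing:
        warnings.warn(f"{n_missing} branches had no length; set to 0", stacklevel=2)
    if tree.length is None:
        tree.length = 0.0
    return tree


def cophenetic_matrix(tree: skbio.TreeNode) -> skbio.DistanceMatrix:
    """Tip-to-tip path-length (cophenetic) distances."""
    tips = [t.name for t in tree.tips()]
    if not tips and tree.name is not None:
        tips = [tree.name]  # a single-tip tree parses as a lone root
    if len(tips) == 1:
        return skbio.DistanceMatrix(np.zeros((1, 1)), ids=tips)
    return tree.tip_tip_distances()


# ---------------------------------------------------------------------------
# metadata
# ---------------------------------------------------------------------------

def derive_metadata(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a metadata frame and derive ``altitude_class`` / ``rmr_per_mass``.

    ``altitude_class`` is ``high`` iff altitude is strictly over
    :data:`HIGH_ALTITUDE_M` metres.
    """
    required = {"sample_id", "season", "altitude_m"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"metadata missing required columns: {sorted(missing)}")
    df = df.copy()
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise FormatError(f"duplicate sample ids in metadata: {dups}")
    bad_season = set(df["season"].astype(str)) - _SEASONS
    if bad_season:
        raise SchemaError(f"unknown season tokens: {sorted(bad_season)}")
    df["altitude_m"] = pd.to_numeric(df["altitude_m"])
    df["altitude_class"] = np.where(df["altitude_m"] > HIGH_ALTITUDE_M, "high", "low")
    if "sex" in df.columns:
        bad_sex = set(df["sex"].astype(str)) - _SEXES
        if bad_sex:
            raise SchemaError(f"unknown sex tokens: {sorted(bad_sex)}")
    if "rmr" in df.columns and "mass_g" in df.columns:
        rmr = pd.to_numeric(df["rmr"])
        mass = pd.to_numeric(df["mass_g"])
        df["rmr_per_mass"] = rmr / mass
    return df.set_index("sample_id", drop=False)


def read_metadata(path) -> pd.DataFrame:
    """Read the sample metadata TSV and derive the computed columns."""
    df = pd.read_csv(path, sep="\t", header=0, dtype={"sample_id": str})
    return derive_metadata(df)


def write_metadata(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
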