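"""Readers and writers for the standard flat-file formats.

* OTU tables: TSV, OTUs as rows and samples as columns, header row first;
  the first header cell may be the amplicon-pipeline token ``#OTU ID``.
* Trees: newick with branch lengths (scikit-bio ``TreeNode``).
* Sample metadata: TSV with ``sample_id`` plus either an ``environment``
  column or ``site`` + ``treatment`` columns (concatenated with "×").
* Matrices: square TSV with matching row/column ids.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from .containers import CommunityTable, DissimilarityMatrix, EnvironmentDesign

logger = logging.getLogger(__name__)

__all__ = [
    "read_community_table", "write_community_table",
    "read_tree", "write_tree", "validate_tree",
    "read_metadata", "write_metadata",
    "read_matrix", "write_matrix",
    "prune_to_shared_otus",
]


def read_community_table(path) -> CommunityTable:
    """Read an OTU × sample TSV count table.

    Raises
    ------
    ValueError
        On duplicate OTU/sample ids, or any cell that is not a
        nonnegative integer (the offending row and column are named).
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    samples = header[1:]
    if len(set(samples)) != len(samples):
        dups = sorted({s for s in samples if samples.count(s) > 1})
        raise ValueError(f"duplicate sample columns in {path.name}: {dups}")
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                      skip_blank_lines=True)
    raw.columns = samples
    if raw.index.has_duplicates:
        dups = raw.index[raw.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate OTU ids in {path.name}: {dups[:5]}")
    values = raw.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(values.isna().to_numpy())
    if bad.size:
        r, c = bad[0]
        raise ValueError(
            f"non-numeric count at OTU {raw.index[r]!r}, sample "
            f"{raw.columns[c]!r} in {path.name}: {raw.iat[r, c]!r}")
    arr = values.to_numpy(dtype=float)
    neg = np.argwhere(arr < 0)
    if neg.size:
        r, c = neg[0]
        raise ValueError(
            f"negative count at OTU {raw.index[r]!r}, sample "
            f"{raw.columns[c]!r} in {path.name}")
    frac = np.argwhere(arr != np.floor(arr))
    if frac.size:
        r, c = frac[0]
        raise ValueError(
            f"non-integer count at OTU {raw.index[r]!r}, sample "
            f"{raw.columns[c]!r} in {path.name}")
    return CommunityTable(values.astype(np.int64))


def write_community_table(table: CommunityTable, path) -> None:
    df = table.counts.copy()
    df.index.name = "#OTU ID"
    df.to_csv(path, sep="\t")


def validate_tree(tree: TreeNode) -> TreeNode:
    """Check tip labels and branch lengths; no silent defaults.

    Every tip must be named and unique; every non-root branch must carry
    an explicit nonnegative length.
    """
    names = []
    for tip in tree.tips():
        if tip.name is None or str(tip.name).strip() == "":
            raise ValueError("tree contains an unlabeled tip")
        names.append(str(tip.name))
    if len(set(names)) != len(names):
        dups = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate tip labels: {dups[:5]}")
    if len(names) < 2:
        raise ValueError("tree must have at least 2 tips")
    for node in tree.traverse(include_self=False):
        if node.length is None:
            who = node.name or "internal node"
            raise ValueError(f"branch without a length at {who!r}")
        if node.length < 0:
            raise ValueError("negative branch length")
    return tree


def read_tree(path) -> TreeNode:
    """Read and validate a rooted newick tree with branch lengths."""
    tree = TreeNode.read(str(path), format="newick")
    return validate_tree(tree)


def write_tree(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def read_metadata(path) -> EnvironmentDesign:
    """Read sample metadata TSV into an :class:`EnvironmentDesign`.

    Requires a ``sample_id`` column. The environment label is taken from
    an ``environment`` column if present, otherwise built as
    ``site × treatment``. Remaining numeric columns become covariates.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise ValueError("metadata must have a 'sample_id' column")
    df = df.set_index("sample_id")
    if "environment" not in df.columns:
        if {"site", "treatment"} <= set(df.columns):
            df["environment"] = (df["site"].astype(str) + "×"
                                 + df["treatment"].astype(str))
        else:
            raise ValueError(
                "metadata needs an 'environment' column or both "
                "'site' and 'treatment'")
    return EnvironmentDesign(df)


def write_metadata(design: EnvironmentDesign, path) -> None:
    df = design.frame.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def read_matrix(path) -> DissimilarityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return DissimilarityMatrix.from_frame(df)


def write_matrix(matrix: DissimilarityMatrix, path) -> None:
    matrix.to_frame().to_csv(path, sep="\t")


def prune_to_shared_otus(table: CommunityTable, tree: TreeNode,
                         prune_missing: bool = False):
    """Reconcile a table with a tree's tip set.

    OTUs absent from the tree are a hard error unless ``prune_missing``,
    in which case they are dropped from the table with a logged count
    (silent pruning would distort phylogenetic turnover). The tree is
    sheared to the table's OTUs when it carries extra tips.
    """
    tips = {t.name for t in tree.tips()}
    missing = [o for o in table.otu_ids if o not in tips]
    if missing:
        if not prune_missing:
            raise ValueError(
                f"{len(missing)} table OTUs are not tips of the tree "
                f"(first: {missing[:5]}); pass prune_missing=True to drop them")
        logger.warning("pruning %d OTUs absent from the tree", len(missing))
        keep = [o for o in table.otu_ids if o in tips]
        table = table.select_otus(keep)
    if tips - set(table.otu_ids):
        tree = tree.shear(table.otu_ids)
        tree.prune()
    return table, tree
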