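"""Ecological plumbing: rarefaction, α-diversity, proportions, Bray–Curtis."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import entropy

from .containers import CommunityTable, DissimilarityMatrix

logger = logging.getLogger(__name__)

__all__ = ["rarefy", "alpha_diversity", "relative_abundance", "bray_curtis"]


def rarefy(table: CommunityTable, depth: int, seed: int) -> CommunityTable:
    """Subsample every sample to ``depth`` reads without replacement.

    Each sample is drawn once from a multivariate hypergeometric (the
    exact law of subsampling reads without replacement). Samples with
    fewer than ``depth`` reads are dropped with a logged warning, never
    upsampled. Reproducible for a fixed ``seed``.
    """
    depth = int(depth)
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    rng = np.random.default_rng(seed)
    totals = table.sample_totals()
    keep = [s for s in table.sample_ids if totals[s] >= depth]
    dropped = [s for s in table.sample_ids if totals[s] < depth]
    if dropped:
        logger.warning("dropping %d samples shallower than depth %d: %s",
                       len(dropped), depth, dropped[:5])
    if not keep:
        raise ValueError(f"no sample has at least {depth} reads")
    out = {}
    counts = table.counts
    for s in keep:
        col = counts[s].to_numpy()
        if totals[s] == depth:
            out[s] = col
        else:
            out[s] = rng.multivariate_hypergeometric(col, depth)
    return CommunityTable(pd.DataFrame(out, index=counts.index))


def relative_abundance(table: CommunityTable) -> pd.DataFrame:
    """Per-sample proportions; every column sums to 1."""
    totals = table.sample_totals()
    empty = totals.index[totals == 0].tolist()
    if empty:
        raise ValueError(f"all-zero samples: {empty[:5]}")
    return table.counts / totals


def alpha_diversity(table: CommunityTable) -> pd.DataFrame:
    """Per-sample OTU richness and Shannon index.

    Richness counts OTUs with at least one read; Shannon is
    ``−Σ p ln p`` over nonzero proportions, reported in nats.
    """
    props = relative_abundance(table)
    richness = (table.counts > 0).sum(axis=0)
    shannon = pd.Series(entropy(props.to_numpy(), axis=0),
                        index=props.columns)
    return pd.DataFrame({"richness": richness.astype(int),
                         "shannon_nats": shannon})


def bray_curtis(table: CommunityTable) -> DissimilarityMatrix:
    """Pairwise Bray–Curtis dissimilarity on counts,
    ``BC(k,l) = Σ|x_ik − x_il| / Σ(x_ik + x_il)``, in [0, 1].
    """
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples")
    totals = table.sample_totals().to_numpy()
    if (totals == 0).sum() >= 2:
        raise ValueError("Bray-Curtis undefined between two all-zero samples")
    dm = squareform(pdist(table.matrix.T.astype(float), metric="braycurtis"))
    return DissimilarityMatrix(tuple(table.sample_ids), dm)
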