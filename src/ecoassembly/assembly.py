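"""Phylogenetic and taxonomic null models for community assembly.

The inference chain follows the established two-step null-model
framework for partitioning deterministic and stochastic assembly:

1. βMNTD — the abundance-weighted mean distance from each OTU in one
   community to its nearest phylogenetic neighbour in the other.
2. βNTI — the standardized effect size of βMNTD against a null in which
   tip labels are shuffled across the regional OTU pool. |βNTI| > 2
   marks selection: βNTI > +2 heterogeneous (divergent) selection,
   βNTI < −2 homogeneous selection.
3. RCbray — a Raup–Crick test on Bray–Curtis for the pairs selection
   cannot explain (|βNTI| ≤ 2): null communities preserve each sample's
   richness and total reads, drawing members with probability
   proportional to occupancy frequency and filling abundances from the
   metacommunity relative abundances. RCbray > +0.95 → dispersal
   limitation, RCbray < −0.95 → homogenizing dispersal, otherwise the
   turnover is undominated (weak selection, dispersal, drift mixed).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import TreeNode

from .containers import CommunityTable, DissimilarityMatrix, EnvironmentDesign
from .diversity import bray_curtis, relative_abundance
from .io import validate_tree

logger = logging.getLogger(__name__)

__all__ = [
    "PROCESS_LABELS", "ProcessSummary",
    "cophenetic_distances", "beta_mntd", "beta_mntd_matrix", "beta_nti",
    "raup_crick_bray", "raup_crick_score", "label_pairs",
    "partition_processes",
]

PROCESS_LABELS = (
    "heterogeneous_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "undominated",
)
DETERMINISTIC = PROCESS_LABELS[:2]
STOCHASTIC = PROCESS_LABELS[2:]


def cophenetic_distances(tree: TreeNode) -> DissimilarityMatrix:
    """Patristic (path-sum) distance between every pair of tips."""
    validate_tree(tree)
    dm = tree.tip_tip_distances()
    return DissimilarityMatrix(tuple(dm.ids), np.asarray(dm.data, dtype=float))


def _align_proportions(p, ids) -> np.ndarray:
    """Coerce a proportion vector onto the matrix id order."""
    if isinstance(p, pd.Series):
        extra = p.index.difference(ids)
        if len(extra):
            raise KeyError(f"OTUs absent from distance matrix: "
                           f"{list(extra[:5])}")
        vec = p.reindex(ids, fill_value=0.0).to_numpy(dtype=float)
    else:
        vec = np.asarray(p, dtype=float)
        if vec.shape != (len(ids),):
            raise ValueError("proportion vector length does not match matrix")
    if (vec < 0).any():
        raise ValueError("negative proportions")
    if vec.sum() == 0:
        raise ValueError("community has empty support")
    if abs(vec.sum() - 1.0) > 1e-8:
        raise ValueError("proportions must sum to 1")
    return vec


def beta_mntd(pk, pl, distances: DissimilarityMatrix) -> float:
    """Abundance-weighted β-mean nearest taxon distance between two
    communities given as proportion vectors over the matrix OTUs.

    βMNTD = 0.5·[Σ_i pk_i·min_{j∈l} d(i,j) + Σ_j pl_j·min_{i∈k} d(j,i)],
    minima over the other community's support; shared OTUs contribute 0.
    """
    ids = list(distances.ids)
    xk = _align_proportions(pk, ids)
    xl = _align_proportions(pl, ids)
    D = distances.values
    sk = np.flatnonzero(xk)
    sl = np.flatnonzero(xl)
    min_k_to_l = D[np.ix_(sk, sl)].min(axis=1)
    min_l_to_k = D[np.ix_(sl, sk)].min(axis=1)
    return 0.5 * (float(xk[sk] @ min_k_to_l) + float(xl[sl] @ min_l_to_k))


def _beta_mntd_all_pairs(P: np.ndarray, D: np.ndarray,
                         supports: list[np.ndarray]) -> np.ndarray:
    """βMNTD for all sample pairs at once.

    ``P`` is OTU × sample proportions, ``D`` the OTU distance matrix.
    mind[i, l] = min_{j in support(l)} D[i, j]; then
    A = Pᵀ·mind gives the one-directional sums and 0.5(A + Aᵀ) the
    symmetrized matrix.
    """
    n = P.shape[1]
    mind = np.empty((D.shape[0], n))
    for l in range(n):
        mind[:, l] = D[:, supports[l]].min(axis=1)
    A = P.T @ mind
    M = 0.5 * (A + A.T)
    np.fill_diagonal(M, 0.0)
    return M


def beta_mntd_matrix(table: CommunityTable,
                     distances: DissimilarityMatrix) -> DissimilarityMatrix:
    """βMNTD for every pair of samples in the table."""
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples")
    dm = distances.reindex(table.otu_ids)
    P = relative_abundance(table).to_numpy()
    supports = [np.flatnonzero(P[:, l]) for l in range(P.shape[1])]
    M = _beta_mntd_all_pairs(P, dm.values, supports)
    return DissimilarityMatrix(tuple(table.sample_ids), M)


def beta_nti(table: CommunityTable, distances: DissimilarityMatrix,
             n_null: int = 999, seed: int = 0) -> DissimilarityMatrix:
    """β nearest taxon index: z-score of observed βMNTD against a
    tip-shuffle null.

    Each null replicate applies one uniform permutation of tip labels
    across the full OTU pool of the table, shared by all sample pairs,
    and recomputes βMNTD. βNTI = (obs − mean_null)/sd_null with the
    sample (n−1) standard deviation. Pairs with a degenerate null
    (sd = 0) are reported as NaN with a warning.
    """
    n_null = int(n_null)
    if n_null < 2:
        raise ValueError("n_null must be >= 2")
    dm = distances.reindex(table.otu_ids)
    P = relative_abundance(table).to_numpy()
    supports = [np.flatnonzero(P[:, l]) for l in range(P.shape[1])]
    D = dm.values
    obs = _beta_mntd_all_pairs(P, D, supports)
    n = P.shape[1]
    rng = np.random.default_rng(seed)
    nulls = np.empty((n_null, n, n))
    S = D.shape[0]
    for b in range(n_null):
        perm = rng.permutation(S)
        Dp = D[np.ix_(perm, perm)]
        nulls[b] = _beta_mntd_all_pairs(P, Dp, supports)
    mean = nulls.mean(axis=0)
    sd = nulls.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (obs - mean) / sd
    np.fill_diagonal(z, 0.0)
    iu = np.triu_indices(n, k=1)
    degenerate = int(np.isnan(z[iu]).sum())
    if degenerate:
        logger.warning("βNTI undefined (null sd = 0) for %d sample pairs",
                       degenerate)
    return DissimilarityMatrix(tuple(table.sample_ids), z)


def raup_crick_score(bc_obs: float, bc_null: np.ndarray) -> float:
    """Rescale an observed Bray–Curtis value against its null sample.

    With ``n_less``/``n_equal`` the numbers of null values below/equal
    to the observation (ties get half weight),
    ``RC = ((n_less + 0.5·n_equal)/n_null − 0.5)·2`` ∈ [−1, 1].
    """
    bc_null = np.asarray(bc_null, dtype=float)
    n_null = bc_null.size
    if n_null == 0:
        raise ValueError("empty null sample")
    n_less = int((bc_null < bc_obs).sum())
    n_equal = int((bc_null == bc_obs).sum())
    return ((n_less + 0.5 * n_equal) / n_null - 0.5) * 2.0


def raup_crick_bray(table: CommunityTable, n_null: int = 999,
                    seed: int = 0) -> DissimilarityMatrix:
    """Bray–Curtis-based Raup–Crick index, rescaled to [−1, 1].

    For each sample pair, ``n_null`` pairs of null communities are
    built: each null community draws its observed richness of OTUs from
    the metacommunity pool with probability proportional to occupancy
    frequency (fraction of samples containing the OTU), then allocates
    its remaining reads multinomially with probability proportional to
    metacommunity relative abundance. With n_less/n_equal the counts of
    null Bray–Curtis values below/equal to the observed one,
    RCbray = ((n_less + 0.5·n_equal)/n_null − 0.5)·2.
    """
    n_null = int(n_null)
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    counts = table.matrix
    n = table.n_samples
    if n < 2:
        raise ValueError("need at least 2 samples")
    pool = np.flatnonzero(counts.sum(axis=1) > 0)
    S = len(pool)
    sub = counts[pool]
    occ_freq = (sub > 0).sum(axis=1) / n                 # membership weights
    meta_ab = sub.sum(axis=1) / sub.sum()                # abundance weights
    log_w = np.log(occ_freq)
    richness = (sub > 0).sum(axis=0)
    totals = sub.sum(axis=0)
    if (richness > S).any():
        raise ValueError("sample richness exceeds pool size")
    bc_obs = bray_curtis(table).values
    rng = np.random.default_rng(seed)

    def null_community(r: int, total: int) -> np.ndarray:
        if r == 0:
            return np.zeros((n_null, S), dtype=np.int64)
        # Gumbel top-k: weighted sampling of r members without replacement.
        keys = log_w[None, :] + rng.gumbel(size=(n_null, S))
        chosen = np.argpartition(-keys, r - 1, axis=1)[:, :r]
        pvals = meta_ab[chosen]
        pvals /= pvals.sum(axis=1, keepdims=True)
        fill = rng.multinomial(total - r, pvals) if total > r else \
            np.zeros((n_null, r), dtype=np.int64)
        out = np.zeros((n_null, S), dtype=np.int64)
        np.put_along_axis(out, chosen, fill + 1, axis=1)
        return out

    rc = np.zeros((n, n))
    for k, l in itertools.combinations(range(n), 2):
        null_k = null_community(int(richness[k]), int(totals[k]))
        null_l = null_community(int(richness[l]), int(totals[l]))
        denom = (null_k + null_l).sum(axis=1)
        bc_null = np.abs(null_k - null_l).sum(axis=1) / denom
        rc[k, l] = rc[l, k] = raup_crick_score(bc_obs[k, l], bc_null)
    return DissimilarityMatrix(tuple(table.sample_ids), rc)


def classify_pair(bnti: float, rc: float) -> str:
    """Five-way process label for one sample pair (strict thresholds)."""
    if np.isnan(bnti):
        raise ValueError("cannot label a pair with undefined βNTI")
    if bnti > 2.0:
        return "heterogeneous_selection"
    if bnti < -2.0:
        return "homogeneous_selection"
    if rc > 0.95:
        return "dispersal_limitation"
    if rc < -0.95:
        return "homogenizing_dispersal"
    return "undominated"


def label_pairs(bnti: DissimilarityMatrix,
                rc: DissimilarityMatrix) -> pd.DataFrame:
    """Per-pair βNTI, RCbray and process label (long format).

    Pairs with undefined βNTI are excluded with a logged count. RCbray
    is reported for every labelled pair but only consulted when
    |βNTI| ≤ 2.
    """
    if bnti.ids != rc.ids:
        rc = rc.reindex(bnti.ids)
    ids = list(bnti.ids)
    rows, skipped = [], 0
    for k, l in itertools.combinations(range(len(ids)), 2):
        z = bnti.values[k, l]
        r = rc.values[k, l]
        if np.isnan(z):
            skipped += 1
            continue
        rows.append({"sample_i": ids[k], "sample_j": ids[l],
                     "beta_nti": z, "rc_bray": r,
                     "process": classify_pair(z, r)})
    if skipped:
        logger.warning("excluded %d pairs with undefined βNTI", skipped)
    return pd.DataFrame(rows,
                        columns=["sample_i", "sample_j", "beta_nti",
                                 "rc_bray", "process"])


@dataclass(frozen=True)
class ProcessSummary:
    """Per-group fractions of the five assembly processes.

    ``fractions`` is indexed by group with one column per process label
    plus ``deterministic`` (the two selection labels) and ``stochastic``
    (the rest); ``pairs`` is the underlying per-pair table.
    """

    fractions: pd.DataFrame
    pairs: pd.DataFrame

    def __post_init__(self) -> None:
        total = self.fractions[list(PROCESS_LABELS)].sum(axis=1)
        if not np.allclose(total[self.fractions["n_pairs"] > 0], 1.0,
                           atol=1e-9):
            raise ValueError("process fractions must sum to 1")


def partition_processes(bnti: DissimilarityMatrix, rc: DissimilarityMatrix,
                        design: EnvironmentDesign,
                        grouping: str = "all") -> ProcessSummary:
    """Aggregate per-pair process labels into per-group fractions.

    ``grouping`` is ``"all"`` (every scored pair in one group) or a
    metadata column/key understood by
    :meth:`EnvironmentDesign.grouping` (e.g. ``"treatment"``,
    ``"site"``, ``"environment"``); a pair belongs to a group when both
    samples share that group value — cross-group pairs are dropped from
    grouped summaries.
    """
    pairs = label_pairs(bnti, rc)
    if grouping == "all":
        pairs = pairs.assign(group="all")
    else:
        key = design.grouping(grouping)
        gi = pairs["sample_i"].map(key)
        gj = pairs["sample_j"].map(key)
        if gi.isna().any() or gj.isna().any():
            raise KeyError("samples missing from metadata grouping")
        pairs = pairs.assign(group=gi.where(gi == gj))
        pairs = pairs.dropna(subset=["group"])
    rows = []
    for g, sub in pairs.groupby("group", sort=False):
        frac = sub["process"].value_counts(normalize=True)
        row = {"group": g, "n_pairs": len(sub)}
        for lab in PROCESS_LABELS:
            row[lab] = float(frac.get(lab, 0.0))
        row["deterministic"] = sum(row[lab] for lab in DETERMINISTIC)
        row["stochastic"] = sum(row[lab] for lab in STOCHASTIC)
        rows.append(row)
    fractions = pd.DataFrame(
        rows, columns=["group", "n_pairs", *PROCESS_LABELS,
                       "deterministic", "stochastic"]).set_index("group")
    return ProcessSummary(fractions=fractions, pairs=pairs)
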