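"""Phylogenetic signal in ecological niches via a Mantel correlogram.

The null-model framework for assembly inference is only interpretable
when close relatives have similar environmental niches. This module
computes abundance-weighted niche values per OTU from sample covariates
and tests, per phylogenetic-distance class, whether niche distance is
correlated with phylogenetic distance (a Mantel correlogram). The sign
convention follows the classical correlogram: a *positive* Mantel r in
a short-distance class means phylogenetically close OTUs are
ecologically similar (positive phylogenetic autocorrelation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .containers import CommunityTable, DissimilarityMatrix, EnvironmentDesign
from .diversity import relative_abundance

logger = logging.getLogger(__name__)

__all__ = ["CorrelogramResult", "otu_niche_values", "niche_distances",
           "mantel_correlogram"]


def otu_niche_values(table: CommunityTable, design: EnvironmentDesign,
                     covariates: list[str] | None = None) -> pd.DataFrame:
    """Abundance-weighted mean covariate value per OTU.

    Covariates are standardized to zero mean and unit variance across
    samples before weighting; the niche value of OTU j for covariate v
    is Σ_s p_js·v_s / Σ_s p_js with p_js the OTU's relative abundance in
    sample s. OTUs absent from every sample are excluded.
    """
    cov = design.covariates()
    if covariates is not None:
        missing = [c for c in covariates if c not in cov.columns]
        if missing:
            raise KeyError(f"unknown numeric covariates: {missing}")
        cov = cov[list(covariates)]
    if cov.shape[1] == 0:
        raise ValueError("metadata provides no numeric covariates")
    cov = cov.loc[table.sample_ids]
    sd = cov.std(axis=0, ddof=0)
    if (sd == 0).any():
        degenerate = sd.index[sd == 0].tolist()
        raise ValueError(f"constant covariates cannot carry niche "
                         f"information: {degenerate}")
    z = (cov - cov.mean(axis=0)) / sd
    P = relative_abundance(table)
    weight_sum = P.sum(axis=1)
    absent = weight_sum.index[weight_sum == 0]
    if len(absent):
        logger.warning("excluding %d OTUs absent from all samples", len(absent))
        P = P.drop(index=absent)
        weight_sum = weight_sum.drop(index=absent)
    W = P.div(weight_sum, axis=0)
    return W @ z


def niche_distances(niche_values: pd.DataFrame) -> DissimilarityMatrix:
    """Euclidean distance between OTU niche vectors."""
    dm = squareform(pdist(niche_values.to_numpy(dtype=float)))
    return DissimilarityMatrix(tuple(niche_values.index), dm)


@dataclass(frozen=True)
class CorrelogramResult:
    """Mantel correlogram over contiguous phylogenetic-distance classes.

    ``classes`` has one row per class: bounds, pair count, Mantel r,
    permutation p-value and the significance flag after progressive
    Bonferroni correction. Classes without pairs (or with a constant
    indicator) are flagged untested.
    """

    classes: pd.DataFrame
    n_perm: int
    seed: int
    alpha: float

    def significant_positive(self, first_k: int = 3) -> bool:
        """True if any of the first ``first_k`` tested classes shows a
        significant positive Mantel r (the short-distance signal the
        assembly framework requires)."""
        tested = self.classes[self.classes["tested"]].head(first_k)
        return bool(((tested["mantel_r"] > 0)
                     & tested["significant"]).any())


def mantel_correlogram(niche_dist: DissimilarityMatrix,
                       phylo_dist: DissimilarityMatrix,
                       n_classes: int = 50, n_perm: int = 999,
                       seed: int = 0, alpha: float = 0.05,
                       min_class_pairs: int = 5) -> CorrelogramResult:
    """Mantel correlogram of niche distance against phylogenetic distance.

    Phylogenetic distances are binned into ``n_classes`` equal-width
    classes covering (0, max]. Per class, the Mantel statistic is the
    Pearson correlation between the niche-distance vector and the
    class-membership indicator, sign-flipped so that positive values
    mean ecological similarity within the class. Significance is a
    two-sided permutation test (rows/columns of the niche matrix
    permuted jointly, +1-corrected p) with progressive Bonferroni
    correction: the k-th tested class is compared against alpha/k, and
    the correlogram is read sequentially from the shortest distances
    outward — once a class fails its threshold, later classes are not
    declared significant (they keep their raw p-values). This is the
    sequential interpretation the progressive correction is built for,
    and it keeps the familywise error of the whole correlogram near
    ``alpha``.
    """
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    phylo = phylo_dist.reindex(niche_dist.ids)
    n = len(niche_dist.ids)
    iu = np.triu_indices(n, k=1)
    dvec = phylo.values[iu]
    dmax = dvec.max()
    if dmax <= 0:
        raise ValueError("phylogenetic distances are all zero")
    edges = np.linspace(0.0, dmax, n_classes + 1)
    which = np.clip(np.searchsorted(edges, dvec, side="left") - 1,
                    0, n_classes - 1)
    which[dvec <= 0] = -1  # zero distances fall outside (0, max]

    n_pairs = len(dvec)
    masks, tested_idx = [], []
    for c in range(n_classes):
        mask = which == c
        cnt = int(mask.sum())
        # a Mantel statistic over a handful of pairs is meaningless and
        # would needlessly break the sequential reading of the correlogram
        if cnt < min_class_pairs or cnt == n_pairs:
            masks.append(None)
        else:
            masks.append(mask)
            tested_idx.append(c)
    if not tested_idx:
        raise ValueError("no usable distance classes")

    Z = np.column_stack([masks[c].astype(float) for c in tested_idx])
    Z -= Z.mean(axis=0)
    Z /= Z.std(axis=0)

    def mantel_r(values: np.ndarray) -> np.ndarray:
        v = values[iu]
        sd = v.std()
        if sd == 0:
            return np.zeros(Z.shape[1])
        zv = (v - v.mean()) / sd
        return -(zv @ Z) / n_pairs

    r_obs = mantel_r(niche_dist.values)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(Z.shape[1])
    for _ in range(int(n_perm)):
        perm = rng.permutation(n)
        r_perm = mantel_r(niche_dist.values[np.ix_(perm, perm)])
        exceed += np.abs(r_perm) >= np.abs(r_obs)
    pvals = (1.0 + exceed) / (n_perm + 1.0)

    rows = []
    rank = 0
    chain_alive = True
    p_iter = iter(zip(r_obs, pvals))
    for c in range(n_classes):
        row = {"class_index": c + 1, "lower": edges[c], "upper": edges[c + 1],
               "n_pairs": int(masks[c].sum()) if masks[c] is not None
               else int((which == c).sum())}
        if masks[c] is None:
            row.update({"tested": False, "mantel_r": np.nan,
                        "p_value": np.nan, "significant": False})
        else:
            r, p = next(p_iter)
            rank += 1
            passed = chain_alive and p <= alpha / rank
            chain_alive = chain_alive and passed
            row.update({"tested": True, "mantel_r": float(r),
                        "p_value": float(p), "significant": bool(passed)})
        rows.append(row)
    classes = pd.DataFrame(rows, columns=["class_index", "lower", "upper",
                                          "n_pairs", "tested", "mantel_r",
                                          "p_value", "significant"])
    return CorrelogramResult(classes=classes, n_perm=int(n_perm),
                             seed=int(seed), alpha=float(alpha))
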