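"""Generalist/specialist classification from the species–environment map.

An OTU's *occupancy* is the number of environments (site × treatment
cells) where it is detected. The observed count of OTUs in each
occupancy class is compared against a permutation null in which every
environment independently receives a uniform random subset of the OTU
pool of the same size as its observed richness. Occupancy classes whose
observed counts are enriched over the null define specialists (low
occupancy) and generalists (high occupancy); everything else is a
common taxon. Levins' niche breadth B = 1/Σ P² provides an independent
continuous check on the dichotomy: B = 1 for a fully specialized OTU
and B = E for one spread uniformly over E environments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CommunityTable, EnvironmentDesign

logger = logging.getLogger(__name__)

__all__ = [
    "OccupancyProfile", "OccupancyNull", "NicheClassification",
    "occupancy_counts", "occupancy_null", "classify_taxa",
    "levins_niche_breadth", "group_summary",
]

LABELS = ("generalist", "specialist", "common")


def _presence_by_environment(table: CommunityTable,
                             design: EnvironmentDesign) -> pd.DataFrame:
    """Boolean OTU × environment presence (≥1 read in ≥1 sample)."""
    env = design.environment_of(table.sample_ids)  # raises on unmapped sample
    present = table.counts > 0
    byenv = present.T.groupby(env).any().T
    return byenv.reindex(columns=design.environments, fill_value=False)


@dataclass(frozen=True)
class OccupancyProfile:
    """Observed occupancy per OTU and OTU richness per environment."""

    occupancy: pd.Series          # per OTU, 0..E (0 = absent everywhere)
    env_richness: pd.Series       # per environment
    n_environments: int

    def class_counts(self) -> pd.Series:
        """Number of OTUs per occupancy class 1..E (absent OTUs excluded)."""
        occ = self.occupancy[self.occupancy > 0]
        return occ.value_counts().reindex(
            range(1, self.n_environments + 1), fill_value=0).sort_index()


@dataclass(frozen=True)
class OccupancyNull:
    """Null distribution of occupancy-class counts.

    ``class_counts[b, c-1]`` is the number of OTUs with occupancy c in
    permutation b; each permutation preserves per-environment richness.
    """

    class_counts: np.ndarray
    n_perm: int
    seed: int
    n_environments: int = field(init=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.class_counts)
        if arr.shape[0] != self.n_perm:
            raise ValueError("class_counts rows must equal n_perm")
        object.__setattr__(self, "class_counts", arr)
        object.__setattr__(self, "n_environments", arr.shape[1])


@dataclass(frozen=True)
class NicheClassification:
    """Per-OTU occupancy + label, and the per-class enrichment test."""

    per_otu: pd.DataFrame         # columns: occupancy, label
    class_pvalues: pd.Series      # empirical one-sided p per class 1..E
    enriched: pd.Series           # bool per class 1..E
    specialist_max: int
    generalist_min: int
    alpha: float

    def labels(self) -> pd.Series:
        return self.per_otu["label"]


def occupancy_counts(table: CommunityTable,
                     design: EnvironmentDesign) -> OccupancyProfile:
    """Observed occupancies; presence is ≥1 read in ≥1 sample of the
    environment (apply after rarefaction so detection effort is equal)."""
    if design.n_environments < 2:
        logger.warning("occupancy analysis with a single environment is "
                       "degenerate: every present OTU has occupancy 1")
    presence = _presence_by_environment(table, design)
    return OccupancyProfile(
        occupancy=presence.sum(axis=1).astype(int),
        env_richness=presence.sum(axis=0).astype(int),
        n_environments=design.n_environments,
    )


def occupancy_null(table: CommunityTable, design: EnvironmentDesign,
                   n_perm: int, seed: int,
                   _block: int = 512) -> OccupancyNull:
    """Permutation null on the species–environment association map.

    For each permutation, every environment independently receives a
    uniform random subset of the global OTU pool with the same size as
    its observed richness; occupancy-class counts are recorded.
    """
    n_perm = int(n_perm)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    profile = occupancy_counts(table, design)
    pool = table.n_otus
    richness = profile.env_richness.to_numpy()
    if (richness > pool).any():
        raise ValueError("environment richness exceeds OTU pool size")
    env_count = profile.n_environments
    rng = np.random.default_rng(seed)
    out = np.empty((n_perm, env_count), dtype=np.int64)
    done = 0
    while done < n_perm:
        b = min(_block, n_perm - done)
        occ = np.zeros((b, pool), dtype=np.int16)
        rows = np.arange(b)[:, None]
        for r in richness:
            if r == 0:
                continue
            keys = rng.random((b, pool))
            chosen = np.argpartition(keys, r - 1, axis=1)[:, :r]
            occ[rows, chosen] += 1
        for c in range(1, env_count + 1):
            out[done:done + b, c - 1] = (occ == c).sum(axis=1)
        done += b
    return OccupancyNull(class_counts=out, n_perm=n_perm, seed=seed)


def classify_taxa(profile: OccupancyProfile, null: OccupancyNull,
                  specialist_max: int = 1, generalist_min: int = 6,
                  alpha: float = 0.05) -> NicheClassification:
    """Label OTUs from the per-class enrichment test.

    A class c is enriched when the empirical one-sided p-value
    ``(1 + #{null count_c ≥ observed count_c}) / (n_perm + 1)`` is ≤
    ``alpha``. OTUs in enriched classes at or below ``specialist_max``
    are specialists; in enriched classes at or above ``generalist_min``,
    generalists; all other present OTUs are common taxa.
    """
    if specialist_max >= generalist_min:
        raise ValueError("specialist_max must be < generalist_min")
    if profile.n_environments != null.n_environments:
        raise ValueError("profile and null disagree on environment count")
    observed = profile.class_counts()
    exceed = (null.class_counts >= observed.to_numpy()[None, :]).sum(axis=0)
    pvals = pd.Series((1.0 + exceed) / (null.n_perm + 1.0),
                      index=observed.index, name="p_enrichment")
    enriched = pvals <= alpha

    occ = profile.occupancy[profile.occupancy > 0]
    labels = pd.Series("common", index=occ.index, name="label")
    occ_enriched = occ.map(lambda c: bool(enriched.loc[c]))
    labels[(occ <= specialist_max) & occ_enriched] = "specialist"
    labels[(occ >= generalist_min) & occ_enriched] = "generalist"
    per_otu = pd.DataFrame({"occupancy": occ, "label": labels})
    return NicheClassification(per_otu=per_otu, class_pvalues=pvals,
                               enriched=enriched,
                               specialist_max=specialist_max,
                               generalist_min=generalist_min, alpha=alpha)


def levins_niche_breadth(table: CommunityTable,
                         design: EnvironmentDesign) -> pd.Series:
    """Levins' B_j = 1 / Σ_i P_ij² with P_ij the share of OTU j's reads
    found in environment i (Σ_i P_ij = 1), so 1 ≤ B_j ≤ E.

    OTUs with zero total are excluded with a warning.
    """
    env = design.environment_of(table.sample_ids)
    env_abund = table.counts.T.groupby(env).sum().T  # OTU × environment
    totals = env_abund.sum(axis=1)
    zero = totals.index[totals == 0]
    if len(zero):
        logger.warning("excluding %d OTUs with zero total from niche "
                       "breadth", len(zero))
        env_abund = env_abund.drop(index=zero)
        totals = totals.drop(index=zero)
    p = env_abund.div(totals, axis=0)
    breadth = 1.0 / (p ** 2).sum(axis=1)
    breadth.name = "niche_breadth"
    return breadth


def group_summary(classification: NicheClassification, table: CommunityTable,
                  design: EnvironmentDesign, by: str | None = None
                  ) -> pd.DataFrame:
    """Counts and percentages of OTUs and reads per label, overall and per
    group (default grouping: metadata 'treatment' if present, else
    'environment'). Percentages within a group sum to 100 over the three
    labels.
    """
    if by is None:
        by = "treatment" if "treatment" in design.frame.columns else "environment"
    groups = {"metacommunity": table.sample_ids}
    keys = design.grouping(by).loc[table.sample_ids]
    for g in dict.fromkeys(keys):
        groups[g] = list(keys.index[keys == g])
    labels = classification.labels()
    rows = []
    for gname, samples in groups.items():
        sub = table.counts[samples]
        present = sub.sum(axis=1) > 0
        present_ids = present.index[present].intersection(labels.index)
        n_otus_total = len(present_ids)
        n_seq_total = int(sub.loc[present_ids].to_numpy().sum())
        for lab in LABELS:
            ids = present_ids[labels.loc[present_ids] == lab]
            n_seq = int(sub.loc[ids].to_numpy().sum())
            rows.append({
                "group": gname, "label": lab,
                "n_otus": len(ids),
                "pct_otus": 100.0 * len(ids) / n_otus_total if n_otus_total else 0.0,
                "n_sequences": n_seq,
                "pct_sequences": 100.0 * n_seq / n_seq_total if n_seq_total else 0.0,
            })
    return pd.DataFrame(rows)
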