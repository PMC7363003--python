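"""Synthetic communities with known assembly processes.

The generator builds (i) a pure-birth (Yule) phylogeny, (ii)
phylogenetically conserved niche traits, and (iii) OTU count tables
assembled under one of five known processes, so every inference stage
can be validated against ground truth:

* ``heterogeneous_selection`` — environments with different niche
  optima; Gaussian selection weights
  ``w = exp(−‖trait − optimum‖²/(2σ_w²))`` filter the metacommunity
  differently per environment.
* ``homogeneous_selection`` — the same optimum everywhere: strong,
  uniform filtering.
* ``neutral`` — no filtering; every sample is a multinomial draw from
  the metacommunity, thinned by a colonization lottery.
* ``dispersal_limitation`` — the OTU pool is split into one disjoint
  subset per environment; samples draw from their subset, mixed with a
  fraction ``m`` of the global pool.
* ``homogenizing_dispersal`` — all samples are deep multinomial draws
  from one shared composition (near-identical replicates).

Niche traits for the selection scenarios follow a multivariate
early-burst Brownian process (rate decaying toward the present), which
concentrates trait variance on deep branches. This makes niches
strongly phylogenetically conserved — the regime the selection
scenarios are meant to probe — and, in several trait dimensions,
prevents chance trait convergence between distant clades. By default
each environment's optimum is anchored to the trait centroid of a real
mid-sized clade (the most phylogenetically compact one whose trait
centroid is well separated from the rest of the pool), so "selection
toward an optimum" always targets a populated region of niche space
regardless of the random tree realization. Passing explicit
``env_values`` instead applies scalar optima to a one-dimensional
trait.

Read sampling is multinomial throughout, matching the rarefied-count
semantics of the downstream analysis. Local ecological drift between
replicate samples has two knobs: a colonization lottery (each OTU
enters a given sample with probability ``retain_prob``) and an optional
lognormal abundance jitter (``drift_sd``); both are disabled for
``homogenizing_dispersal``, which by definition erases local drift.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from .containers import CommunityTable, EnvironmentDesign
from . import io as eio

logger = logging.getLogger(__name__)

__all__ = ["PROCESSES", "ScenarioConfig", "SyntheticDataset",
           "simulate_tree", "simulate_traits_bm", "simulate_niche_traits",
           "simulate_communities", "make_dataset", "make_scenario",
           "default_scenario", "planted_niche_table"]

PROCESSES = ("heterogeneous_selection", "homogeneous_selection", "neutral",
             "dispersal_limitation", "homogenizing_dispersal")
SELECTION_PROCESSES = PROCESSES[:2]

# sd of the measurement noise added to the environmental covariates
# written into sample metadata (standardized trait units)
_COVARIATE_NOISE_SD = 0.05


@dataclass(frozen=True)
class ScenarioConfig:
    """Knobs of one synthetic scenario.

    ``selection_width`` scales σ_w: it is the width in trait units when
    ``env_values`` are given explicitly, and a multiplier on the
    anchor clade's trait radius in the default clade-anchored mode.
    ``bm_rate`` (σ²_BM, trait² per branch-length unit) scales the trait
    process. ``migration_rate`` m ∈ [0, 1] mixes the global pool into
    dispersal-limited local pools. ``lognormal_sd`` shapes the
    metacommunity species-abundance distribution.
    """

    process: str
    n_otus: int = 150
    n_environments: int = 2
    samples_per_environment: int = 6
    reads_per_sample: int = 5000
    tree_seed: int = 11
    community_seed: int = 12
    selection_width: float = 1.0
    bm_rate: float = 1.0
    env_values: tuple | None = None
    migration_rate: float = 0.0
    lognormal_sd: float = 2.0
    drift_sd: float = 0.0
    retain_prob: float = 0.5
    niche_dims: int = 5
    conservation_decay: float = 12.0
    clade_size_range: tuple = (15, 50)

    def __post_init__(self) -> None:
        if self.process not in PROCESSES:
            raise ValueError(f"unknown process {self.process!r}; "
                             f"choose one of {PROCESSES}")
        for name in ("n_otus", "n_environments", "samples_per_environment",
                     "reads_per_sample", "niche_dims"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.selection_width <= 0:
            raise ValueError("selection_width must be > 0")
        if self.bm_rate < 0:
            raise ValueError("bm_rate must be >= 0")
        if not 0.0 <= self.migration_rate <= 1.0:
            raise ValueError("migration_rate must be in [0, 1]")
        if self.drift_sd < 0:
            raise ValueError("drift_sd must be >= 0")
        if not 0.0 < self.retain_prob <= 1.0:
            raise ValueError("retain_prob must be in (0, 1]")
        if self.env_values is not None:
            if len(self.env_values) != self.n_environments:
                raise ValueError("env_values needs one entry per environment")
            object.__setattr__(self, "env_values",
                               tuple(float(v) for v in self.env_values))
        lo, hi = self.clade_size_range
        if not 2 <= lo <= hi:
            raise ValueError("invalid clade_size_range")
        object.__setattr__(self, "clade_size_range", (int(lo), int(hi)))


@dataclass(frozen=True)
class SyntheticDataset:
    """A generated phylogeny, table, design, traits and the true process.

    ``traits`` is a DataFrame (OTU × trait dimension); ``optima`` the
    per-environment niche optimum used under selection (all-zero rows
    for non-selective processes).
    """

    tree: TreeNode
    table: CommunityTable
    design: EnvironmentDesign
    traits: pd.DataFrame
    optima: pd.DataFrame
    process: str
    config: ScenarioConfig


def simulate_tree(n_tips: int, seed: int, birth_rate: float = 1.0) -> TreeNode:
    """Ultrametric pure-birth (Yule) tree with ``n_tips`` tips.

    Waiting times between speciations are exponential with rate
    (number of lineages) × ``birth_rate``; the lineage that splits is
    uniform. Tips are labelled ``OTU_0001`` … in a deterministic order,
    so a seed fully determines the newick string.
    """
    if n_tips < 2:
        raise ValueError("a tree needs at least 2 tips")
    rng = np.random.default_rng(seed)
    root = TreeNode()
    active = [(TreeNode(), 0.0), (TreeNode(), 0.0)]
    for node, _ in active:
        root.append(node)
    t = 0.0
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / (k * birth_rate))
        node, origin = active.pop(int(rng.integers(k)))
        node.length = t - origin
        children = [(TreeNode(), t), (TreeNode(), t)]
        for child, _ in children:
            node.append(child)
        active.extend(children)
    t += rng.exponential(1.0 / (n_tips * birth_rate))
    for node, origin in active:
        node.length = t - origin
    for i, tip in enumerate(root.tips()):
        tip.name = f"OTU_{i + 1:04d}"
    return root


def simulate_traits_bm(tree: TreeNode, sigma2: float, seed: int,
                       root_value: float = 0.0) -> pd.Series:
    """Brownian-motion trait evolution along the tree.

    Each branch adds a Normal(0, sigma2 × branch length) increment to
    the parent's value, starting from ``root_value`` at the root.
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    rng = np.random.default_rng(seed)
    values: dict[int, float] = {id(tree): float(root_value)}
    traits = {}
    for node in tree.preorder(include_self=False):
        step = rng.normal(0.0, np.sqrt(sigma2 * node.length))
        values[id(node)] = values[id(node.parent)] + step
        if node.is_tip():
            traits[node.name] = values[id(node)]
    return pd.Series({t.name: traits[t.name] for t in tree.tips()},
                     name="trait")


def simulate_niche_traits(tree: TreeNode, seed: int, n_dims: int = 5,
                          decay: float = 12.0,
                          sigma2: float = 1.0) -> pd.DataFrame:
    """Multivariate early-burst trait evolution (strongly conserved
    niches).

    Each dimension evolves as Brownian motion whose rate decays with
    depth, ``σ²(t) = σ² · exp(−decay · t / T)`` with ``T`` the tree
    height; branch variances integrate that rate along the branch.
    ``decay = 0`` reduces to plain Brownian motion. Columns are
    standardized to zero mean and unit variance across tips, so one
    unit of trait distance is one standard deviation of the pool's
    niche diversity.
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    if decay < 0:
        raise ValueError("decay must be >= 0")
    rng = np.random.default_rng(seed)
    height = max(tree.distance(t) for t in tree.tips())
    tips = [t.name for t in tree.tips()]
    cols = {}
    for k in range(n_dims):
        depth = {id(tree): 0.0}
        values = {id(tree): 0.0}
        out = {}
        for node in tree.preorder(include_self=False):
            d0 = depth[id(node.parent)]
            d1 = d0 + node.length
            depth[id(node)] = d1
            if decay > 0:
                var = (sigma2 * height / decay
                       * (np.exp(-decay * d0 / height)
                          - np.exp(-decay * d1 / height)))
            else:
                var = sigma2 * node.length
            values[id(node)] = (values[id(node.parent)]
                                + rng.normal(0.0, np.sqrt(var)))
            if node.is_tip():
                out[node.name] = values[id(node)]
        cols[f"axis_{k + 1}"] = pd.Series(out)
    frame = pd.DataFrame(cols).loc[tips]
    sd = frame.std(ddof=0)
    sd = sd.where(sd > 0, 1.0)
    return (frame - frame.mean()) / sd


def _anchor_clades(tree: TreeNode, traits: pd.DataFrame,
                   size_range: tuple, n_anchors: int,
                   min_separation: float = 3.0) -> list[tuple]:
    """Choose ``n_anchors`` disjoint clades to serve as niche optima.

    Candidates are clades within ``size_range``; each is scored by
    phylogenetic compactness (mean nearest-neighbour patristic distance
    among its tips, relative to tree height) and by trait separation
    (centroid norm over trait radius). The most compact well-separated
    clades are picked greedily, skipping clades overlapping an earlier
    pick. Returns ``(centroid, radius, tip-set)`` triples.
    """
    dm = tree.tip_tip_distances()
    D = np.asarray(dm.data)
    pos = {name: i for i, name in enumerate(dm.ids)}
    height = D.max() / 2.0
    lo, hi = size_range
    cands = []
    for node in tree.non_tips(include_self=False):
        tips = [t.name for t in node.tips()]
        if not lo <= len(tips) <= hi:
            continue
        V = traits.loc[tips].to_numpy()
        centroid = V.mean(axis=0)
        radius = float(np.sqrt(((V - centroid) ** 2).sum(axis=1).mean()))
        idx = [pos[t] for t in tips]
        sub = D[np.ix_(idx, idx)]
        np.fill_diagonal(sub, np.inf)
        compact = float(sub.min(axis=1).mean() / height)
        separation = float(np.linalg.norm(centroid) / max(radius, 1e-9))
        cands.append((compact, separation, centroid, radius,
                      frozenset(tips)))
    if not cands:
        raise ValueError("no clade in the configured size range; adjust "
                         "clade_size_range or n_otus")
    well_separated = [c for c in cands if c[1] >= min_separation] or cands
    well_separated.sort(key=lambda c: c[0])
    picked = [well_separated[0]]
    while len(picked) < n_anchors:
        pool = [c for c in well_separated
                if all(not (c[4] & p[4]) for p in picked)]
        if not pool:
            pool = [c for c in sorted(cands, key=lambda c: c[0])
                    if all(not (c[4] & p[4]) for p in picked)]
        if not pool:
            raise ValueError(
                f"could not find {n_anchors} disjoint anchor clades")
        # later anchors sit as far as possible from the earlier ones on
        # the tree, so between-environment turnover crosses deep branches
        taken = [pos[t] for p in picked for t in p[4]]

        def cross_distance(c):
            idx = [pos[t] for t in c[4]]
            return float(D[np.ix_(idx, taken)].mean())

        picked.append(max(pool, key=cross_distance))
    return [(c[2], c[3], c[4]) for c in picked]


def _sample_labels(config: ScenarioConfig) -> tuple[list[str], list[str]]:
    samples, env_of = [], []
    for e in range(config.n_environments):
        env = f"env_{e + 1:02d}"
        for r in range(config.samples_per_environment):
            samples.append(f"{env}.rep{r + 1:02d}")
            env_of.append(env)
    return samples, env_of


def _resolve_optima(tree: TreeNode, traits: pd.DataFrame,
                    config: ScenarioConfig) -> tuple[np.ndarray, float]:
    """Per-environment optimum matrix (E × d) and selection width σ_w."""
    E = config.n_environments
    d = traits.shape[1]
    if config.env_values is not None:
        if d != 1:
            raise ValueError("explicit env_values require one-dimensional "
                             "traits")
        optima = np.asarray(config.env_values, dtype=float)[:, None]
        return optima, float(config.selection_width)
    if config.process not in SELECTION_PROCESSES:
        return np.zeros((E, d)), float(config.selection_width)
    n_anchors = 1 if config.process == "homogeneous_selection" else min(E, 2)
    anchors = _anchor_clades(tree, traits, config.clade_size_range, n_anchors)
    radius = max(max(r for _, r, _ in anchors), 0.1)
    sigma_w = max(0.5 * radius * config.selection_width, 0.05)
    rows = [anchors[e % len(anchors)][0] for e in range(E)]
    return np.vstack(rows), sigma_w


def simulate_communities(tree: TreeNode, traits, config: ScenarioConfig
                         ) -> SyntheticDataset:
    """Assemble OTU count tables under the configured process.

    Metacommunity base abundances are lognormal(0, ``lognormal_sd``);
    per-sample sampling probabilities combine them with the
    process-specific filters described in the module docstring, then a
    colonization lottery and optional abundance jitter are applied
    (except under ``homogenizing_dispersal``), and counts are one
    multinomial draw of ``reads_per_sample`` reads.
    """
    if isinstance(traits, pd.Series):
        traits = traits.to_frame(name="axis_1")
    otus = [t.name for t in tree.tips()]
    if set(traits.index) != set(otus):
        raise ValueError("traits must cover exactly the tree tips")
    traits = traits.loc[otus]
    X = traits.to_numpy(dtype=float)
    S = len(otus)
    optima, sigma_w = _resolve_optima(tree, traits, config)
    rng = np.random.default_rng(config.community_seed)
    base = rng.lognormal(0.0, config.lognormal_sd, size=S)
    samples, env_of = _sample_labels(config)
    env_index = {f"env_{e + 1:02d}": e for e in range(config.n_environments)}

    pools = None
    if config.process == "dispersal_limitation":
        pools = np.array_split(rng.permutation(S), config.n_environments)
    shared = base / base.sum()

    counts = np.zeros((S, len(samples)), dtype=np.int64)
    for s, env in enumerate(env_of):
        e = env_index[env]
        if config.process in SELECTION_PROCESSES:
            sq = ((X - optima[e]) ** 2).sum(axis=1)
            p = base * np.exp(-sq / (2.0 * sigma_w ** 2))
        elif config.process == "neutral":
            p = base.copy()
        elif config.process == "dispersal_limitation":
            local = np.zeros(S)
            local[pools[e]] = base[pools[e]]
            if local.sum() == 0:
                raise ValueError("empty local pool; increase n_otus")
            p = ((1.0 - config.migration_rate) * local / local.sum()
                 + config.migration_rate * shared)
        else:  # homogenizing_dispersal
            p = shared.copy()
        if config.process != "homogenizing_dispersal":
            if config.drift_sd > 0:
                p = p * rng.lognormal(0.0, config.drift_sd, size=S)
            if config.retain_prob < 1.0:
                keep = rng.random(S) < config.retain_prob
                if (p * keep).sum() > 0:   # never empty a sample entirely
                    p = p * keep
        if p.sum() <= 0:
            raise ValueError("no OTU left to sample; selection too narrow")
        counts[:, s] = rng.multinomial(config.reads_per_sample, p / p.sum())

    table = CommunityTable(pd.DataFrame(counts, index=otus, columns=samples))
    meta = {"environment": env_of}
    for k in range(optima.shape[1]):
        vals = np.array([optima[env_index[e], k] for e in env_of])
        noise = rng.normal(0.0, _COVARIATE_NOISE_SD, size=len(env_of))
        meta[f"env_axis_{k + 1}"] = vals + noise
    design = EnvironmentDesign(pd.DataFrame(
        meta, index=pd.Index(samples, name="sample_id")))
    optima_df = pd.DataFrame(
        optima, index=[f"env_{e + 1:02d}"
                       for e in range(config.n_environments)],
        columns=list(traits.columns))
    return SyntheticDataset(tree=tree, table=table, design=design,
                            traits=traits, optima=optima_df,
                            process=config.process, config=config)


def make_dataset(config: ScenarioConfig) -> SyntheticDataset:
    """Tree + traits + communities from one config.

    Traits are one-dimensional Brownian when ``env_values`` are given
    explicitly (scalar optima), otherwise the multivariate early-burst
    niche process.
    """
    tree = simulate_tree(config.n_otus, config.tree_seed)
    # traits get their own stream, well away from tree/community seeds
    trait_seed = config.tree_seed + 10007
    if config.env_values is not None:
        traits = simulate_traits_bm(tree, config.bm_rate, trait_seed)
    else:
        traits = simulate_niche_traits(tree, trait_seed,
                                       n_dims=config.niche_dims,
                                       decay=config.conservation_decay,
                                       sigma2=config.bm_rate)
    return simulate_communities(tree, traits, config)


def default_scenario(process: str, seed: int) -> ScenarioConfig:
    """Canonical benchmark configuration for each assembly process.

    Selection scenarios use a fairly even metacommunity (lognormal
    σ = 0.5) so the abundance-weighted phylogenetic turnover reflects
    many community members; the drift/dispersal scenarios use a steeper
    (σ = 2–3), more realistic abundance distribution. Homogenizing
    dispersal is sequenced deeply (30 000 reads) because its signature
    is Bray–Curtis similarity beyond sampling noise.
    """
    seed = int(seed)
    common = dict(tree_seed=seed, community_seed=seed + 1, n_otus=150)
    if process in SELECTION_PROCESSES:
        return ScenarioConfig(process=process, n_environments=2,
                              samples_per_environment=6,
                              reads_per_sample=5000, lognormal_sd=0.5,
                              retain_prob=0.5, **common)
    if process == "neutral":
        return ScenarioConfig(process=process, n_environments=2,
                              samples_per_environment=6,
                              reads_per_sample=5000, lognormal_sd=2.0,
                              retain_prob=0.5, **common)
    if process == "dispersal_limitation":
        return ScenarioConfig(process=process, n_environments=4,
                              samples_per_environment=3,
                              reads_per_sample=5000, lognormal_sd=2.0,
                              retain_prob=0.7, migration_rate=0.0, **common)
    if process == "homogenizing_dispersal":
        return ScenarioConfig(process=process, n_environments=2,
                              samples_per_environment=6,
                              reads_per_sample=30000, lognormal_sd=3.0,
                              **common)
    raise ValueError(f"unknown process {process!r}")


def planted_niche_table(seed: int, n_background: int = 400,
                        n_specialists: int = 50, n_generalists: int = 50,
                        n_environments: int = 16,
                        samples_per_environment: int = 3,
                        mean_reads: float = 20.0):
    """Presence-structured table with planted specialists and generalists.

    Background OTUs occupy a uniformly random number of environments;
    planted specialists occur in exactly one environment, planted
    generalists in all of them. Counts for a present (OTU, sample) cell
    are 1 + Poisson(``mean_reads``), so detection is certain and the
    planted occupancies survive downstream presence calls.

    Returns ``(table, design, truth)`` with ``truth`` the planted label
    per OTU ('specialist', 'generalist' or 'background').
    """
    rng = np.random.default_rng(seed)
    envs = [f"env_{e + 1:02d}" for e in range(n_environments)]
    samples, env_of = [], []
    for env in envs:
        for r in range(samples_per_environment):
            samples.append(f"{env}.rep{r + 1:02d}")
            env_of.append(env)
    otus, truth, presence_rows = [], {}, []
    for i in range(n_specialists):
        otus.append(f"SPEC_{i + 1:03d}")
        truth[otus[-1]] = "specialist"
        row = np.zeros(n_environments, dtype=bool)
        row[rng.integers(n_environments)] = True
        presence_rows.append(row)
    for i in range(n_generalists):
        otus.append(f"GEN_{i + 1:03d}")
        truth[otus[-1]] = "generalist"
        presence_rows.append(np.ones(n_environments, dtype=bool))
    for i in range(n_background):
        otus.append(f"BG_{i + 1:04d}")
        truth[otus[-1]] = "background"
        occ = int(rng.integers(1, n_environments + 1))
        row = np.zeros(n_environments, dtype=bool)
        row[rng.choice(n_environments, size=occ, replace=False)] = True
        presence_rows.append(row)
    presence = np.array(presence_rows)
    counts = np.zeros((len(otus), len(samples)), dtype=np.int64)
    for s, env in enumerate(env_of):
        col = presence[:, envs.index(env)]
        counts[col, s] = 1 + rng.poisson(mean_reads, size=col.sum())
    table = CommunityTable(pd.DataFrame(counts, index=otus, columns=samples))
    design = EnvironmentDesign(pd.DataFrame(
        {"environment": env_of},
        index=pd.Index(samples, name="sample_id")))
    return table, design, pd.Series(truth, name="planted_label")


def make_scenario(config: ScenarioConfig, outdir, force: bool = False
                  ) -> SyntheticDataset:
    """Generate a dataset and write table/tree/metadata/truth to disk."""
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise FileExistsError(f"{outdir} exists and is not empty; "
                              f"use force=True to overwrite")
    outdir.mkdir(parents=True, exist_ok=True)
    ds = make_dataset(config)
    eio.write_community_table(ds.table, outdir / "table.tsv")
    eio.write_tree(ds.tree, outdir / "tree.nwk")
    eio.write_metadata(ds.design, outdir / "metadata.tsv")
    ds.traits.rename_axis("otu_id").to_csv(outdir / "traits.tsv", sep="\t")
    truth = dataclasses.asdict(config)
    truth["ground_truth_process"] = config.process
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
    return ds
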