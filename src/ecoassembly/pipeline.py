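"""End-to-end analysis pipeline with a machine-readable run report.

Stages mirror the analysis order: rarefaction → α-diversity →
generalist/specialist classification → phylogenetic-signal check →
βNTI/RCbray assembly inference → process partition. The signal check
gates assembly inference: without a significant positive Mantel r in
the shortest phylogenetic-distance classes, phylogenetic turnover does
not track ecology and βNTI is uninterpretable; ``force_assembly``
overrides the gate.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as eio
from .assembly import (beta_nti, cophenetic_distances, partition_processes,
                       raup_crick_bray)
from .diversity import alpha_diversity, rarefy
from .niche import (classify_taxa, group_summary, levins_niche_breadth,
                    occupancy_counts, occupancy_null)
from .phylosignal import mantel_correlogram, niche_distances, otu_niche_values

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

REPORT_SCHEMA_VERSION = 1


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and cause."""


@dataclass(frozen=True)
class RunConfig:
    """All inputs and knobs of one pipeline run."""

    table: str
    tree: str
    metadata: str
    outdir: str
    rarefaction_depth: int | None = None   # None → minimum sample total
    seed: int = 0
    n_perm: int = 10000                    # occupancy permutations
    n_null: int = 999                      # βNTI / RCbray null replicates
    specialist_max: int = 1
    generalist_min: int = 6
    alpha: float = 0.05
    grouping: str = "all"
    covariates: tuple | None = None        # None → all numeric columns
    n_classes: int = 50
    prune_missing: bool = False
    force_assembly: bool = False

    def validate(self) -> None:
        for name in ("table", "tree", "metadata"):
            path = Path(getattr(self, name))
            if not path.exists():
                raise PipelineError(f"validation: {name} file not found: "
                                    f"{path}")
        if self.rarefaction_depth is not None and self.rarefaction_depth <= 0:
            raise PipelineError("validation: rarefaction depth must be "
                                "positive")
        for name in ("n_perm", "n_null", "n_classes"):
            if getattr(self, name) < 1:
                raise PipelineError(f"validation: {name} must be >= 1")
        if not 0 < self.alpha < 1:
            raise PipelineError("validation: alpha must be in (0, 1)")
        if self.specialist_max >= self.generalist_min:
            raise PipelineError("validation: specialist_max must be below "
                                "generalist_min")


def _stage(report: dict, name: str):
    class _Timer:
        def __enter__(self):
            logger.info("stage %s ...", name)
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            report["timing_seconds"][name] = round(dt, 3)
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            return False
    return _Timer()


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages, write artifacts under ``config.outdir`` and return
    the report dictionary (also written as ``report.json``)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    seeds = {k: int(v) for k, v in zip(
        ("rarefaction", "classification", "correlogram", "beta_nti",
         "raup_crick"),
        rng.integers(2 ** 31, size=5))}
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "software_version": __version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in dataclasses.asdict(config).items()},
        "seeds": seeds,
        "timing_seconds": {},
    }

    with _stage(report, "load"):
        table = eio.read_community_table(config.table)
        tree = eio.read_tree(config.tree)
        design = eio.read_metadata(config.metadata)
        design.environment_of(table.sample_ids)  # every sample mapped
        table, tree = eio.prune_to_shared_otus(
            table, tree, prune_missing=config.prune_missing)

    with _stage(report, "rarefaction"):
        depth = (config.rarefaction_depth
                 if config.rarefaction_depth is not None
                 else int(table.sample_totals().min()))
        # zero-total OTUs stay in the table: the full input OTU set is the
        # regional pool the βNTI tip-shuffle null randomizes over
        table = rarefy(table, depth, seeds["rarefaction"])
        report["rarefaction"] = {"depth": depth,
                                 "n_samples": table.n_samples,
                                 "n_otus": table.n_otus}

    with _stage(report, "alpha_diversity"):
        alpha = alpha_diversity(table)
        alpha.rename_axis("sample_id").to_csv(
            outdir / "alpha_diversity.tsv", sep="\t")
        report["alpha_diversity"] = {
            "mean_richness": float(alpha["richness"].mean()),
            "mean_shannon_nats": float(alpha["shannon_nats"].mean())}

    with _stage(report, "classification"):
        profile = occupancy_counts(table, design)
        null = occupancy_null(table, design, config.n_perm,
                              seeds["classification"])
        cls = classify_taxa(profile, null,
                            specialist_max=config.specialist_max,
                            generalist_min=config.generalist_min,
                            alpha=config.alpha)
        breadth = levins_niche_breadth(table, design)
        per_otu = cls.per_otu.join(breadth, how="left")
        per_otu["class_p"] = per_otu["occupancy"].map(cls.class_pvalues)
        per_otu.rename_axis("otu_id").to_csv(
            outdir / "classification.tsv", sep="\t")
        enrich = pd.DataFrame({
            "observed_count": profile.class_counts(),
            "p_enrichment": cls.class_pvalues,
            "enriched": cls.enriched})
        enrich.rename_axis("occupancy_class").to_csv(
            outdir / "class_enrichment.tsv", sep="\t")
        summary = group_summary(cls, table, design)
        summary.to_csv(outdir / "group_summary.tsv", sep="\t", index=False)
        counts = cls.labels().value_counts()
        report["classification"] = {
            "n_generalists": int(counts.get("generalist", 0)),
            "n_specialists": int(counts.get("specialist", 0)),
            "n_common": int(counts.get("common", 0)),
            "median_breadth_generalist": float(
                breadth[cls.labels() == "generalist"].median())
            if counts.get("generalist", 0) else None,
            "median_breadth_specialist": float(
                breadth[cls.labels() == "specialist"].median())
            if counts.get("specialist", 0) else None,
        }

    with _stage(report, "phylogenetic_signal"):
        covariates = (list(config.covariates)
                      if config.covariates is not None else None)
        niche = otu_niche_values(table, design, covariates)
        ndist = niche_distances(niche)
        phylo = cophenetic_distances(tree).reindex(ndist.ids)
        correlogram = mantel_correlogram(
            ndist, phylo, n_classes=config.n_classes, n_perm=config.n_null,
            seed=seeds["correlogram"], alpha=config.alpha)
        correlogram.classes.to_csv(outdir / "correlogram.tsv", sep="\t",
                                   index=False)
        has_signal = correlogram.significant_positive()
        report["phylogenetic_signal"] = {
            "significant_positive_short_classes": bool(has_signal)}
        if not has_signal and not config.force_assembly:
            raise PipelineError(
                "stage 'phylogenetic_signal': no significant positive "
                "Mantel correlation in the shortest phylogenetic-distance "
                "classes; assembly inference is not interpretable "
                "(use force_assembly to override)")

    with _stage(report, "assembly"):
        phylo_full = cophenetic_distances(tree)
        bnti = beta_nti(table, phylo_full, n_null=config.n_null,
                        seed=seeds["beta_nti"])
        rc = raup_crick_bray(table, n_null=config.n_null,
                             seed=seeds["raup_crick"])
        eio.write_matrix(bnti, outdir / "beta_nti.tsv")
        eio.write_matrix(rc, outdir / "rc_bray.tsv")
        summary = partition_processes(bnti, rc, design,
                                      grouping=config.grouping)
        summary.pairs.to_csv(outdir / "pairwise_processes.tsv", sep="\t",
                             index=False)
        summary.fractions.to_csv(outdir / "process_fractions.tsv", sep="\t")
        report["assembly"] = {
            "grouping": config.grouping,
            "fractions": json.loads(
                summary.fractions.to_json(orient="index")),
        }

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
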