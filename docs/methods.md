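# Methods

This note documents the models, numerical choices and known limitations
behind `ecoassembly`, in the order the pipeline runs them.

## Data model and plumbing

OTU tables are nonnegative integer counts (OTUs × samples, TSV with an
optional `#OTU ID` header token); trees are rooted newick with branch
lengths, held as scikit-bio `TreeNode`s; metadata is a TSV with
`sample_id` and either an `environment` column or `site` + `treatment`
(concatenated with "×"). Reading is strict: duplicate ids, negative,
fractional or non-numeric counts, unlabeled tips and missing branch
lengths are hard errors — silent repair of any of these corrupts the
downstream null models. OTUs missing from the tree are likewise a hard
error unless pruning is requested explicitly, because silently dropping
them changes βMNTD.

Rarefaction draws each sample once from a multivariate hypergeometric
distribution — the exact law of subsampling reads without replacement —
at a common depth (default: the minimum sample total). Samples below
depth are dropped, never upsampled. OTUs whose counts fall to zero
**stay in the table**: the full input OTU set is the regional pool that
the βNTI null randomizes over (see below). Whether rare-OTU filtering
should precede or follow rarefaction is left to the caller; the package
applies no abundance filter of its own.

The Shannon index is reported in nats (column `shannon_nats`; the
natural-log convention is stated in the output header because reporting
conventions differ across tools). Bray–Curtis is computed on counts,
`Σ|x−y|/Σ(x+y)`.

## Generalist/specialist classification

Presence of an OTU in an environment means ≥ 1 read in ≥ 1 sample of
that environment, evaluated after rarefaction so detection effort is
equal across samples. The null model permutes the species–environment
association map: each environment independently receives a uniform
random subset of the OTU pool with the same size as its observed
richness (richness preservation is the only constraint imposed;
fixed-margin swap algorithms that also preserve per-OTU occupancy are a
different null and out of scope). Per occupancy class c the empirical
one-sided enrichment p-value is `(1 + #{null ≥ obs}) / (n_perm + 1)`;
classes at p ≤ α (default 0.05, no cross-class multiplicity correction
— each class is a separate scientific claim and the calibration test
bounds the per-class error) define the labels. Defaults: specialists
occupy ≤ 1 environment, generalists ≥ 6 — both exposed as flags, since
the sensible cutoffs depend on the number of environments surveyed.
"Common" deliberately includes OTUs in enriched classes *between* the
two cutoffs; only the tails are given ecological labels.

Levins' breadth normalizes each OTU's environment-level abundance
profile to a probability vector, giving the testable bounds
1 ≤ B ≤ E and B ≤ occupancy. OTUs with zero total are excluded with a
warning.

## Phylogenetic signal (Mantel correlogram)

OTU niche values are abundance-weighted means of standardized sample
covariates; niche distance is Euclidean. Phylogenetic distances are
binned into `n_classes` equal-width classes over (0, max]; per class
the Mantel statistic is the Pearson correlation between the
niche-distance vector and the class indicator, sign-flipped so positive
r at short distances means close relatives have similar niches (the
classical correlogram convention; verified against vegan's
`mantel.correlog` in the test suite). Significance is a two-sided
permutation test (999 permutations of the niche matrix) under
progressive Bonferroni: the k-th tested class is held to α/k *and* the
correlogram is read sequentially from short distances outward, stopping
at the first non-significant class. The sequential reading is what
keeps the familywise error of the whole correlogram near α (~5% on
trait-shuffled controls); without it, 20–50 classes at α/k accumulate
roughly Σα/k ≈ 15–20% false signal. Classes with fewer than
`min_class_pairs` (default 5) pairs are reported but not tested — a
Mantel statistic over a handful of pairs is noise, and letting it break
the sequential chain would hide real signal further out.

The pipeline treats a significant positive r in the first three tested
classes as the prerequisite for assembly inference, and aborts without
it unless `force_assembly` is set. Note the flip side: a dataset whose
samples all experienced the *same* selective filter has no covariate
variation, hence no detectable niche signal, even though βNTI would
correctly report homogeneous selection — that is precisely what the
override flag is for.

## βMNTD, βNTI, RCbray and the partition

βMNTD is abundance-weighted with minima over the partner community's
support; shared OTUs contribute zero. The implementation vectorizes all
sample pairs through one min-reduction per sample and a single matrix
product, and is checked to 1e-12 against a brute-force double loop.

The βNTI null shuffles tip labels uniformly across the **full OTU pool
of the input table** — one shuffle per replicate shared by all pairs
(per-pair shuffles would make the matrix internally inconsistent).
999 replicates; z-scores use the sample (n−1) standard deviation. Pairs
whose null distribution is degenerate (sd = 0, e.g., a star phylogeny
or two samples with identical support) are NaN with a warning and are
excluded from process labelling with a logged count. Because the pool
defines the null, homogeneous selection acting on *every* sample of a
dataset is only detectable when the table retains pool members outside
the selected set; this is a property of the method, not of this
implementation.

RCbray builds, per sample pair, 999 pairs of null communities: members
drawn without replacement with probability proportional to occupancy
frequency (Gumbel top-k sampling), remaining reads allocated
multinomially by metacommunity relative abundance, each member keeping
at least one read. The observed Bray–Curtis is rescaled against the
null sample as `((n_less + ½·n_equal)/n_null − ½)·2`; exact float ties
get half weight, which is well-defined because identical integer count
configurations produce bit-identical Bray–Curtis values.

Thresholds follow the published decision tree with strict inequalities:
βNTI > +2 heterogeneous selection, βNTI < −2 homogeneous selection,
otherwise RCbray > 0.95 dispersal limitation, RCbray < −0.95
homogenizing dispersal, else undominated. Boundary values (βNTI = ±2,
RCbray = ±0.95) therefore fall to the stochastic/undominated side.
RCbray is computed for every pair but only consulted when |βNTI| ≤ 2.
Group summaries aggregate pairs whose two samples share a grouping key
(`treatment`, `site`, `environment`) or all pairs (`all`, the default);
which pairs compose a published per-treatment figure is often ambiguous
in the literature, so all groupings are exposed and none is claimed
canonical.

Every stochastic operation takes an explicit seed; identical inputs,
seed and replicate count give bit-identical outputs (asserted by test).

## Synthetic communities

The simulator is first-class code: it defines the conditions under
which the inference chain is validated.

* **Phylogeny.** Pure-birth (Yule) trees, ultrametric, exponential
  waiting times — the simplest process with controllable depth.
* **Niche traits.** By default a 5-dimensional early-burst Brownian
  process: per-dimension BM whose rate decays as
  `exp(−decay·t/T)` (decay 12) so trait variance concentrates on deep
  branches. Two properties motivated this over plain 1-D BM, with which
  detection of planted selection depended heavily on the random tree:
  a one-dimensional trait lets distant clades collide in niche space
  (convergence), and weak conservation blurs the clade structure the
  βNTI scenarios must plant. Several independent dimensions make
  collisions vanishingly rare; the early burst makes niches strongly
  heritable. Columns are standardized, so trait units are pool-level
  standard deviations. Scalar plain-BM traits remain available (and are
  used by the Mantel benchmark); explicit `env_values` trigger them.
* **Selection.** Gaussian weights `exp(−‖trait−optimum‖²/(2σ_w²))` on
  top of lognormal metacommunity abundances. By default the optimum of
  each environment is anchored to the trait centroid of a real clade:
  among clades of 15–50 tips whose trait centroid is well separated
  from the pool, the phylogenetically most compact one is chosen, with
  σ_w = half its trait radius; for heterogeneous selection the second
  environment gets the anchor clade most distant on the tree. Anchoring
  guarantees that "selection toward an optimum" targets a populated
  region of niche space for every random tree — with free-floating
  optima the selected set is occasionally near-empty or scattered, and
  the planted signal disappears through no fault of the inference.
* **Drift and dispersal.** Replicate samples differ through a
  colonization lottery (each OTU enters a sample with probability
  `retain_prob`, default 0.5) and optionally a lognormal abundance
  jitter (`drift_sd`). Dispersal limitation splits the pool into
  disjoint per-environment subsets mixed with a fraction `m` of the
  global pool; homogenizing dispersal draws every sample from one
  shared composition and disables drift (that is what "homogenizing"
  means). Reads are multinomial, matching rarefied-count semantics.

### Benchmark scenarios

`default_scenario(process, seed)` fixes the conditions used by the
recovery tests: 150 OTUs; selection scenarios use 2 environments × 6
samples × 5,000 reads with a fairly even metacommunity (lognormal
σ = 0.5) so βMNTD reflects many members rather than one dominant;
neutral uses a steeper, more realistic σ = 2; dispersal limitation uses
4 isolated pools (m = 0) × 3 samples; homogenizing dispersal is
sequenced deeply (30,000 reads, σ = 3) because its signature is
similarity beyond sampling noise — at saturating depth *and* a flat
abundance distribution the null communities converge on the observed
ones and the signature fades. Problem sizes were chosen so each
benchmark completes in seconds while leaving every recovery fraction
comfortably above the 70% bar across development seeds.

### What passing these tests does and does not show

The generator emulates phylogenetically conserved, clade-structured
niches, lognormal abundances, multinomial read sampling and idealized
drift/dispersal. It does not emulate sequencing error, chimeras,
compositional artifacts, OTU-clustering noise, phylogeny estimation
error, or selection on traits that are *not* phylogenetically
conserved. Recovery of planted processes here therefore demonstrates
correctness of the inference machinery under the framework's own
assumptions — not that those assumptions hold for any particular real
community.

## Pipeline

Stages: load/validate → rarefy → α-diversity → classification →
phylogenetic-signal gate → βNTI + RCbray → partition → report. The
JSON report records software version, config, per-stage seeds (derived
from the master seed) and wall-clock per stage; every number in it is
recomputable by calling the module functions with those seeds. Progress
is logged to stderr and to `ecoassembly.log` in the output directory.

## Known limitations

* βNTI at small pool sizes (≲100 OTUs) has wide null spread; |z| > 2
  requires strong planted structure, and degenerate (NaN) pairs appear
  when samples saturate the pool.
* The occupancy null preserves environment richness only; nulls that
  also fix per-OTU occupancy (swap algorithms) would be stricter and
  are not implemented.
* The correlogram's equal-width classes follow observed distances; with
  strongly gapped trees some classes are empty and are skipped rather
  than merged.
* `group_summary` percentages are per-group compositions; they are not
  comparable across groups with very different sampling depth unless
  the table was rarefied (the pipeline rarefies first).
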