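# Methods

## Model

`pomanet` treats miRNA regulation as a directed bipartite graph
G = (M, T, E) with miRNAs M, target genes T, and edges E ⊆ M × T drawn
from merged target-interaction databases. The statistic of interest is
the *NOD* (novel out-degree) of a miRNA m:

    NOD(m) = |{ g ∈ T(m) : indeg(g) = 1 }|,

the number of targets g whose only regulator is m. NOD satisfies, by
construction:

* NOD(m) ≤ outdeg(m);
* Σ_m NOD(m) = #{genes with in-degree exactly 1};
* removing another miRNA never decreases NOD(m); adding edges from
  other miRNAs never increases it (uniqueness can only be destroyed by
  competition).

The biological premise is that genes with a single regulator are frail
network positions: deregulation of the sole upstream miRNA propagates
unbuffered, so miRNAs with many unique targets ("high independent
regulatory power") are promising markers of a phenotype shift. The
pipeline therefore intersects two orthogonal signals: a miRNA must be
differentially expressed between the contrast groups *and* hold
significantly many unique targets.

## Differential expression

Expression is a miRNA × sample matrix with a two-level sample labelling
(responder / non-responder). The per-miRNA test is the classical
two-sample Student's t (pooled variance, df = nA + nB − 2); a Welch
variant is available. A moderated (limma-style) t is deliberately not
implemented: the package screens with the plain statistic and reports
Benjamini–Hochberg FDR alongside the raw p-values for reuse, while
selection itself uses raw p < 0.05 and |fold-change| > 2. Input is
assumed log2-normalized (the form in which normalized series matrices
are distributed), so the fold-change rule is applied as
|log2FC| > log2(2) = 1 with log2FC = mean difference; a `scale="linear"`
switch computes the ratio of means instead and refuses non-positive
means. Degenerate rows follow fixed conventions: both groups constant
and equal → p = 1; both constant but different → p = 0, flagged
`zero_variance` in a QC column. Missing data are handled complete-case
(rows with any missing value are dropped with a counted warning);
duplicate row IDs are collapsed by per-sample mean after miRNA ID
normalization.

miRNA IDs are normalized by lowercasing and stripping the species
prefix (`hsa-`), with an optional, explicit alias table mapping reported
names to official mature names (the packaged table covers the 30
curated literature miRNAs, e.g. `miR-196b → mir-196b-5p`). Gene symbols
are uppercased only; no symbol-alias resolution is attempted, because
silent alias mapping would change edge counts unauditably.

## NOD significance

The tables this pipeline is patterned on attribute NOD significance to a
signed-rank test, but a signed-rank test requires paired observations
and no pairing of NOD values exists; the printed p-values cannot be
reconstructed from any documented procedure. The package therefore
implements two explicit null models and treats printed p-values, where
used, as fixtures:

**Empirical tail** (deterministic, the `PomaConfig` default):

    p(m) = (1 + #{m' ∈ M : NOD(m') ≥ NOD(m)}) / (1 + |M|).

The count includes m itself, so p is never 0 and is monotone
non-increasing in NOD — matching the monotone NOD→p pattern seen in
published candidate tables. Its limitation is structural: the k-th
ranked miRNA can never receive p below (1 + k)/(1 + |M|), so in a
network where several true biomarkers tie at the top of the NOD
distribution, a rank-based tail at α = 0.05 cannot select more than
⌊0.05·(|M|+1)−1⌋ of them. It is the right default for a single-network
descriptive run, not for joint recovery of several candidates in small
networks.

**Degree-preserving rewiring** (`rewire_permutation`): the null
randomizes which miRNA holds which targets while preserving every
miRNA's out-degree and every gene's in-degree, via curveball trades
(two random miRNAs re-deal the symmetric difference of their target
sets). Because in-degrees are preserved, the set of unique genes is
invariant; the null asks whether m holds more of them than a random
degree-matched reallocation would. p-values use the standard +1
smoothing, p = (1 + #{NOD\* ≥ NOD}) / (1 + n_perm). The sampler runs one
Markov chain per call: burn-in 10·|M| trades, thinning 2·|M| trades
between samples (curveball chains mix in O(|M|) trades on graphs of
this density; the two-seed self-consistency test bounds residual
autocorrelation empirically). Default n_perm = 1000; values below 100
trigger a warning.

A candidate is selected when it is DE, maps into the network, has
NOD ≥ 1, and its NOD p-value is below `nod_alpha` (default 0.05,
`nod_alpha = 0` is allowed and selects nothing). NOD is always computed
on the **full** network: uniqueness is judged against all miRNAs, not
only the DE subset, since curated non-DE miRNAs also carry NOD
annotations. Candidate ordering is NOD descending, then p ascending,
then ID — stable and diff-able.

## Subnetwork reporting

The candidate-specific subnetwork is the edge-induced subgraph on the
selected miRNAs and all their targets. Uniqueness flags default to the
strictest reading — a gene is unique only if its in-degree in the
*parent* network is 1 — with a `uniqueness="subnetwork"` option that
judges uniqueness among candidates only (the two readings differ for
genes shared with non-candidate miRNAs). Accounting reports both the
deduplicated gene count and the pair count; pairs minus genes equals
the number of shared-gene collisions.

## Enrichment

Over-representation of a query gene list in GMT collections uses the
upper-tail hypergeometric probability P[X ≥ k] for overlap k, set size
K, query size n, universe N, with BH correction across sets. The
universe defaults to the union of all GMT genes and is overridable
(typically intersected with the network's gene space); no default
background of an online annotation service is assumed, because such
backgrounds are version-dependent and unauditable.

## Synthetic benchmark

The generator produces the statistical structure the pipeline assumes,
plus a truth record, with three planted miRNA classes:

| class | DE shift | reserved unique targets | should be selected |
|---|---|---|---|
| biomarkers (5) | yes | 8 | **yes** |
| DE-only decoys (5) | yes | 0 | no |
| high-NOD-only decoys (10) | no | 8 | no |

Reserved genes are excluded from the background edge pool, so a planted
miRNA's NOD is at least its reservation by construction. Background
edges are Poisson(mean_degree) draws per miRNA without replacement from
the shared pool. Expression is i.i.d. Gaussian on the log2 scale
(baseline uniform in [6, 12] log2 units, noise σ = 0.5 per sample) with
the planted shift (2.0 log2 units) added to responder samples of
DE-planted miRNAs; group sizes default to 9 vs 29, mirroring a small
clinical two-arm profiling study, so power characteristics are
comparable.

Standard regime: 100 miRNAs, 1000 genes, mean_degree = 35 (3.5%
density, within the 1–4% per-miRNA target density of integrated target
databases). The density is a power-analysis choice for the rewiring
null: the background probability that a given target is unique is
(1 − d/|pool|)^(|M|−1) ≈ 0.02 at d = 35, so a degree-50 miRNA's null
NOD mean is ≈ 2.6 while every planted miRNA observes NOD ≥ 8 — the
planted-miss and decoy-false-positive probabilities are both
negligible, including for miRNAs in the upper tail of the Poisson
degree distribution. At lower densities (≈ 2%) the same analysis shows
degree-dispersed planted miRNAs landing at p ≈ 0.066, which is why the
density sits at the upper end of the realistic range. The ten
high-NOD decoys also serve a second purpose: their reserved blocks keep
the network's unique-gene pool large, which inflates the rewiring null
for low-NOD miRNAs and makes the benchmark harder, not easier.

The benchmark's scored property (20 seeds, rewiring null with 500
permutations, α = 0.05): `run_poma` selects exactly the planted
biomarkers — all five recovered, both decoy classes rejected. DE-only
decoys always pass the DE stage (the shift is 10 standard errors) and
must be rejected on NOD significance; high-NOD decoys have top-tier NOD
and must be rejected at the DE stage. Neither signal alone separates
the classes, which is the pipeline's central discriminative claim.

What the generator does **not** emulate: array probe effects, batch
effects, correlated noise, heavy-tailed expression, miRNA–target
expression coupling, or the topology of real target databases (degree
distributions of real networks are far more skewed than Poisson).
Passing the benchmark shows the pipeline's machinery is correct and
discriminative under its own assumptions; it does not certify
performance on real profiling data.

## Fixtures

Two curated literature tables ship as packaged TSVs: 30 published
chemoradiotherapy-response miRNAs with reported/official IDs and NOD
annotations, and 9 candidate biomarkers with DE p-values, target counts
and NOD p-values. Because the seven source databases are
version-dependent snapshots, the integrated network behind those values
is not reconstructable; instead `fixtures.py` builds deterministic toy
networks realizing the printed values exactly — each miRNA owns a block
of synthetic unique genes (in-degree 1) plus shared genes of in-degree
≥ 2 (for the candidate table, shared slots are paired across different
candidates so out-degrees also match). The printed NOD p-values are
consumed as data, never re-derived.

## Numerical and interface choices

* Permutation and empirical p-values use +1 smoothing; p ∈ (0, 1].
* All writers emit sorted rows; manifests omit timestamps; every
  random procedure takes an explicit integer seed — re-running a
  manifest reproduces outputs byte-identically.
* Edge lists: TSV with per-database column dialects, `#` comments
  ignored, malformed rows dropped with counted warnings, duplicate
  pairs merged with concatenated source labels.
* Exports: sorted TSV, SIF, GraphML (node `kind`, edge `sources`,
  uniqueness flags on subnetworks).
* t-tests and hypergeometric tails are delegated to scipy; BH to
  statsmodels; the NOD statistic, the curveball null, and the generator
  are implemented here.

## Problem sizes

The shipped test suite and the acceptance script run the 20-seed
standard benchmark (100 miRNAs × 1000 genes, 500 permutations per
seed, ≈ 50 s), 100 random graphs for the NOD oracle, 1000 null
replicates for t-test calibration, and exhaustive enumeration up to
12-gene universes for the hypergeometric oracle — sizes chosen so the
whole suite completes in about a minute while keeping Monte-Carlo error
well below the margins being asserted.

## Known limitations

* The empirical-tail null is rank-bounded (see above); use the rewiring
  null when several candidates may tie at high NOD.
* Gene symbols are not alias-resolved; merging databases with mixed
  symbol conventions will under-merge.
* The DE stage assumes approximately Gaussian log2 expression within
  groups; heavy-tailed data would need a robust variant.
* The rewiring null conditions on both degree sequences; nulls that
  also preserve, e.g., database provenance structure are out of scope.
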