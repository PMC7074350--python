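# Methods

## The question the pipeline answers

When two diploid species hybridise and the hybrid doubles its genome, the
resulting allotetraploid starts with one copy of each parental repeatome.
If nothing happens afterwards, the genomic abundance of every repeat family
in the tetraploid equals the sum of its abundances in the two parents —
strict additivity. Departures from additivity measure post-polyploidisation
repeat turnover (amplification or deletion), and an asymmetry between the
maternal and paternal contributions would support the nuclear–cytoplasmic
interaction (NCI) hypothesis, which predicts preferential degradation of the
paternal subgenome inside the maternal cytoplasm.

polyrep implements this comparison for unassembled, low-coverage reads.
Because each species is sampled at the same *genome proportion* (reads whose
total bases equal a fixed fraction, 2% by default, of that species' 1C
size), cluster read counts are directly comparable across genomes of
different sizes, and "abundance" never requires an assembly.

## Pipeline stages

1. **Read preparation.** Reads are discarded if any base has Phred quality
   ≤ 10 or if they contain more than 3 N bases, then trimmed to 91 bp
   (keeping the 5′ end). The permissive quality threshold is deliberate:
   harsher filtering depletes AT/GC-rich satellite reads and biases
   abundance estimates. Each species' surviving reads are subsampled
   without replacement to n = round(proportion × 1C / 91) and read ids are
   prefixed with a five-letter species code.

2. **Comparative clustering.** All three read sets are pooled and a
   similarity graph is built: candidate pairs share ≥ 2 exact 17-mers; an
   edge requires a banded global alignment (edit-distance band implied by
   the identity threshold) with identity ≥ 0.90 over ≥ 0.55 of the read
   length; edge weight is identity × coverage. For uniform-length reads a
   global alignment spans the whole read, so coverage is 1 and identity is
   the operative threshold. Clusters are connected components; components
   above 100 vertices are refined by greedy modularity maximisation
   (resolution 1.0), and a refinement is accepted only when its modularity
   reaches 0.3 — the conventional floor for genuine community structure.
   Without that gate, greedy modularity splits even homogeneous dense
   single-family components (measured Q ≈ 0.003–0.017 on planted families
   of 114–146 reads), whereas genuinely merged communities split at
   Q ≈ 0.5. Per-species counts are recovered from the read-id prefixes;
   clusters are ranked CL1, CL2, … by total size, ties broken by smallest
   member read id.

   Two k-mer seeding regimes matter. The default (k = 17, ≥ 2 shared) is
   fast but approximate: a read pair within the 9-edit threshold can, with
   low probability, share no 17-mer at all when its mismatches are evenly
   spaced. With k = 9 and ≥ 1 shared k-mer, the pigeonhole principle
   guarantees every pair within 9 edits of each other is examined, so the
   seeded graph provably equals an exhaustive all-pairs alignment; the
   oracle-equality tests run in this regime.

3. **Filtering.** A cluster is flagged as contaminant when ≥ 50% of its
   reads share a canonical (strand-collapsed) 17-mer with any supplied
   reference (e.g. organellar genomes). A species is *present* in a cluster
   when it contributes ≥ 10 reads. Flagged clusters are removed; clusters
   present in fewer than two species are removed as species-specific;
   clusters absent from the tetraploid are excluded from regressions but
   kept in the deviation curves with their observed (sub-threshold)
   tetraploid count — total loss of a parental repeat is a real downsizing
   signal, not a missing value. The strict alternative (require presence in
   all three species) is available via `require_all_species`. Every removal
   is logged with exactly one reason.

4. **Additivity statistics.** For each retained cluster, E = m + p and
   D = t − E in exact integer arithmetic. Clusters are ranked by E
   ascending (ties by cluster id) and E and D are accumulated; the curve is
   plotted as signed cumulative deviation against ln(cumulative E). The
   signed quantity is primary — only it can show downsizing — with |cum D|
   as a reporting option. The same arithmetic on 1C values gives the
   genome-size deviation percentage, 100 × (observed − expected)/expected.

5. **Parental-bias regressions.** Cluster sizes are natural-log
   transformed. Each parent's regression ln t = b0 + b1 ln x uses clusters
   with both counts ≥ 10 (log positivity, matching the presence filter).
   The slope comparison stacks both parents' observations with a paternal
   indicator I and tests the interaction term b3 in
   ln t = b0 + b1 ln x + b2 I + b3 (ln x·I) by the extra-sum-of-squares
   F-test: SS = SSE_restricted − SSE_full,
   F = SS/(SSE_full/(n_total − 4)), df = (1, n_total − 4), where
   n_total = 2 × n_clusters. All fits are closed-form normal-equation OLS;
   the test suite checks them against statsmodels to 1e-8–1e-10. A joint
   plane fit of ln t on ln m and ln p supports the 3D visualisation.

## Statistical properties of the slope-equality test

The stacked design duplicates the tetraploid response: ln t appears once in
each parent's group, so the two groups' errors are correlated and the
classical F calibration is only approximate. Empirically (1000 replicates
per regime) the type-I rate at nominal α = 0.05 ranges from under 1%
(strongly conservative, when structural noise dominates) to over 10% (when
heteroskedastic count noise dominates), depending on sequencing depth and
parental divergence. This is a property of the standard analysis recipe,
not of this implementation.

Power has a sharper caveat: **a uniform multiplicative bias on one parent is
invisible to a slope test when parental abundances are proportional to each
other**, because scaling one parent's contribution only shifts the
regression intercept in log space. The slope test detects a bias only
through the nonlinear mixing of *unequal* parental contributions, i.e. when
the two parents' abundance profiles are substantially decorrelated. A
negative slope-equality result in a young polyploid with very similar
parents therefore constrains cytoplasmic bias only weakly — consistent with
the biological reading that closely related progenitors leave little room
for a detectable effect.

## Standard study conditions

Two frozen count-level scenarios define the package's statistical claims
(both via `simulate_cluster_counts`; counts are multinomial draws at fixed
genome proportion, with the tetraploid receiving proportionally more reads
in line with its larger genome):

* **Additive null** (`additive_null_scenario`): 100 clusters; per-family
  abundance from the exact discrete power law P(k) ∝ k^(−1.8) on
  [1, 5000], shared between parents and perturbed per lineage by lognormal
  noise with sd 0.3 (moderate repeat turnover between closely related
  progenitor lineages); 20,000 reads per diploid. Under these conditions
  the slope-equality test's empirical type-I rate is close to nominal
  (3.9–5.2% across independent 1000-replicate batches).
* **Biased scenario** (`biased_scenario`): 200 clusters; independent
  parental abundances (exponent 2.0 — long-diverged progenitors); 50,000
  reads per diploid; paternal contribution multiplied by rho = 0.5. The
  test rejects in ≈ 90% of replicates.

The exact discrete power law matters here: the continuous-floor
approximation used for genome-scale supports has a visibly different pmf at
small copy numbers and shifts the calibration regime.

## The read-level simulator

`simulate_parents` draws per-family copy numbers once from a bounded power
law (support [1, 1C/unit_length], optionally floored at `min_copies` to
restrict to the detectable range), perturbs each parent independently
(lognormal, sd 0.3 by default), and mutates an ancestral consensus at half
the requested divergence per lineage. If drawn repeat content exceeds the
1C size, copy numbers are rescaled proportionally and the rescaling is
logged. `apply_inheritance` unions the family namespaces and applies the
inheritance model per family (multiplier results rounded half away from
zero, since abundances are counts); the tetraploid's 1C value is the
parental sum adjusted by the net repeat gain/loss. The merged family keeps
the maternal consensus — the parental variants lie within the per-copy
divergence envelope, so clustering behaviour is unchanged.

`generate_reads` emits n = round(proportion × 1C / read_length) reads:
each is a window of one family's consensus (families weighted by genomic
bp), first mutated at the family's per-copy divergence (sampling a diverged
genomic copy), then at the sequencing error rate; the remainder of the
genome yields unique random background reads. Reads never span copy
junctions, qualities are a constant Phred 35, and every read's true source
family is recorded for truth-based tests. No indels, no paired ends, no
quality-score model: the downstream analysis uses none of these.

What the simulator does *not* emulate — and hence what green tests do not
show about real data: sequencing indels and quality gradients, tandem-array
junction reads, nested/chimeric repeats, library GC bias, and any
RepeatExplorer-specific behaviour (satellite detection, annotation). Cluster
granularity here is family-level by construction; on real data a clusterer
may split families into subfamilies, which changes cluster counts but — as
the counts stay proportional across species within each split — perturbs
the additivity and bias statistics far less than it perturbs cluster
identity.

A geometric caveat: similarity is full-length global identity, so two reads
drawn from distant windows of a long monomer connect only through chains of
near-offset intermediates. With the default 300 bp monomer this requires
reasonably dense family coverage; the packaged demo and the recovery
fixtures use satellite-like 91 bp monomers (monomer = read length), where
every same-family pair is directly alignable and ground truth is
unambiguous.

## Numerical and design choices

* Rounding of counts and subsample sizes: half away from zero.
* Subsampling is uniform without replacement, order-preserving,
  deterministic per seed.
* The quality filter is strict ("minimum > 10": a base at exactly Phred 10
  fails); a per-read-mean variant is available by flag.
* Curve ranking key is E ascending (the shared baseline); t or m+p+t are
  selectable. x-axis is ln(cumulative E); a per-cluster variant is
  available from the same table.
* `slope_equality_test` clips tiny negative SS differences (numerical
  artefacts of the two solves) at 0; F = 0 gives p = 1 exactly.
* Degenerate guards: regressions require n ≥ 3 (n ≥ 4 for the plane),
  non-zero predictor variance, and non-collinear predictors; each raises a
  ValueError naming the problem. The pipeline records such failures in
  report.json instead of aborting.
* Determinism: one global seed is split into per-stage seeds via
  `numpy.random.SeedSequence` in a fixed stage order; vertex order in the
  graph is lexicographic read id; identical config + seed reproduces
  byte-identical TSV/JSON outputs.

## Problem sizes

The test suite and the acceptance script run everything at desk scale, as
the package's own standard conditions: 1000 replicates × 100 clusters for
type-I calibration, 300 replicates × 200 clusters for power, ~1200 reads
for cluster recovery (with the exhaustive all-pairs oracle on a 396-read
subsample), 10 families × 50,000 reads/species for the additivity null, and
20 demo pipeline runs of ~1000 pooled reads each.

## Known limitations

* The slope-equality F-test's calibration is regime-dependent (correlated
  stacked errors, above); treat its p-values as approximate.
* Cluster identity with monomers ≫ read length depends on coverage density
  (chaining); abundance statistics are robust to the resulting splits,
  cluster-level recovery metrics are not.
* Contaminant flagging is presence/absence by shared canonical k-mers — a
  deliberate blunt instrument; it does not classify contaminants.
* No claim of output-identity with RepeatExplorer2; published cluster-level
  statistics that depend on its exact clustering are out of scope.
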