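# Methods

## Homology model

`splithom` treats homology calling as deterministic filtering of a
local-alignment table. One alignment record is a single HSP between a
microbial protein-cluster representative (query) and a human protein
(subject), with 1-based inclusive coordinates on both sequences, percent
amino-acid identity, e-value and bitscore, plus both sequence lengths
(required because every filter is a coverage fraction). Gene positions are
ordinal ranks along a contig, not base pairs: the distance between two genes
is the difference of their ranks, which matches how protein-catalog gene
identifiers encode position and makes the neighborhood criterion independent
of gene length.

Multiple HSPs for the same (query, subject) pair are **not** merged in the
full-length branch: each alignment is judged on its own coverage. An
interval-union merge is available (`joint_coverage`) and is exactly what the
split branch uses across neighboring genes, where the union is the point.

## Thresholds

| parameter | default | meaning |
|---|---|---|
| `microbe_cov` | 2/3 (exact rational) | minimum HSP coverage of the microbial protein |
| `human_cov` | 0.70 | minimum (joint) HSP coverage of the human protein |
| `min_microbe_len` | 80 aa | minimum microbial protein length |
| `max_feature_gap` | 3 ranks | maximum gene-rank gap between neighborhood members |
| `contamination_sd` | 3.0 | multiplier k in the mean + k·SD identity ceiling |

All boundary comparisons are inclusive ("at least"), and coverages are
computed as exact rationals so that e.g. a 60/90 alignment sits exactly on
the 2/3 boundary and is retained. The contamination ceiling is estimated on
the records that pass the human-coverage filter (the full-length candidate
distribution), using the sample SD (n−1); a flag
(`cutoff_before_human_cov`) estimates it one stage earlier for sensitivity
analyses. The split branch never re-estimates the ceiling: it reuses the
full-length one frozen, because split fragments have systematically
different coverage geometry and would bias the moments.

## Design choices where the design was open

* **Neighborhood formation.** "Three or fewer features apart" is
  interpreted pairwise (|Δrank| ≤ 3) with transitive chaining: neighborhoods
  are connected components of the gap graph, restricted to one contig and
  strand. Because ranks live on a line, components are maximal runs of
  sorted ranks with consecutive differences ≤ 3; a brute-force graph oracle
  in the tests confirms the equivalence.
* **"Jointly but not individually."** Enforced per final neighborhood as
  max single-member subject coverage strictly < `human_cov`. Strict
  inequality routes boundary cases to the full-length branch, so no gene is
  simultaneously a full-length call and a split member for the same human
  protein at the same locus.
* **Re-checking order.** Joint coverage is evaluated once per
  (human, genome) group, re-checked per neighborhood after the
  feature-distance step, and re-checked again after contamination removal;
  after removal the neighborhood graph is also re-formed, since dropping a
  bridging member can disconnect a component (covered by a dedicated test).
* **Counting unit.** n_full / n_split per human protein default to distinct
  cluster ids (full-length: clusters with an accepted call; split: clusters
  participating in ≥ 1 neighborhood). Distinct genomes and distinct
  neighborhoods are selectable; the choice is stamped into output
  provenance. Split-majority means strictly n_split > n_full.
* **Enrichment.** "Classic" one-sided Fisher per term on true-path-
  propagated annotations, BH-corrected; an "elim"-style variant (most
  specific terms first, their proteins removed from ancestors at p < 0.01)
  is available behind a flag. The headline odds ratio of the 2×2
  localization table is the conditional-MLE estimate with its exact
  conditional CI (what R's `fisher.test` reports); the cross-product ad/bc
  is reported alongside, with a flagged Haldane–Anscombe 0.5 correction when
  a cell is zero. Mitochondrial localization is a `[Mm]itochondr` match on
  cellular-component term names.
* **Faith's PD.** Root-inclusive by convention (sum of branch lengths of
  the union of root-to-tip paths), computed on the midpoint-rooted species
  tree; a root-exclusive flag subtracts the root-to-MRCA path. Midpoint
  rooting verifies that the total branch length and all pairwise tip
  distances are preserved.
* **Ontology-class membership.** A class is the descendant closure of its
  root term; exclusions are gene-level (one annotation anywhere inside an
  excluded subtree removes the protein entirely).

## Synthetic data: what it emulates and what it does not

The generator plants, per (human protein, genome), full-length homologs
with probability `p_full` and split neighborhoods with probability
`p_split` (2–3 fragments, consecutive gene-rank gaps drawn from {1,2,3},
same strand and contig). Planted items pass their filters with margin:
single-HSP coverages are drawn from [0.75, 0.95] on both sides, fragment
unions cover 78–95% of the human protein while each fragment stays well
under 70%, and human protein lengths (300–700 aa by default) are large
enough that every fragment also clears the 80-aa / 2/3-coverage microbial
filter. Genuine identities follow a Normal truncated to [10, 50] whose
**post-truncation** mean and SD equal `identity_mean`=30 and
`identity_sd`=7.27 (the pre-truncation scale is solved numerically), so the
estimated contamination ceiling converges to 30 + 3·7.27 ≈ 51.8%;
contaminants draw from the same Normal truncated to [90, 100]. Bitscores
are a simple increasing function of alignment length × identity — adequate
for best-hit selection, not a model of real score statistics.

Six decoy classes are planted as labeled, mutually disjoint configurations,
one rejection mechanism each: strand-flip, contig-split, gap-4,
undercoverage (joint ≈ 0.5), individual-cover (one member alone ≥ 70%,
which is therefore a *correct* full-length call but must not yield a split
call), and contaminant. Independently planted items are separated by a
buffer of 8 gene ranks so they can never chain into one neighborhood.

Consequences for interpretation: passing the recovery tests shows the
filters implement their definitions exactly and are mutually consistent; it
does **not** show robustness to features of real data the generator omits —
fragmented assemblies, paralog families sharing a neighborhood, chimeric
clusters, multi-HSP alignments, identity distributions with heavy tails, or
annotation errors in feature order.

All randomness derives from one master seed through independent per-table
streams (SeedSequence spawning), so outputs are byte-identical under a
fixed seed and adding a table does not perturb the others.

## Problem sizes

The recovery and decoy analyses run at 200 genomes × 300 human proteins
(≈ 50,000 alignment records, ≈ 12,000 planted neighborhoods), which the
pipeline processes in a few seconds on one CPU; test oracles run at
10⁴ random interval sets, 10³ neighborhood instances (≤ 12 features),
an exhaustive small-cell grid plus a 400-table random sweep of 2×2 tables
with totals up to 200, and 10² random trees with ≤ 64 tips. The
contamination-cutoff check standardizes a 5,000-point sample to mean 30.0
and sample-SD 7.2667 exactly, so the ceiling reproduces 51.8 to the printed
precision.

## Known limitations

* Split homologs spanning contig boundaries are out of scope by
  construction (the strand/contig criterion requires one assembly unit).
* Enrichment numbers are not expected to reproduce any particular
  DAG-decorrelating enrichment tool; "classic" Fisher on propagated
  annotations is the default and the decorrelating variant is approximate.
* The feature-table GFF3 reader ranks CDS features by start coordinate
  within a contig; catalogs whose gene ids already encode rank should use
  the id-suffix dialect instead.
* With fewer than two full-length candidates no contamination ceiling can
  be estimated; calls are then emitted without the identity filter and the
  split stage runs with contamination filtering disabled.
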