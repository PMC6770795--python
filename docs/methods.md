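# Methods

This note documents the models and procedures implemented in `harmonics`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical conventions.

## Period classes

Oscillating transcripts are labelled by closed windows on the fitted period:
24 ± 4 h (circadian, `P24`), 12 ± 2 h (`P12`) and 8 ± 1 h (`P8`); anything
else is `NONE`. The "±" convention does not itself say whether the window
ends belong to the class; both ends are treated as inclusive here so that a
boundary period (e.g. exactly 9 h) is classified rather than dropped. The
windows are disjoint, so the label is unambiguous. Detection of rhythmicity
itself (spectral G-tests, curve fitting) is upstream and out of scope: the
package starts from labelled gene sets.

## Homolog resolution

Candidates are ranked per query lexicographically by (confidence desc, GOC
desc, target %ID desc, query %ID desc, dN/dS, target id asc) and assigned
greedily in ascending query-id order with each target usable once; a query
whose candidate is taken falls through to its next candidate, and a query
with no free candidate is reported unmapped — never imputed, since manual
curation has no algorithmic counterpart.

Open design points, resolved as follows:

* **dN/dS direction.** The cascade lists "dN/dS ratio" without a direction;
  values closest to 0 rank first (purifying selection is the conservative
  signal of true orthology). `dnds_low_better=False` inverts this.
* **Missing scores** rank below any present value at that cascade level,
  so a fully scored candidate always beats a partially scored one on the
  first level where they differ.
* **Serialization of many-to-many conflicts.** Greedy in ascending
  query-id order with a smallest-target-id final tie-break: deterministic,
  order-insensitive to input row shuffles, and injective in both
  directions (checked at construction). Whether a published analysis
  enforced global one-to-one or per-query best is usually unstated; both
  are supported (`one_to_one` flag), one-to-one being the default because
  it is the stricter reading of "resolved homology".

## Co-localization networks and conservation

`build_network` induces, for each chromosome, a clique over the gene-set
members assigned to it; genes alone on their chromosome are isolates and
are removed before statistics, and the pruning is re-applied after every
transformation (relabelling, intersection). Components are verified to be
cliques with edges = Σ C(n_i, 2) on every emitted network. A gene assigned
to two chromosomes, or unplaced/patch contigs, are input errors rather
than silently resolved.

The cross-species comparison relabels the second species' network onto
first-species ids via the inverted homology map and intersects node sets
and edge sets. Because each parent's edge relation is a same-chromosome
equivalence, the intersection relation is again an equivalence and the
result is again a union of cliques. Chromosome *identity* across species is
never required — only co-membership in both genomes.

The **conservation score** is defined as

    100 × (intersection network nodes) / (species-1 network nodes)

rounded half-up to an integer percent. The published values this package is
benchmarked against (65%, 23%, 6%) all follow from the corresponding
printed node-count pairs (33/51, 45/199, 103/1827) under exactly this
formula, which is why it was adopted; no explicit formula is published.

`chromosome_coverage` reports, per chromosome, the fraction of its genes
belonging to the oscillating set, with uncovered chromosomes reported as 0.

## Connectivity permutation test

The null model is node-set resampling against a fixed interaction
reference: `n_iter` sets of size |target| drawn uniformly without
replacement from the reference nodes outside the focal set, each scored by
the number of unique edges joining it to the focal set. Conventions:

* genes present in both sets are removed from the target side before
  counting, so focal self-connectivity cannot inflate the statistic;
* duplicate interaction records collapse to one edge by default;
  `count_records=True` preserves MITAB record multiplicity, since published
  counts from aggregated interaction databases may be record counts;
* SD uses the n−1 denominator; z = (obs − mean)/SD with ±∞ sentinels when
  the null is constant; the empirical p uses the +1/+1 pseudo-count and is
  therefore never 0;
* `exhaustive_null` enumerates all C(|universe|, k) subsets (bounded at
  10⁶) in lexicographic order and is the oracle for the sampler.

Degree-preserving edge rewiring is deliberately not offered; the resampled
null matches the set-resampling design the package models.

## Stability statistics

All group comparisons are rank-based. "Kruskal–Wallis with Residue Number
as covariate" has no standard definition; it is implemented as rank
residualization — rank-transform the feature, regress by least squares on
the rank-transformed covariate, run tie-corrected KW on the residuals
(χ², k−1 df). This is an interpretation, not a published formula; the
`adjust_for_residues` flag disables it, a constant covariate reduces it
exactly to the plain test, and Residue Number itself is never adjusted
against its own ranks. Dunn's z uses the pooled-rank formula with the
standard tie correction

    z_ij = (R̄_i − R̄_j) / sqrt[(N(N+1)/12 − ΣT/(12(N−1))) (1/n_i + 1/n_j)]

with two-sided normal p-values; the FDR family is Benjamini–Hochberg over
the group pairs within each feature (the family is not published;
cross-feature correction can be applied downstream if preferred). Spearman
matrices are tie-aware, symmetric with unit diagonal, and pairs involving a
constant column are reported missing. Two-sided tests throughout.

## Synthetic-data generator

The generator's defaults define the conditions the package is tested
under; they mirror the motivating study's scale: 20 chromosomes, a
3000-gene universe, period sets of 56 / 205 / 2054 genes, a 200-node PPI
at edge probability 0.02, and energy laws from the published group
statistics (`FOLDX_GROUP_STATS`, 18 features × 4 groups). Sizes that are
nowhere published were fixed once as package choices: the circadian
reference subnetwork (`ncrg_size`) at 20 genes, and 350 non-oscillating
proteins in the energy table.

**Two-species assignment.** Each species-1 chromosome has one syntenic
partner chromosome in species 2 (an injective partner map). Each gene
retains that partner with probability `conservation_rho`; otherwise it is
dispersed, and the dispersed genes of a chromosome go to *distinct*
non-partner chromosomes, so broken synteny never re-creates
co-localization among former neighbours. `conservation_rho` is therefore a
per-gene synteny-retention probability (pair co-localization probability
rho²), and the conservation score of the full pipeline estimates rho up to
a vanishing rho(1−rho)^(m−1) term, m the per-chromosome clique size — with
the default 50-gene cliques the bias is < 10⁻³ across the tested range.
This requires a species-2 chromosome partition finer than real genomes
(`n_chromosomes_species2`, default: species-1 count + clique size + 1); on
real genomes, chance co-localization of dispersed genes would inflate a
node-based conservation estimate, which is a known limitation of the
statistic itself.

**Homolog candidates.** Every gene has a true target (its species-2
counterpart) with confidence 1; a `multi_map_rate` fraction of genes gains
1–3 decoys with confidence 0 and randomized GOC/%ID/dN/dS. The true
candidate is strictly best on the first cascade level by construction, so
cascade resolution is verifiable (tests require ≥ 99% planted recovery).

**PPI.** Erdős–Rényi background at `ppi_edge_prob`; focal↔target pairs use
min(1, p·(1 + `enrichment_delta`)) (δ = ∞ saturates the cap). Cross-edge
counts follow the binomial closed form; with δ = 0 the focal set is
exchangeable with random sets (null calibration), and z responds
monotonically to δ.

**Energy tables.** Each feature is sampled independently per group from a
normal law with the configured mean/SD; Residue Number is rounded with a
floor of 30 residues. Independence means the generator does not reproduce
the strong between-feature correlations of real energy decompositions
(almost every term scales with protein size); passing tests therefore
validate the test statistics and their calibration, not any claim about
feature dependence in real proteins. Real energy terms are also not
normal; the normal emulation matches only the first two moments.

**Seeding.** One global integer seed; each sub-generator derives its
stream from a fixed offset via `numpy` `SeedSequence`-style keys, so
modules regenerate independently and byte-identically (same-seed file
hashes are asserted in tests).

## Pipeline

Stages exchange plain files (TSV, one-id-per-line sets, minimal MITAB 2.5,
SIF/GraphML, JSON) and re-run independently from intermediates. The run
manifest records the config snapshot, seed, per-stage status/timing and a
SHA-256 per output file; manifest hash equality across repeated runs is
the determinism regression test. Problem sizes in the test-suite and the
acceptance script (e.g. 1000-gene genomes over 50 seeds, 100-replicate
calibrations, 10⁴-draw Monte-Carlo oracles) were chosen as the smallest
sizes at which the binomial/SE tolerances are sharp enough to be
informative.

## Known limitations

* The conservation score is node-based; an edge-based score would weight
  large cliques differently. Only the node-based form reproduces the
  published percentages.
* Intersection rows published alongside the benchmarked node counts for
  the 12-h and 24-h sets report more components than nodes — impossible
  for simple graphs and presumably a table misprint; those cells are not
  modelled.
* The resampling null conditions on the observed reference topology; it
  does not model uncertainty in the interaction snapshot itself.
* Published group sizes behind the energy statistics are unknown, so
  exact p-value reproduction is out of reach by design; the package
  targets calibration and direction/recovery instead.
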