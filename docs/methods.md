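# Methods

## The model

`offtargetnet` operationalizes a simple and widely used hypothesis from
network pharmacology: the proteins that physically interact with a drug's
target — its *first neighbors* in the binary protein–protein interaction
(PPI) graph — are candidate off-targets for that drug, and drugs that bind
the same target or its neighbors are candidates for drug–drug
interactions.  The package builds, around a set of focal drugs, a
heterogeneous **protein–drug network**:

* protein nodes: the focal drugs' targets, plus every first neighbor of
  those targets (strictly one hop — neighbors of neighbors are never
  pulled in);
* drug nodes: the focal drugs themselves (optionally collapsed into one
  node per drug-class group) and every other drug binding any included
  protein;
* edges: `binds` (drug → protein) and `ppi` (the *full induced* PPI
  subgraph on the included proteins, so neighbor–neighbor edges count,
  not only target–neighbor spokes);
* self-pairs: a protein interacting with itself (a dimer) is stored as a
  flagged edge, but a protein is never its own first neighbor.

Drugs connect only to proteins; there are no drug–drug edges.  Only
drug→target rows matching the configured organism (default `HUMAN`) enter
a build, so viral targets in a drug table are listed but excluded from
human networks.

## Quantities computed

**Topology.**  Degree (a self-pair contributes 1 by default, configurable
to 2), unnormalized shortest-path betweenness (pair counts; a
`2/((n−1)(n−2))` normalization flag is available), closeness with the
standard component scaling for disconnected graphs
(`(r/Σd)·(r/(n−1))`, r = reachable others), and diameter/radius as
eccentricity extrema.  All distances are unweighted and ignore edge
types and self-pairs.  On disconnected networks, diameter and radius are
computed on the largest connected component and reported together with
the component count, so the restriction is visible to the caller.

**Neighborhood similarity.**  Two drug networks are compared by the
Jaccard index of their protein sets, summarized as a contingency row
(M11 shared, M10 unique to A, M01 unique to B):

    J = M11 / (M11 + M10 + M01),   dJ = 1 − J.

By default the compared sets are targets ∪ neighbors (a flag restricts
to neighbors only); the choice is recorded in the run manifest.  A zero
denominator (two empty sets) is *undefined* rather than silently 0 —
Table-style outputs never legitimately produce an empty union, so a zero
would mask input errors.  Indices are printed to 6 decimals.

**Structural similarity.**  The Tanimoto coefficient — the same
statistic as the Jaccard index, applied to molecular feature sets — is
computed over a deterministic path-based fingerprint: every linear
atom–bond path of length 1..7, hashed to an integer feature id
(unfolded, so folding collisions cannot occur).  Fingerprint schemes are
implementation-defined in general, so absolute Tanimoto values are only
comparable within one scheme; the package therefore treats published
ranges from other tools as scheme-dependent and does not target them.
Degenerate molecules without bonds (e.g. methane) have empty
fingerprints, and a Tanimoto between two empty fingerprints is
undefined.

**Over-representation.**  Each annotation term is tested individually
(term-for-term): with k study hits out of n study genes against K
background hits out of N background genes, p = P(X ≥ k) for
X ~ Hypergeometric(N, K, n), which is identical to the one-sided
(greater) Fisher exact test — the identity is asserted numerically in
the test suite.  p-values come from scipy's numerically stable
implementation.  Benjamini–Hochberg step-up adjustment
(q(i) = min over j ≥ i of m·p(j)/j, capped at 1) is applied over all
tested terms (K ≥ 1 in the background); the implementation is a direct
numpy transcription cross-checked against
`statsmodels.stats.multitest.multipletests` in tests.  The background
defaults to *all* supplied genes, annotated or not; a flag restricts to
annotated genes (tool conventions differ, so both are offered and the
default is stated).  There is no ontology-graph propagation: annotations
are used as given.  Fold enrichment is (k/n)/(K/N); report rendering
prints values strictly above 100 as `>100`.

**Proteoforms and diseases.**  A proteoform count is the plain sum of
PTM events, allelic variants, and splice transcripts.  PTM breakdowns
pool events over a protein set across a fixed vocabulary of 11 UniProt
feature classes (unknown categories are rejected at parse time) and
report percentages rounded half-up to two decimals; a set with zero PTM
events has an undefined breakdown.  Disease rankings aggregate
per-disease scores across the queried genes with `max` by default (a
single strong association should surface a disease; `mean` is a flag)
and break ties by (score descending, label ascending) for determinism.

## Synthetic data: what it emulates and what it does not

The generators replace live DrugBank/PICKLE/GO/DisGeNET-style services
with seeded flat-file snapshots whose ground truth is recorded at
generation time.

* **Interactome** — preferential attachment: each new node attaches to
  `m` existing nodes with probability ∝ degree+1.  Chosen over
  Erdős–Rényi because real interactomes are hub-dominated (the test
  suite pins max degree ≥ 3× median at realistic sizes); `m = 1` yields
  a tree.  A fraction of nodes receive self-pairs to emulate dimers.
  Defaults: 1000 proteins, m = 3, 5% self-pairs.
* **Drugs** — a 6-member class sharing the top hub receptor (two members
  get a personal second target), mirroring the structure of a real drug
  class; singleton drugs on random proteins; 40 drugs total.  One
  non-human (viral-target) row exercises the organism filter.
* **Planted neighbor overlap** — two extra drugs bind two *fresh* target
  nodes wired to a shared pool and private pools of chosen sizes, so the
  pair's expected (M11, M10, M01) is exact set arithmetic, not a sampled
  approximation.  Defaults: union 40, overlap ρ = 0.5.
* **Annotations** — 50 terms at a uniform 5% background rate, plus one
  planted term given exactly the study/background hit counts that meet a
  requested fold (default 5) on the focal class's neighborhood; a
  requested fold of 1 plants nothing (the null model).  Unachievable
  folds (k would exceed n) raise a configuration error rather than being
  silently clipped.
* **Proteoforms** — Poisson event counts with a multinomial category
  mixture (defaults approximating a realistic PTM profile dominated by
  modified residues), plus Poisson allelic/splice counts.
* **Diseases** — Beta(2, 5)-distributed scores scaled below 0.9, with
  one planted disease at 0.95 on a chosen gene, so it dominates any
  ranking that includes that gene.

All draws flow from one integer seed through per-component substreams;
reruns are bit-identical.  What passing tests on this data *show* is
that the pipeline's set logic, counting, statistics, and report plumbing
are exact; what they *cannot* show is agreement with any specific
database snapshot — real interactomes have evidence-level structure,
annotation semantics, and identifier noise the generators deliberately
omit.  Published network sizes and mean degrees from specific database
snapshots are therefore out of scope and never asserted.

## Numerical choices and degenerate inputs

* Percentages: decimal half-up rounding at 2 decimals (not banker's
  rounding), matching the two-decimal reporting convention.
* Undefined-over-zero: empty-union Jaccard/Tanimoto, mean neighbor
  degree of a neighborless target, and zero-event PTM breakdowns raise
  `UndefinedResultError` instead of returning 0.
* Ties: enrichment rows sort by (p, q, term id); disease rankings by
  (score desc, label asc); comparisons by (label A, label B); the
  largest connected component breaks size ties by the lexicographically
  smallest node tuple.  All outputs are order-invariant to input row
  order.
* The run manifest (input checksums, all parameters, seed, version) is
  hashed and embedded as a header comment in every output table; two
  runs with equal manifests produce byte-identical bundles (asserted in
  tests).

## Problem sizes used by the test suite

Oracle equivalence runs 200 random graphs of ≤ 8 nodes against
exhaustive path enumeration and all hypergeometric tails for backgrounds
N ≤ 12 against full draw enumeration.  Statistical calibration uses 1000
null replicates and 500 planted-signal replicates at 300 proteins × 40
terms (study size 20, fold 5).  Pipeline closure runs the full snapshot
at the default study conditions (1000 proteins, 40 drugs).  These sizes
were chosen so every suite is exact or tightly bounded while the whole
suite completes in seconds.

## Known limitations

* Identifier spaces are taken as pre-mapped accession strings; there is
  no aliasing/ID-mapping layer.
* No evidence-level or directness filtering of PPI edges: the reader
  ingests whatever snapshot is supplied.
* No ontology DAG handling, no weighted edges, no eigenvector-style
  centralities, and no 3D/pharmacophore structural similarity.
* The path-based fingerprint is a reasonable default, not a calibrated
  reproduction of any external tool's descriptor; absolute Tanimoto
  values should not be compared across tools.
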