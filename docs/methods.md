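# Methods

## The model

funact treats drug-action discovery as per-drug supervised ranking over a
typed heterogeneous network with three node types — molecules (genes whose
proteins a drug binds), functions (GO terms) and phenotypes (diseases) — and
18 edge types drawn from curated databases and literature co-occurrence.
A drug enters the network through its targets (molecules) and indications
(phenotypes).  For every candidate function the linkage to those two access
points is summarised by meta-path features, and a per-drug SVM learns which
linkage patterns characterise the drug's known (positive) functional
actions against inferred negatives.

A **meta-path** is a sequence of node types and edge types; each concrete
path instantiates exactly one meta-path.  Target-side meta-paths run
molecule→function with at most 3 steps, indication-side meta-paths
function→phenotype with at most 2 — the points at which most known
drug-affected functions sit within reach of targets and indications while
the path space is still enumerable.  Directed edge types may be traversed
against their direction; the reverse traversal is a distinct step in the
meta-path identity (marked `<` in canonical strings).  Path instances are
**simple paths** (no repeated node): on undirected relations, walks would
otherwise inflate counts with back-and-forth oscillations.  Paths to or
from multiple targets/indications are pooled before statistics are taken,
giving one column per meta-path rather than per endpoint.

### Path-degree product

For a path p with hops (u→v), and degree taken with respect to the hop's
edge type and traversal orientation,

    PDP(p) = Π over hops  deg_out(u)^-w · deg_in(v)^-w ,   w ≥ 0.

Intermediate nodes therefore contribute both their arriving and leaving
degrees.  Every factor's base is ≥ 1 (the traversed edge itself
contributes), so PDP ∈ (0, 1]; `w = 0` gives PDP = 1 and collapses the PDP
sum onto the path count; PDP is non-increasing in w.  The default damping
exponent is **w = 0.5**.  A `global` degree mode is also provided, reading
degrees across all edge types at once (zero degrees treated as 1) for the
coarser in/out-degree formulation; the edge-type-specific (`metaedge`) mode
is the default because it keeps the (0, 1] guarantee.

Each observed meta-path yields three features per function: path count,
PDP sum and PDP max.  Meta-paths with no instance for any evaluated
function are dropped from the matrix.

### Labels on the GO hierarchy

Positive examples are GO terms; they are expanded by ancestor closure
(true-path rule) with namespace roots excluded.  A descendant-closure mode
exists for the converse reading.  Negatives are inferred by the
zero-topology-similarity rule: a term is negative when its ancestor closure
(term included) intersects each positive's closure in exactly one node —
necessarily the namespace root.  The rule is applied per namespace and only
when that namespace holds ≥ 3 positives; roots themselves are excluded,
since the root trivially zero-matches everything.  Only `is_a` edges are
used by default (`part_of` optional).  The hierarchy is never part of the
traversal network.

### Feature selection and the SVM

"Linear-regression coefficients per feature" is implemented as univariate
OLS of the label on each z-scored column over the labelled rows only
(candidates are excluded to avoid leakage).  With standardized x the slope
is cov(x, y); columns are ranked by |slope| (a strong negative association
is as informative to an SVM as a positive one), ties broken by column
string, constant columns ranked last and never selected.  Top k = 20 by
default.  Selection is refit once per drug on all labelled examples; a
strict `select_in_fold` mode refits it inside every CV training fold.

The SVM is a soft-margin SVC with RBF kernel, C = 1, gamma = `scale`
(1 / (n_features · feature variance)) and class-balanced weights, since
positives are typically few.  Features are standardised with training-fold
statistics only.  Cross-validation is stratified 4-fold over 20 iterations;
iteration r reshuffles folds with seed + r; the reported mean ± sd pools
all folds × iterations (80 values).  Ranking uses the decision margin, not
probabilities — only the ordering matters for AUROC and top-k lists.

## The shipped schema and the calibrated meta-path space

The 18-edge-type schema is shipped as an editable TSV
(`src/funact/data/multilevel_schema.tsv`): edge type, node-type pair, directedness.
Several published renderings of this table are ambiguous about which
node-type pairs two resources cover; the shipped assignment is the unique
one whose per-pair relation counts reproduce the published column totals
exactly (notably PhenoGO spans both function-function and
function-phenotype, and EndoNet's positive-decrease spans
molecule-molecule and molecule-function).

Counting the meta-path space depends on one further convention: whether an
undirected relation's two traversal orientations are identified or kept
distinct in the meta-path identity.  Under plain unordered storage the
schema spans 2,865 meta-paths (molecule→function ≤ 3 plus
function→phenotype ≤ 2).  The **calibrated convention**
(`multilevel_schema_calibrated.tsv`) retains the source-row orientation of undirected
relations from the CODA resources and the UMLS NCI thesaurus — sources
whose rows are ordered — and generates mechanical reverse steps for them,
while OMIM, MedlinePlus, MTHMST and MEDLINE co-occurrence (symmetric by
construction) stay unordered.  Orientation retention only affects relations
on homogeneous node-type pairs (M–M, F–F, P–P), where the two orientations
become distinct steps; the calibrated space is 3,732 meta-paths and
3 × 3,732 = 11,196 candidate features, matching the published totals.  This
is a calibration, fixed once and documented here: no uniform all-or-nothing
convention on the reconciled table reproduces those totals.  Both schema
files are inputs — any recalibration is a one-line TSV edit — and the
enumerator is cross-checked against an independent dynamic-programming
counter under every convention in the test suite.

## The synthetic benchmark

Real multi-level networks cannot be redistributed here, so the generators
in `funact.synthetic` define the study conditions.  The network uses a
six-relation schema (one undirected relation per node-type pair plus a
directed molecule→molecule regulation type) with fixed edge counts: 60
molecules / 140 functions / 30 phenotypes, 120 PPI edges (mean degree 4),
120 annotations, 40 regulations, 80 function-function, 60
function-phenotype and 40 phenotype-phenotype edges — dense enough for
background paths to exist, sparse enough that they stay uninformative.

A drug case has 2 targets, 2 indications, 20 positives, 20 negatives and
100 candidates, 5 of which are planted unlabelled true functions.  Signal
is planted by wiring a function to each target through a fresh
PPI + annotation bridge (the target-side signal meta-path `M-PPI-M-Annot-F`)
and directly to each indication, with probability 0.9 for
positives/planted functions versus 0.05 background for everything else.
Setting signal = background yields a valid null construction.  All
generators are pure functions of (config, seed); a single integer seed
derives independent per-component streams.

What the generator does *not* emulate: scale-free degree structure,
modularity, co-occurrence frequency statistics, or correlated annotations.
Passing benchmarks therefore demonstrate that the pipeline recovers linkage
signal of the planted form at these sizes — not performance on real curated
networks.

## Numerical and design choices

* Determinism everywhere: meta-paths sort by (length, canonical string),
  path instances by node-id sequence, candidate ties by function id; a
  fixed seed reproduces CV reports and rankings bit-for-bit.
* Duplicate edge rows collapse; self-loops are rejected (meaningless for
  target→function linkage); undirected duplicates collapse regardless of
  row order.
* Degrees of undirected relations count incident edges in both
  orientations, so out- and in-degree coincide.
* z-scoring uses population standard deviation; constant columns are
  assigned slope 0 rather than NaN.
* CV fold counts are reduced (with a recorded warning) when a class is
  smaller than the fold count; below 2 per class the split is refused.
* The permutation null is assessed on the fixed selected feature set:
  labels are permuted after selection, so the null isolates the SVM/CV
  stage.  Refitting selection on permuted labels adds the optimistic bias
  of in-sample selection and is available through the strict in-fold mode.

## Known limitations

* The published meta-path-space total is reproduced only under the
  documented calibrated orientation convention; the plain reconstruction
  gives 2,865.
* Univariate selection ignores feature redundancy; 20 duplicated columns
  of one signal can crowd out weaker independent signals.
* The default selection-before-CV protocol leaks labelled information into
  the CV estimate (the strict in-fold mode avoids this at higher variance).
* Path search is exhaustive per (function, meta-path); it is sized for
  networks up to a few thousand edges, not for full curated networks with
  millions of relations, where per-meta-path sparse matrix products would
  be the natural optimization.
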