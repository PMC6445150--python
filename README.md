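# funact

Meta-path based prioritization of **functional drug actions** — the GO terms
(biological processes, molecular functions, cellular components) that a drug
affects — on a **multi-level biological network** of molecules, functions and
phenotypes.

Most computational approaches to drug-affected functions rely on molecular
networks alone, yet a large fraction of GO terms have no associated gene and
are invisible to them.  funact instead works on a typed heterogeneous network
that also contains function-function, function-phenotype and
phenotype-phenotype relations, and uses a drug's two access points — its
**target** proteins (molecules) and its **indications** (phenotypes) — to
score every candidate function.

## Method

For a candidate function *f*, funact extracts all heterogeneous paths from
the targets to *f* (length ≤ 3) and from *f* to the indications (length ≤ 2)
and groups them by **meta-path** — the type-level sequence of node types and
edge types, e.g. `M-[CODA|BioGRID|undirected_link]-M-[CODA|GO|undirected_link]-F`.
Each observed meta-path contributes three features:

* **PC** — the path count;
* **Σ PDP** — the sum of path-degree products, where
  `PDP(path) = Π over hops (deg_out(u)^-w · deg_in(v)^-w)` with damping
  exponent `w = 0.5`, discounting paths through hub nodes;
* **max PDP** — the most specific single path.

Features are ranked by the magnitude of the univariate OLS slope of the
label on the z-scored column, computed on labelled example functions
(positives from curated drug descriptions; negatives inferred as GO terms
sharing only the namespace root with every positive — the
zero-topology-similarity rule, applied per namespace when ≥ 3 positives
exist there).  The top 20 features feed a per-drug soft-margin SVM
(RBF kernel, class-balanced), evaluated by stratified 4-fold
cross-validation over 20 iterations (AUROC), and unlabelled functions are
ranked by the decision margin.

## Worked example

Everything runs on seeded synthetic data; no downloads are required.

```sh
funact simulate --seed 4 --out demo
funact run --nodes demo/nodes.tsv --edges demo/edges.tsv \
           --schema demo/schema.tsv --case demo/drug_case.json \
           --out demo_run --seed 4
```

Output:

```
[cv] mean AUROC 0.966 ± 0.062 (4-fold × 20)
1       F0004   0.9424
2       F0113   0.8853
3       F0035   0.8407
4       F0088   0.8212
5       F0032   0.7388
6       F0139   0.7029
7       F0105   0.5278
8       F0095   0.4817
9       F0131   0.4763
10      F0108   0.4502
```

The simulated case plants five unlabelled true functions among 100
candidates (`demo/ground_truth.json` lists them: F0004, F0035, F0105,
F0113, F0133); four of the five appear in the top 10.  The cross-validated
AUROC (0.966 ± 0.062 over the 80 held-out folds) measures how well the
model separates the 20 positive from the 20 negative example functions.
`demo_run/` also contains `features.tsv` (the per-function feature triples),
`selection.tsv` (ranked coefficients), `cv_report.json` and `manifest.json`
(config hash and seed for bit-for-bit reproduction).

The library mirrors the CLI: `generate_network` / `generate_drug_case`,
`build_feature_matrix`, `select_features`, `cross_validate`,
`rank_candidates`, or the one-call `run_case` (see `funact/pipeline.py`).

## The multi-level schema

The shipped schema (`src/funact/data/multilevel_schema.tsv`) catalogues 18 edge types
over molecule/function/phenotype node pairs: curated molecular relations
(BioGRID, RegNetwork, TRANSFAC, KEGG, EndoNet), GO annotations, PhenoGO,
four UMLS resources (NCI, OMIM, MedlinePlus, MTHMST) and binarized MEDLINE
MeSH co-occurrence.  Directed relations can be traversed in reverse as
distinct meta-path steps.  With the calibrated orientation convention
(`multilevel_schema_calibrated.tsv`; see docs/methods.md) the enumerator spans
**3,732 meta-paths** (11,196 features):

```sh
funact enumerate --calibrated
# target-side: 3672  indication-side: 60  total: 3732  features: 11196
```

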