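# Methods

## Scope and model

`imglkit` reconstructs, as a tested pipeline, the inference chain that
turns multi-protocol differentiation transcriptomes into (i) similarity /
divergence scores of induced microglia-like cells (iMGL) versus in vivo
microglia, (ii) a microglia-specific marker panel, and (iii) a consensus
master-TF circuitry obtained by propagating signed regulatory cascades and
scoring each TF's Master Regulatory Index (MRI). The chain operates on
bulk RNA-seq counts; read alignment, quantification, QC scoring,
gene-ontology enrichment and the curation of the TF→target edge resource
are upstream/external and out of scope — the package consumes a count
matrix, a metadata table, and any signed edge list.

## Preprocessing

The multi-study matrix is assembled over the union of gene identifiers
(missing entries 0; duplicated sample ids are an error). Genes with zero
counts in *all* samples are removed once, on the global matrix; one read
is then added to every remaining cell; finally the matrix is
quantile-normalized: each column sorted, the reference distribution formed
as the rank-wise mean across columns, and every value mapped back through
its within-column rank. Jointly normalizing all samples (rather than per
batch) is the package default; callers can subset columns to override.

**Ties.** Two conventions are implemented. The default, `ties="stable"`,
assigns tied values consecutive reference values in stable input order, so
every output column carries *exactly* the reference multiset and repeated
normalization is a fixed point to machine precision — properties the test
suite asserts at 1e-9 on integer-count fixtures, which always contain
ties. `ties="average"` gives tied values the mean of the reference values
over their tied rank span (the pheatmap/limma-style convention); it breaks
exact multiset equality whenever tie patterns differ between columns,
which is why it is not the default.

## Differential expression

Each (protocol, cell type) group is contrasted against its own protocol's
iPSC samples; protocols lacking iPSC data use the designated fallback
protocol's iPSC samples. The test runs on the quantile-normalized
pseudocounted matrix with values rounded back to integers — deliberately
mirroring a pipeline that feeds normalized counts to a count-model test.
This is statistically unorthodox (normalization equalizes the marginal
distributions being compared), so the engine is held to an explicit
contract instead of a brand: approximately uniform null p-values
(fraction < 0.05 within [0.035, 0.065] at 2000 genes, 6 vs 6,
dispersion 0.05) and ≥ 95% recovery of planted 4-fold effects at
padj < 0.01. The implementation is Welch's t on log2 values with
Benjamini–Hochberg adjustment per contrast; both contract properties are
enforced by tests, and a genuine negative-binomial GLM (pydeseq2) serves
as an independent cross-check on planted fixtures in the test suite. The
calibration and power checks run the test on pseudocounted raw counts:
a two-group simulation has no technical amplitude differences to remove,
and cross-sample normalization is exercised by the full-pipeline checks
instead. With a single sample per side no p-value exists; calls fall back
to fold-change alone and the result is flagged.

Up/down calls: fold-change > 2 (resp. < 1/2) AND padj < 0.01, both
configurable.

## Identity scoring

* `%Common = |up(iMGL) ∩ up(control)| / |up(iMGL)| × 100`,
  `%Divergence = 100 − %Common`; purely set-based, undefined (error) for
  an empty iMGL up-set.
* Markers: `up(fetal microglia) \ ⋃ up(negative controls)`, with the
  negative-control up-sets derived by the same DE machinery and thresholds
  as the iMGL contrasts (the thresholds are not restated separately for
  controls anywhere, so reusing them is the parsimonious choice). A
  reported ">4-fold" annotation on marker displays is treated as display
  information, not a selection filter.
* PCA: centered PCA (full SVD) of samples over log10 normalized values of
  a caller-chosen gene subset — the pipeline uses the fetal-microglia
  up-set. The subset is an explicit input because upstream gene-count
  bookkeeping of that set is ambiguous in published descriptions.
* Heatmap: marker × group log2FC matrix, hierarchically biclustered with
  Euclidean distance and average linkage (the pheatmap-compatible default
  family; the linkage method is configurable), deterministic leaf order.
  Markers untested in a contrast are recorded as 0 and flagged.

## Cascade propagation and MRI

A protocol's network keeps the edge-resource genes with |log2FC| > 2
(node status = fold-change sign) and the edges whose two endpoints
survive. From a seed TF, the predicted status of a node along a path is
the seed's status composed with the product of edge signs; a node is
*coherent* when prediction matches observation, and propagation continues
only through coherent nodes (an incoherent node absorbs the signal). The
adopted reference semantics is **any-coherent-path**: a node is coherent
if *some* path of coherent intermediates predicts it correctly.

Because a node's observed status is fixed, the sign parity any admissible
path must carry is determined per node (parity(v) = status(v) ×
status(seed)); an edge u→v is traversable iff parity(u) × sign(u→v) =
parity(v). The coherent set is therefore exactly the reachability closure
in this filtered edge set, so a single visited-once BFS *is* the fixpoint:
no iteration is needed, termination is O(V+E) on any graph including
cycles. The test suite still verifies this equivalence against an
independent exhaustive simple-path oracle on a seeded ensemble of small
random signed graphs, for every possible seed TF.

`MRI(tf) = |coherent set| / |network nodes| × 100`, seed excluded from its
own coherent set, denominator = all nodes of the reconstructed network.
TFs (nodes with out-degree > 0) are ranked by MRI, ties broken by coherent
count then gene id. "Significant MRI" has no published cutoff; the default
rule — MRI ≥ 1% and ≥ 5 coherent targets — is permissive, configurable,
and echoed into the output metadata. Unsigned edge lists are accepted with
an all-activating interpretation behind an explicit flag.

## Consensus and regulome

Presence = significant MRI and upregulated status (downregulated TFs can
be admitted with a flag; the consensus concept targets over-expressed
masters). TFs present in ≥ 3 protocols are retained and classified
relative to the focal protocol: **a** present everywhere; **b** focal +
≥ 2 others but not all (the "not all" exclusion is required for the groups
to partition); **c** ≥ 3 non-focal protocols and absent in focal. The
regulome of chosen seed TFs is the union over protocols of first-neighbor
edges from a seed to any consensus TF, annotated with group labels and
contributing protocols. When no seeds are given, the pipeline defaults to
the two group-a TFs with the highest mean MRI — on fixtures this recovers
the planted master pair without being told.

## Synthetic study conditions

The generator emulates the study design end-to-end. Defaults (the study
conditions; all configurable):

| parameter | default | meaning |
|---|---|---|
| n_genes | 2000 | gene universe |
| protocols | 6 (Abud, Muffat, Douvaras, McQuade, Trudler, Chen) | Chen = focal |
| own iPSC | Abud, Trudler, Chen | others fall back to Abud iPSC |
| n_reps_per_group | 6 | replicates per (protocol, cell type) |
| markers | 120 | up in fetal/adult microglia and (partially) iMGL |
| shared immune program | 150 genes | up in controls, subtracted from markers |
| negative-control private programs | 5 × 40 genes | make subtraction nontrivial |
| masters | 2 (wide + narrow) | the seed-TF pair |
| intermediates | 4 focal-deficient + 4 partial | TF layer under the wide master |
| targets | 8 per intermediate, 20/40 direct | cascade leaves |
| edge signs | 80% activation / 20% repression | master→intermediate edges always activating |
| extra edges | 10% of tree edges (+40 decoys among background genes) | cycles and filtering exercised |
| nb_dispersion | 0.05 | NB variance = μ + 0.05 μ² |
| fold_change_up | 8 | planted program fold |
| tf_fold_boost | 2 | extra fold on the planted TF layer |
| base_mean_range | (20, 2000), log-uniform | baseline expression |
| library_size_range | (0.8M, 1.2M) | expected column total, program-free composition |

Notable choices, each made from the mechanism rather than from any single
test outcome:

* **fold_change_up = 8.** The network stage keeps nodes at |log2FC| > 2
  (i.e. 4-fold); a planted 4-fold effect would sit exactly on that
  threshold and be retained by a coin flip, so detectability-by-
  construction requires the planted fold to clear the strictest downstream
  threshold with margin. Quantile normalization additionally compresses an
  8-fold planted effect to an observed log2FC of ~2.3–3.
* **Baseline headroom.** A gene already at the ceiling (floor) of the
  dynamic range cannot express an up (down) fold on a rank-preserving
  scale, so planted genes draw their baseline from a range leaving room
  for one full effective fold.
* **tf_fold_boost.** The TF layer emulates over-expressed factors (the
  focal protocol drives differentiation by TF overexpression), and single
  genes have no redundancy against normalization compression; masters and
  intermediates therefore carry twice the program fold.
* **Focal deficiency** is modeled purely as absence of activation: the
  deficient intermediates (and, since the cascade does not fire, their
  private targets) have no fold change in the focal iMGL group. No
  transcript-truncation mechanics are modeled.
* **Partial intermediates** skip two random non-focal protocols each, so
  consensus group b is populated and group a is exactly the master pair.
* **Library size** scales the expected column total under the program-free
  composition; planted fold changes therefore reproduce exactly in
  group-mean ratios, while planted mass shifts totals slightly (the usual
  composition effect), so exact column-sum equality holds under a null
  truth.

What the generator does **not** emulate: batch/lab effects beyond library
size, gene-length and GC biases, correlated gene-gene noise, isoform
structure, partially overlapping cell-type programs, or an edge resource
with false edges at realistic density. Passing the planted-recovery tests
therefore demonstrates the correctness of the computations under the
declared noise model, not performance on real compendia.

## Problem sizes and determinism

The default fixture is 2000 genes × 108 samples and analyzes in ~0.2 s;
multi-seed checks use 10–20 fixtures and the oracle ensemble uses 100
graphs of ≤ 10 nodes, keeping the whole suite and the acceptance script
within seconds on one CPU. Every random draw flows from a single integer
seed through `numpy.random.default_rng` seed sequences; identical configs
yield byte-identical fixtures, and the pipeline manifest records the
config hash plus SHA-256 of every output so reruns are verifiably
identical.

## Known limitations

* Testing quantile-normalized values with a two-group location test
  inherits the caveat described above; effect-size estimates are
  rank-compressed relative to raw-count GLMs (the cross-check test bounds
  the discrepancy on planted effects).
* The any-coherent-path cascade semantics is one fixed convention among
  several plausible ones for multi-path/cycle conflict handling; the
  package documents and tests it rather than claiming equivalence to any
  external tool's internals.
* With one replicate per side the DE stage degrades to fold-change-only
  calls, flagged but unavoidable.
* MRI denominators count all network nodes, so MRIs from networks of very
  different sizes are comparable only as fractions, not as absolute reach.
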