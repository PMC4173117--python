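# Methods

## Pipeline model

The package models a cluster heatmap as three blocks: a **data block**
(feature names plus a row dendrogram whose leaves carry the displayed
feature vectors and the IDs of the data points they represent), an optional
**metadata block** (per-row annotations keyed by leaf ID, never clustered),
and an optional **column dendrogram** over the feature axis.  All downstream
operations — exploration queries, rendering, serialization — consume this
document; the pipeline (`cli.api_run`) is the single code path that builds
it, whether invoked from Python or from the console script.

## Clustering

Agglomerative clustering starts from singleton clusters and repeatedly joins
the pair at minimal inter-cluster distance.  `compute_linkage` delegates to
`scipy.cluster.hierarchy.linkage`; `naive_linkage` re-derives the same merge
sequence from first principles in O(n³), recomputing every inter-cluster
distance per step from the linkage definition: single/complete/average from
the cross-pair point distances, Ward from the between-centroid form
√(2·|A||B|/(|A|+|B|)) · ‖c_A − c_B‖ (so two singletons merge at their
Euclidean distance), centroid from cluster means, median from recursively
maintained midpoints, and weighted (WPGMA) from its defining recursion.
The dual route is the headline correctness argument: on random continuous
data the two must produce identical merge trees with heights equal to within
1e-9, and the tests and the acceptance script assert exactly that over
hundreds of instances.

Determinism details:

* **Tie-breaking** in `naive_linkage` merges the pair with the
  lexicographically smallest (min index, max index).  SciPy orders ties by
  its own internal scheme, so oracle-equality is asserted on continuous
  random data where exact ties have probability zero.  One systematic
  degenerate case is excluded by construction: with only two features the
  correlation distance of centred vectors is always exactly 0 or 2, so every
  instance is maximally tied; equality tests for the correlation metric use
  at least three features.
* **Child orientation**: the left child is the member whose smallest
  original leaf index is smaller, applied identically in both routes.
* **Monotonicity**: single/complete/average/weighted/Ward heights are
  non-decreasing by construction and this is asserted; centroid and median
  may produce inversions, which are tolerated and flagged with a warning.
* Heights within (−1e−9, 0) arising from floating-point roundoff in the
  cosine and correlation metrics are clipped to 0.

Leaves are named `leaf_0..leaf_{n−1}` in input row order and inner nodes
`node_0..node_{n−2}` in merge order (0-based).  Node IDs are generated,
never taken from row IDs — those live in each leaf's `objects` list.

## Scaling and display pairing

Min-max scaling is per feature only: x' = (x − min)/(max − min).  A constant
feature (max = min) maps to 0 everywhere — this keeps the output inside
[0, 1] and avoids the undefined 0/0 without dropping the column.  With
`write_original`, clustering consumes the scaled matrix while leaf features
carry the raw values; the row dendrogram is therefore identical to the
all-normalized run's, which the tests assert node by node.

## Row compression

`cut_to_k` undoes the last k−1 merges, i.e. takes the k clusters present
just before them (for monotone linkages these are also the k−1 highest
merges).  Aggregation is per-feature mean or median; metadata aggregate with
the same statistic for numeric columns and by most-frequent label for
categorical ones, ties broken lexicographically (a deterministic and
inspectable rule).  The k reduced rows are then re-clustered from scratch to
produce the output dendrogram — the document format has no collapsed-subtree
encoding, and re-clustering k aggregate vectors is the simplest consistent
reading; with k = n it reproduces the original merge heights exactly, which
is tested.  When `write_original` and compression combine, leaf features are
aggregated from the original values and clustering uses aggregates of the
normalized values.  Minimum k is 2, since a 1-leaf dendrogram has no merge.

A leaf's `count` stays 1 even when its `objects` list holds several
compressed data points: `count` counts heatmap rows, not data points.

## Serialization choices

* Key order is fixed and node IDs are emitted in natural (`leaf_0, leaf_1,
  …, node_0, …`) order, so output is byte-deterministic.
* Integral floats are written as JSON integers (`"distance": 0`); parsing
  coerces distances and features back to float, and document equality is
  numeric, so round-trips are exact.  A `digits` option rounds distances for
  compactness; it is off by default.
* When a column dendrogram is present the feature order is **materialized**:
  `feature_names` and every leaf's `features` array are permuted into the
  column tree's leaf order, so a consumer needs no extra reordering step.
* Unknown keys at the top level and inside nodes are preserved opaquely and
  re-emitted, for forward compatibility.
* The validator treats violations as data (a list of human-readable
  strings naming node and rule), not exceptions; serializing or rendering an
  invalid document raises with the full report.

## Exploration semantics

`cut_at(tree, k)` refines a crown iteratively: starting from the root,
repeatedly split the selected node with the highest (distance, merge-order)
rank.  On monotone trees this equals removing the k−1 highest merges; in the
presence of inversions it still always yields a valid partition of the
leaves, which the property tests check for every k.  Highlight queries
return leaf IDs rather than colours, keeping them renderer-agnostic.

## Rendering

The SVG renderer is a pure function of (document, options).  Coordinates are
formatted to two decimals, colours come from named 3-stop linear scales
(interpolated per channel, clamped to the data range; a degenerate range
maps to the scale midpoint), and categorical metadata colours are assigned
by sorted label order from a fixed qualitative palette — all choices made so
identical inputs give identical bytes.  The heatmap colour range is the
per-document min/max by default with a per-column option.  Dendrogram branch
offsets are linear in merge distance, so deeper merges are drawn farther
from the leaves.  Hiding the heatmap (for very wide matrices such as hashed
fingerprints) leaves the dendrograms and metadata in place.

## Synthetic data

`make_blobs` draws k Gaussian cluster centres from a standard normal and
rescales them so the minimum pairwise centre distance equals
separation × noise_sd; points get isotropic Gaussian noise and round-robin
(then shuffled) labels so every cluster is non-empty.  Defaults are 60 rows,
5 features, 3 clusters, separation 8, noise 1 — a size at which every
pipeline path runs in well under a second.  At separation 50 the blobs are
so far apart that cutting the Ward tree at k recovers the labels with
adjusted Rand index exactly 1.0, which is the label-recovery acceptance
check; at separation 0 the labels are noise by construction.  What the
generator does **not** emulate: correlated descriptor blocks, heavy-tailed
or discrete count features, and missing values as they occur in real
screening data — passing tests demonstrate algorithmic correctness, not
robustness to those properties.  Generators are pure functions of an
explicit seed; no global random state is touched.

Test and acceptance problem sizes (n ≤ 30 for oracle comparisons, ≤ 60 rows
for pipeline runs, 200 random instances per property) were chosen so the
whole suite completes in seconds while still exercising every branch; the
O(n³) oracle is the binding factor.

## Command-line contract

Only `axis=row` and `axis=both` are accepted: the document format requires a
row dendrogram, so `none` and column-only runs are rejected with a clear
message rather than inventing an unclustered-row encoding.  `write_original`
requires `normalize` (it is meaningless otherwise).  Missing data cells are
an error by default; `--missing drop` removes the affected rows.  Mixed-type
metadata columns fall back to categorical, the safe superset.  Logs go to
standard error; the document goes only to the output path.

## Known limitations

* The O(n³) oracle is for testing; production clustering inherits SciPy's
  complexity but the whole pipeline is still in-memory and single-threaded.
* Metadata joined to reduced rows is aggregated; there is no encoding for
  per-data-point metadata under compression.
* The SVG renderer is static by design — interactivity belongs to the
  browser libraries that consume the document.
* Scaffold grouping treats the key function as pluggable; the bundled
  Murcko key requires RDKit and canonical SMILES input.
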