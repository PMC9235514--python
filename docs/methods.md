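# Methods

## Model and assumptions

The package assumes the data were drawn from a distribution whose density
concentrates along a tree embedded in gene-expression space — the classic
picture of a differentiating cell population, where intermediate cell states
fill the paths between progenitor and fates.  Everything downstream rests on
that assumption: the density tree is only a faithful summary when there *is* a
single connected hierarchy.  Data containing several disconnected hierarchies,
isolated terminal clusters, or dominant cyclic structure violate the assumption
and the method will force a spanning tree through unsupported regions (it warns
when the maximum spanning tree is forced through zero-count edges, which is the
symptom of exactly this situation).

Input is a preprocessed, continuous cells × features matrix.  The package
deliberately performs no normalisation, gene selection or log-transform of its
own (optional `--log1p` / `--scale` convenience flags exist on the CLI and are
recorded in the config snapshot); the quality of upstream preprocessing is the
user's responsibility.  PCA-reducing very wide matrices before fitting is
supported simply by passing the reduced matrix.

## Density tree

1. k-means (k-means++ initialisation, 10 restarts, Lloyd, `max_iter=300`,
   `tol=1e-4`, seeded) quantizes the data into k centroids; the stored
   assignment is re-derived as the deterministic nearest-centroid map with
   ties broken toward the lower centroid index.
2. Each data point increments the edge between its two nearest centroids
   (ordered lexicographically by (distance, index), so exact ties are
   reproducible).  The count of edge {a,b} is the empirical mass of the
   second-order Voronoï region of the pair.
3. The maximum spanning tree of the complete centroid graph under these counts
   is computed by Kruskal with union–find, processing edges in
   (descending count, ascending index pair) order.  The explicit ordering makes
   the tree unique even with tied counts.  Zero-count edges remain candidates —
   the complete graph guarantees connectivity — but any accepted zero-count
   edge is reported in a warning, since it represents a connection with no data
   support.
4. Geodesic distances (edge counts along the unique tree path) are computed by
   breadth-first search from every vertex, once, before training; they enter
   the loss as constants.

The per-edge counts drive two further derived quantities: the degree-2 centroid
list (the interior branch points penalised by the cosine loss) and the pruned
overlay (tree edges with strictly more than `min_count = 100` supporting
points), which is purely presentational — losses always use the full tree.

## Losses

With hᵢ = f(xᵢ) the 2-D embedding, embedding-space centroids are the
per-cluster means of the hᵢ under the *high-dimensional* k-means assignment.
The correct pair (c′ᵢ,₁, c′ᵢ,₂) of a point is fixed by the input space; the
current pair (cᵢ,₁, cᵢ,₂) is its two nearest embedding-space centroids and is
recomputed (as a non-differentiable index selection) at every evaluation.

- reconstruction: mean squared Euclidean error.
- push–pull: mean over points of
  d_geo(cᵢ,₁, cᵢ,₂) · (pull² − push²) where pull and push are the summed
  distances to the correct/current pair, both normalised by ‖c′ᵢ,₁ − c′ᵢ,₂‖.
  Because the current pair minimises the summed distance, each contribution is
  non-negative and vanishes exactly when the pairs coincide.  The
  normalisation makes the loss scale-free, removing the incentive to collapse
  the embedding; the unnormalised variant is kept (`naive_push_pull_loss`) as
  a reference and shrinks by ×0.25 under a ×0.5 contraction, which the test
  suite checks.  When the current pair equals the correct pair the geodesic
  factor multiplies an exact zero, so matched points contribute nothing either
  way.
- compactness: the pull ratio squared alone; per-point minimum 1 attained on
  the segment between the correct centroids.
- cosine: 1 − mean cosine of the angle between (c − n₁) and (n₂ − c) over
  degree-2 centroids c (neighbours ordered by index).  An empty degree-2 set
  (star trees) yields 0 — there is nothing to straighten — avoiding a 0/0.

Numerical guards: every distance denominator and every norm in the cosine term
is floored at ε = 1e-8, so coincident centroids produce large finite values
rather than faults.  Candidate centroids for the current pair are not filtered
in any way (the correct centroids may also be the current ones).

## Training

The autoencoder is fully connected with encoder dims
(d, 2048, 256, 32, 2), hidden layers wider than d omitted, decoder mirrored,
ReLU after every layer except the final encoder and final decoder layers.
Weights and biases are initialised uniformly in ±1/√fan_in from a seeded
generator.

Since no automatic-differentiation framework is part of the package's
dependency set, training runs on a purpose-built reverse-mode engine
(`densitree.autodiff`, ~200 lines of NumPy): dense affine maps, ReLU,
elementwise arithmetic, reductions, row gathering and segment means, each with
its adjoint.  The segment-mean adjoint is what lets gradients flow through the
embedding-space centroids into every member point, which the push–pull,
compactness and cosine terms all rely on.  The engine is gradient-checked
against central finite differences in the test suite.  The optimiser is Adam
(β = 0.9/0.999, ε = 1e-8) implemented alongside.

Phase 1 (pretraining) minimises reconstruction alone on shuffled minibatches
(default batch 256, lr 2e-4).  Phase 2 (finetuning) is full-batch (default lr
1e-3): each epoch encodes all points, rebuilds centroids inside the graph,
refreshes the current pairs, evaluates the combined loss and takes one Adam
step.  Full-batch is required because the centroids are means over whole
clusters.  No early stopping or schedules: fixed epoch budgets, as the
procedure is defined.  Checkpoints store the layer plan and all parameters in
a single zip archive; training reproducibility comes from the config snapshot
plus seed (all generators are derived from it), so RNG state is not serialised
separately.

## Synthetic data

The generator emulates the statistical shape of branching differentiation
data: smooth unit-step random walks (momentum-filtered directions, optional
constant in-plane curvature) form the skeleton; points are allocated to
branches as evenly as possible (±1), placed uniformly in arc length, and
perturbed by isotropic Gaussian noise.  Layouts: `backbone` (a main branch
with side branches at uniformly sampled origins, initial directions
orthogonalised against the local backbone tangent — the 10 000 × 100,
backbone + 9 branch benchmark uses this) and `star` (all branches from one
origin, so leaves = branches).  Defaults: step 1.0, branch length 60,
momentum 0.8, noise_sd 0.3 — noise well under the inter-branch separation, a
regime comparable to preprocessed scRNA-seq data where branch-scale signal
exceeds local noise.

`lyre_data` is a deterministic-skeleton special case used heavily in tests:
two arms curving toward each other until their tips are ≈3.5 units apart
(versus ≈7.5 units between adjacent on-branch centroids at k = 12) plus one
straight arm.  This is precisely the geometry where the Euclidean-distance MST
shortcuts the data-free gap while the density tree keeps the path through the
junction, so it exercises the method's central claim.  The tip gap stays above
5× the default noise scale so the density-tree topology of the generated data
is unambiguous.

What the generator does *not* emulate: count noise (dropout, library-size
variation, negative-binomial sampling), batch effects, or unequal branch
densities.  Tests passing on these fixtures therefore demonstrate the
correctness of the algorithmic machinery and its behaviour on clean branching
manifolds, not robustness to raw scRNA-seq artefacts — the method expects
those to be handled upstream.

## Evaluation suite

The metric k-means runs Lloyd to strict convergence (`tol=0`, up to 500
iterations): only at a true fixed point are the returned labels exactly the
nearest-centre assignment, which is what makes the identity embedding attain
exactly 1 on the Voronoï metrics.  High-dimensional geodesic distances are
shortest paths on the Euclidean-weighted symmetric kNN graph (k = 15 by
default); pairs disconnected in that graph are excluded from the correlation.
Pairwise-distance correlations subsample 1 000 points (seeded, without
replacement) when n > 3 000; a `full` flag disables this.  The k-sweep AUC is
the arithmetic mean over the grid 10…100 step 10 (identical to a trapezoidal
integral up to endpoint weighting on a uniform grid).  Degenerate distance
sets (all equal) report correlation 0 with a warning.  Relative scores map
the best method to 100 and scale others proportionally; for lower-is-better
metrics the ratio inverts.

## Problem sizes

The test suite trains on scaled-down instances chosen to exercise every code
path at desk scale: the end-to-end recovery check uses 2 000 points in 50
dimensions with k = 20 and 50 + 50 epochs over ten seeds, and the
reproducibility check uses 300 points.  `scripts/acceptance.py` runs the full
10 000 × 100 benchmark with k = 50 and 150 + 150 epochs (lr 1e-3 / 1e-2), the
toy setting's own budget.

## Known limitations

- A single connected tree is assumed; forests would require cutting low-count
  edges, which is deliberately not implemented.
- k must be chosen by the user (default 50): large enough that the tree is a
  skeleton, small enough that edge counts remain meaningful density estimates.
- Full-batch finetuning holds the whole matrix and its graph in memory; for
  larger-than-memory data the encode pass would need chunking (gradients can
  be accumulated per chunk with identical results), which is not currently
  wired in.
- The reconstruction term uses squared error on continuous values; count
  likelihoods (e.g. ZINB) are out of scope.
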