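# Methods

## The index

For an object `i` in cluster `A` of a crisp partition, with a pairwise
dissimilarity matrix `d`:

- `a(i)` — power mean `M_p` of the dissimilarities from `i` to the
  other members of `A` (the self-distance is excluded);
- `c(i, C)` — power mean of the dissimilarities from `i` to all members
  of another cluster `C`, and `b(i) = min_C c(i, C)`;
- `s(i) = (b(i) − a(i)) / max(a(i), b(i)) ∈ [−1, 1]`.

The power mean of exponent `p` is
`M_p(x) = ((1/n) Σ x_k^p)^(1/p)`, with the limits `M_0` = geometric
mean, `M_−∞` = min, `M_∞` = max. At `p = 1` the index is exactly
Rousseeuw's silhouette. Lowering `p` shifts the index from a
*compactness* criterion (all within-cluster distances matter, spherical
clusters favoured) to a *connectedness* criterion (only the nearest
members matter, so elongated, ring-shaped or otherwise irregular but
well-separated clusters can still score highly). At `p = −∞` the index
reads like single linkage; at `p = +∞` like complete linkage.

Sample-level summaries are the **mean silhouette width** (MSW), the
plain arithmetic mean of `s(i)` over objects — the exponent `p` acts
only inside `a` and `b`, never in the aggregation — and the
**misclassification rate** (MR), the share of objects with strictly
negative `s(i)`. Objects with `s(i) = 0` (including singletons) do not
count as misclassified.

## Conventions and degenerate inputs

- **Singletons.** An object alone in its cluster takes `s = 0` by
  convention; its undefined `a` is recorded as 0. Singletons stay in
  the MSW denominator — dropping them would silently inflate MSW for
  methods (notably single linkage) that shed outliers into singleton
  clusters.
- **Zero distances.** Duplicate objects produce zeros, which violate
  the positivity the power mean formally requires. We extend by
  continuity: for `p > 0` zeros enter the formula unchanged; for
  `p ≤ 0` any zero forces `M_p = 0` (its limiting value). If
  `a = b = 0` then `s = 0` rather than 0/0.
- **Ties.** If several clusters attain `b(i)`, the reported neighbour
  is the smallest label in canonical sorted order; `s(i)` is
  unaffected.
- **Numerics.** Finite nonzero exponents are evaluated after rescaling
  by the sample extreme (`max` for `p > 0`, smallest positive value for
  `p < 0`), so every ratio lies in (0, 1] and the formula cannot
  overflow for any value magnitude or any `|p|`; results are clipped
  into `[min, max]` to absorb rounding. `p = 0` and `p = ±∞` are
  special-cased exactly; every other exponent goes through the one
  general code path. The finite-`p` approach to the extremes is slow —
  the relative gap behaves like `(1/n)^(1/|p|)`, still ≈ 3.6% at
  `p = 30` for `n = 3` — which is why the infinite exponents are
  short-circuited rather than approximated.

## Default exponent grid

`{−∞, −3, −2, −1, 0, 1, 2, 3, +∞}`: every classical special case of
the power mean (min, harmonic, geometric, arithmetic, quadratic, max)
padded symmetrically with small integers around zero. MSW/MR read
across this grid form a profile, analogous to a diversity profile; raw
values at different `p` span systematically different ranges (wider at
low `p`), so the profile should be read as a family of related indices
ordered by compactness-sensitivity, not compared point-for-point, and
no "optimal p" is estimated.

## Agglomerative clustering

`agglomerate` implements the stored-matrix Lance–Williams scheme: the
closest pair of clusters merges and the distance of the merged cluster
to every other is the linear recurrence
`d(m,h) = α_i d(i,h) + α_j d(j,h) + β d(i,j) + γ |d(i,h) − d(j,h)|`
with the textbook coefficients for single, complete, group-average
(UPGMA) and flexible-beta linkage. Flexible-beta uses the classic
equal-weight variant `α_i = α_j = (1 − β)/2`, `γ = 0`, default
`β = −0.25` (the conventional space-conserving choice; `β` must lie in
(−1, 1), and `β = 0` reduces to McQuitty/WPGMA — a property the test
suite uses as a cross-check). Ties in the minimal dissimilarity break
on the lexicographically smallest pair of node ids, making merges
deterministic across platforms. The O(n³) stored-matrix algorithm is a
deliberate choice over nearest-neighbour chains: it follows the
recurrence verbatim, is easy to verify, and handles the n ≤ 1,000
problems here in seconds. Cutting a tree at `k` clusters undoes the
last `k − 1` merges; labels are consecutive integers in order of first
member appearance. Merge heights are monotone for single, average and
complete linkage; for flexible-beta monotonicity is not asserted (the
sufficient condition `α_i + α_j + β ≥ 1` fails at `β = −0.25`), only
nestedness of the cuts.

## Synthetic point patterns

The generator produces eight 100-point, two-cluster planar archetypes,
each isolating one combination of separation, compactness and
connectedness, plus a 1,000-point uniform pattern without structure.
Exact shape parameters (blob standard deviations, strip length and
gap, ring radius, bridge density, duplicate offset = 1% of the blob
standard deviation) were fixed once so that each archetype's defining
geometric premise holds by construction, and verified empirically
across seeds:

- `distinct`, `unequal`: between-cluster gaps far exceed within-cluster
  diameters, so MR = 0 at every exponent for `distinct`;
- `parallel`: strip gap (3.0) exceeds strip width (0.5), so all
  objects classify correctly for `p < 1` while large `p` penalises the
  strips' elongation;
- `concentric`: ring nearest-neighbour spacing (≈ 0.75) is far below
  the ring–core gap (≈ 5), so connectedness (`p = −∞`) vindicates the
  ring while any `p ≥ 1` condemns it wholesale (diameter-spanning
  within-ring distances exceed the distance to the core);
- `offset_pairs_same` / `offset_pairs_diff`: identical coordinates for
  a given seed — two overlapping blobs in which every point has a
  duplicate at offset 0.01 — differing only in whether the duplicate
  shares its label. This isolates local connectedness exactly: at
  `p = −∞` the same-label variant is flawless and the split-label
  variant almost entirely misclassified.

All randomness flows from the explicit per-call seed through a local
`numpy.random.Generator`; regeneration is bit-identical and no global
RNG state is touched.

What the generator does **not** emulate: real data are rarely
two-dimensional, Euclidean or two-cluster; there is no measurement
noise model, no missing data, and cluster shapes beyond
blob/strip/ring are absent. Passing the archetype contracts shows the
index responds to separation, compactness and connectedness as
designed — not that any particular `p` is right for a given real
dataset.

## Experiments

- **Archetype sweeps** score the generator's reference labels (no
  clustering step) across the exponent grid with Euclidean distances.
- **Iris worked example**: Fisher's 150-flower table, sepal length and
  petal length only, each standardized to mean 0 and standard
  deviation 1 with the n−1 denominator; Euclidean distances; the three
  species as the partition. This configuration is fully deterministic.
- **Method comparison**: a uniform random pattern (default 1,000
  points) is clustered by all four linkage rules; every cut at
  k = 2…20 is scored across the grid. Structureless data expose each
  method's inherent geometry: single linkage attains the highest
  mean-over-k MSW at `p = −∞` (with a monotone nonincreasing MSW-vs-k
  curve) and by far the lowest at `p = 1` and `p = +∞`, where the
  compact-cluster methods (average, complete, flexible-beta) behave
  near-identically. These orderings are stochastic properties; the
  test suite requires them in at least 9 of 10 seeds.

## Problem sizes

The test suite exercises the full published configurations: n = 100
archetypes, the 150-point Iris table, and n = 1,000 for the method
comparison (10 seeds, restricted there to the three exponents the
ordering claims involve). The exhaustive oracle comparison enumerates
every two-cluster labelling for n = 6, 9 and 12.

## Known limitations

- No null-model standardization of MSW/MR profiles is provided;
  comparing raw values across `p` conflates index range with
  classification quality, and a randomization-based expectation would
  be the right correction. Deciding on an appropriate null model is
  left for future work.
- Only crisp partitions are supported (no fuzzy memberships), and only
  the four linkage rules used by the experiments (no Ward, centroid or
  median linkage, whose Lance–Williams forms need squared-distance
  bookkeeping).
- Weighted power means are out of scope.
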