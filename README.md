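# gensil — generalized silhouette width for cluster validation

Silhouette width is the standard per-object index of classification
quality: for object *i* it contrasts the average distance *a(i)* to its
own cluster with the average distance *b(i)* to the nearest other
cluster,

    s(i) = (b(i) − a(i)) / max(a(i), b(i)) ∈ [−1, 1].

Because *a* and *b* are arithmetic averages, the classic index prefers
compact, spherical clusters and undervalues elongated, ring-shaped or
otherwise irregular but well-separated ones. `gensil` replaces both
averages with the power (generalized/Hölder) mean

    M_p(x) = ((1/n) Σ x_k^p)^(1/p),

so a single exponent *p* tunes the index continuously between a
**connectedness** criterion (*p* = −∞: only nearest neighbours decide,
as in single linkage), the **classic silhouette** (*p* = 1) and a strict
**compactness** criterion (*p* = +∞: farthest members decide, as in
complete linkage). Reading the mean silhouette width (MSW) and the
misclassification rate (MR, the share of objects with negative *s*)
across a grid of exponents gives a profile of classification quality
ordered by compactness-sensitivity — intended for anyone validating
clusterings of ecological, epidemiological or other multivariate data
where spherical clusters cannot be assumed.

The package provides:

- `generalized_mean` / `silhouette_widths` / `silhouette_profile` — the
  index itself, from any dissimilarity matrix and crisp partition;
- `agglomerate` / `cut_tree` — Lance–Williams agglomerative clustering
  (single, group-average, complete, flexible-beta with β = −0.25);
- `generate` / `iris_fixture` — seeded 2-D benchmark archetypes and the
  standardized two-variable Iris fixture;
- `archetype_sweep` / `iris_sweep` / `method_comparison` — the
  end-to-end experiment drivers;
- a `gensil` command-line interface (`silhouette`, `profile`,
  `compare`, `simulate`).

## Worked example: the Iris species partition

Score Fisher's Iris data (sepal length and petal length, standardized;
Euclidean distances; the three species as the partition) across the
default exponent grid:

```python
from gensil import iris_sweep

res = iris_sweep()
print(res.frame().round(4).to_string())
```

```
     p    n     msw      mr
0 -inf  150  0.7144  0.0867
1 -3.0  150  0.6904  0.0867
2 -2.0  150  0.6654  0.0867
3 -1.0  150  0.6206  0.0867
4  0.0  150  0.5703  0.1267
5  1.0  150  0.4068  0.1533
6  2.0  150  0.3690  0.1733
7  3.0  150  0.3435  0.1867
8  inf  150  0.2373  0.2000
```

Under the connectedness reading (negative *p*) only 13 of 150 flowers
(8.7%) sit closer to the wrong species — all in the *versicolor*/
*virginica* overlap — and the partition scores a healthy MSW ≈ 0.71.
As *p* grows the compactness criterion takes over: by *p* = +∞ thirty
flowers (20.0%) are flagged and MSW falls to 0.237. *I. setosa* never
receives a negative width at any exponent. The per-object tables are in
`res.tables[p]`; `res.misclassified(p)` lists the flagged objects.

The same computation from the shell:

```sh
gensil simulate --pattern concentric --seed 1 --out rings.csv
gensil profile --coords rings.csv --label-column label
```

The concentric rings illustrate the point of the generalization: the
ring cluster is perfectly valid by connectedness (MR = 0 at *p* = −∞)
yet every ring member is condemned once *p* ≥ 1.

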