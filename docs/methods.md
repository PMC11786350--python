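# Methods

## Model and optimization

`fastdeconv` factorizes a non-negative genes × spots matrix `X` as
`X ≈ W Hᵀ` with `W ≥ 0` the cell-type signatures and `H ≥ 0` the per-spot
abundances, minimizing

```
f(W, H) = ||X − W Hᵀ||²_F + λ₁ Tr(Hᵀ L H) + λ₂ ||H J − J_M||²_F .
```

The Laplacian term assumes that spots adjacent in space *and* similar in
histology share cell-type composition; it equals
`½ Σ_{j,l} G_jl ||h_j − h_l||²`, so it penalizes abundance differences only
across graph edges. The sum-to-one term is evaluated through the identity
`||H J − J_M||²_F = M · Σ_j (rowsum_j(H) − 1)²` (with `J` of shape `R × M`
and `J_M` of shape `M × M`, both all ones), so the all-ones matrices are
never materialized.

Updates are multiplicative, derived from the KKT stationarity conditions by
the usual auxiliary-function splitting of each gradient into non-negative
parts; the Laplacian splits as `L = D − G`:

```
W ← W ⊙ (X H) ⊘ (W HᵀH + ε)
H ← H ⊙ (XᵀW + λ₁ G H + λ₂ M 1_{M×R}) ⊘ (H WᵀW + λ₁ D H + λ₂ M H 1_{R×R} + ε)
```

Both preserve non-negativity and leave `f` non-increasing; correctness is
enforced by monotonicity, fixed-point and approximate-KKT tests rather than
by trusting the algebra. The denominator floor `ε = 1e-12` prevents 0/0
without perturbing converged values. Iteration stops when the relative
objective change falls below `tol = 1e-5` (checked every iteration) or
after `max_iter = 1000` iterations. Initialization is uniform(0, 1) from a
user seed by default; a non-negative double-SVD start is available
(`init="svd"`), with exact zeros replaced by `mean(X)/100` so the
multiplicative updates can move them. Identical seed, configuration and
inputs reproduce results bit for bit.

`X` is taken as provided (counts or pre-normalized values); no internal
normalization is applied. Because λ₂ only *encourages* unit row sums,
reported proportions are the row-normalized `H` (all-zero rows become the
uniform vector with a logged warning); the raw `H` is kept alongside.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `R` | — | number of cell types to infer; must be ≤ min(N, M) |
| `λ₁` | 1 | weight of graph smoothing; ≈0.01 behaves like plain NMF, ≳10 prioritizes the graph over reconstruction |
| `λ₂` | 1 | weight of the sum-to-one pull on abundance rows |
| `k` | 5 | neighbours kept per spot row before symmetrization |
| `β` | range ratio | histology scale in the fused distance; 0 when intensity is absent or constant (vague histology should contribute little, and 0 is that limit) |
| `window` | 5 | pixel window side for the median spot intensity |

## Graph construction choices

The fused quantity `d²(i,j)` is a squared *distance*, yet the Laplacian
penalty needs a *similarity* whose large values mean "near". Distances are
therefore converted before the per-row top-k retention: binary mode
(default) gives each row's k nearest neighbours weight 1; heat-kernel mode
gives `exp(−d²/σ²)` with `σ²` the median of all kept squared distances.
This is the standard graph-regularized-NMF construction and the only
reading under which the trace term pulls neighbouring spots together.
Row-wise top-k selection breaks distance ties at the lower spot index;
symmetrization is by elementwise maximum (mutual-kNN by flag), which
guarantees a symmetric PSD Laplacian with zero row sums. After max
symmetrization every row has at least k nonzeros, but a hub spot that
appears in many other rows' neighbour lists can exceed 2k; the support is
exactly the union of outgoing and incoming kNN edges.

The median-intensity window is interpreted on image pixels (a `window ×
window` patch around each spot centre, clipped at borders, rescaled by the
dtype's maximum representable intensity); a lattice mode taking the median
over the nearest `window²` *spots* is provided for platforms without a
registered image coordinate system. RGB histology is converted to grey by
the standard luminance weights 0.2126/0.7152/0.0722. No image registration
is performed — pixel centres must be supplied.

## Synthetic data generator

The generator emulates spot formation by cell pooling. Per spot: a
proportion vector `p ~ Dirichlet(α)` with region-specific `α`;
`cells_per_spot = 10` cells assigned to types multinomially with
probabilities `p`; each cell's counts negative-binomial (gamma–Poisson,
dispersion 0.5, i.e. var = µ + 0.5 µ²) around its type's mean profile; the
spot vector is the sum over its cells. The ground-truth proportion matrix
holds the *realized* cell-count fractions, so its rows sum to 1 exactly.

Type mean profiles are a shared lognormal(0, 1) baseline with a disjoint
marker block per type (`marker_fraction = 0.2` of the genes, split evenly)
elevated `effect_size = 4`-fold — a moderate, well-powered marker signal
comparable to canonical markers between broad neural cell classes. The
built-in layered design has three regions of 75/140/45 spots with
`α = (1,3), (3,1), (1,1)` (first type dominant in the middle layer, second
in the inner layer, balanced outside), laid out as concentric annuli of
equal width on a disc with the first-listed region innermost. Synthetic
intensities take region levels 0.3/0.55/0.8 plus N(0, 0.02²) noise, so the
histology term of the graph is exercised. Before deconvolution the gene
set is reduced by a per-gene two-sample Wilcoxon rank-sum test between cell
types (one-vs-rest when there are more than two), Benjamini–Hochberg
adjusted, keeping genes with adjusted p < 1e-5.

What the generator does *not* emulate: real single-cell pools have
correlated genes, library-size variation between cells, dropout structure,
batch effects, and far larger gene panels; real histology carries texture
beyond a per-region brightness level. Passing tests therefore demonstrate
correctness of the machinery and recoverability under a clean generative
model, not field performance on tissue data. Real single-cell profiles can
be substituted through the `Signatures`/`simulate_dataset` interface.

## Evaluation conventions

Factors are annotated by maximum Pearson correlation of their `W` column
against reference signatures; the rule is many-to-one, and estimated
columns mapping to the same reference type are summed before scoring.
Reference types that receive no factor score a correlation of 0 and still
enter the (unweighted) mean — a conservative, total convention. RMSE is
computed on row-normalized proportion matrices. Pearson correlation of a
constant vector is undefined and is recorded as 0 with a warning. The ARI
uses K-means with 10 restarts at a fixed seed on the abundance rows.

## Rank selection

`scan_ranks` fits several seeded restarts per candidate rank and records
the best final reconstruction error, the explained variance, and a
stability score (mean over restart pairs of the mean |Pearson r| between
optimally matched signature columns, matched by the Hungarian algorithm;
1 by convention for a single restart). `suggest_rank` returns the elbow of
the error curve: both axes are rescaled to the unit square — making the
suggestion invariant to affine rescaling of the errors — and the interior
point farthest from the chord between the first and last points wins, ties
going to the smaller rank. These are pragmatic library criteria, not a
claim of optimality.

## Problem sizes and numerical checks

The shipped simulation study runs 10 replicates of the 260-spot design
with 500 genes (about 100 after DE filtering) at `R = 2`, `λ₁ = λ₂ = 1` —
a scale at which one replicate fits in well under a second while leaving
the Dirichlet structure, DE filtering and graph regularization fully
exercised. Property tests check: objective monotonicity across a
(rank × λ₁ × λ₂) grid; iterate-for-iterate equality with an independent
plain MU-NMF when both penalties vanish; the closed-form sum-to-one
identity against explicit all-ones matrices; Laplacian row sums and the
trace/double-loop identity; monotone response of row-sum deviations to λ₂;
and approximate KKT stationarity (`min(H, |∂f/∂H|)` small) at tight
tolerance on planted instances.

## Known limitations

- The factorization is non-convex; different seeds reach different local
  minima. Use restarts (`scan_ranks`) when the answer matters.
- λ₂ encourages but does not enforce simplex rows; downstream consumers
  should use the normalized proportions.
- The DE filter tests marginal location shifts only; co-expressed or
  compensating genes are invisible to it.
- Heat-kernel edge weights share one global bandwidth; strongly
  non-uniform spot densities may warrant a per-row bandwidth.
- Kullback–Leibler data fidelity and multi-slide joint factorization are
  out of scope.
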