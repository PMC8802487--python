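# Methods

## The cosine model and why PCA recovers the cycle

Each cell-cycle gene g is modeled with single-peaked periodic mean
expression f_g(θ) = A_g cos(θ − d_g), amplitude A_g > 0 and peak location
d_g ∈ [0, 2π). Expanding on the orthonormal pair (cos θ, sin θ)/√π shows
that the variance–covariance operator of the gene population is determined
by the 2×2 matrix

    C₂ = (1/G) Σ_g A_g² u(d_g) u(d_g)ᵗ,   u(d) = (cos d, sin d)ᵗ,

whose trace is mean(A²). Its eigenvectors q_i, pushed to gene space as
M q_i / ‖M q_i‖ with M the G×2 matrix of rows A_g u(d_g)ᵗ, are the
loadings empirical PCA of noise-free data converges to
(`simulate.expected_gene_loadings`; verified at n = 10⁴ cells to 10⁻²).
C₂ has rank 2 — and the polar angle of PC scores tracks θ — iff genes peak
at ≥ 2 distinct locations not separated by π. PCA uses no sample ordering,
so time-ordered and shuffled cells yield identical loadings; this is the
core of the transfer argument.

An eccentric score ellipse (unequal eigenvalues) distorts the polar angle
*monotonically* relative to θ: ordering is preserved exactly but spacing
is not. This matters for how recovery is scored (below).

## Simulators

Both simulators share cosine means and return the true θ per cell.

* **Cosine–Gaussian** (`simulate_cosine_gaussian`): entry (g, j) =
  A_g cos(θ_j − L_g) + ε, ε ~ N(0, σ²) i.i.d.; treated as continuous
  log-scale expression. Defaults emulate the canonical demonstration:
  two families of 50 genes, locations 0.2 and 1.2, amplitudes 0.5 and
  1.0, σ = 0.2, 1000 cells on an equidistant θ grid.
* **Gamma–Poisson** (`simulate_nb`): λ⁰_g = A_g cos(θ − L_g) + c with the
  positivity offset c defaulting to max_g A_g (the smallest value keeping
  all means non-negative); cell mean λ′_g = l·λ⁰_g/Σ_g λ⁰_g so the
  expected per-cell total is exactly the library size l; λ_g ~
  Gamma(shape 1/B², scale λ′_g B²) with biological coefficient of
  variation B (mean λ′_g, extra variance λ′²B²); counts y_g ~ Poisson(λ_g).
  Defaults: 100 genes with 100 equally spaced peak locations, A = 3,
  l = 2000, B = 0.1, 5000 cells with uniform-random θ.

What the generators emulate: periodic single-peak dynamics, sequencing
depth, and overdispersion. What they do not: dropout beyond Poisson
sampling, batch effects, doublets, multiple non-cycling cell types, and
genes whose variation is driven by other processes. Passing tests on this
synthetic data therefore demonstrates correctness of the machinery and its
noise/depth behavior, not performance on arbitrary real tissues — in
particular not on datasets where differentiation dominates the cell-cycle
genes, a documented failure mode of PCA-based embeddings.

At library size 10 some simulated cells have zero total counts; recovery
experiments drop them (equivalently, any positive `min_genes_per_cell` QC)
before normalization, which requires positive totals.

## QC and normalization

"Expressed" means count > 0. Filtering runs once, cells first: (1) drop
cells with fewer than `min_genes_per_cell` (default 200) expressed genes;
(2) among survivors, drop cells deviating more than `mad_k` (default 3)
median absolute deviations from the median of log2(total counts) and
log2(expressed genes); (3) drop genes expressed in fewer than
`min_cells_per_gene` (default 20) remaining cells. The MAD is the raw
median absolute deviation (`mad_constant` = 1; set 1.4826 for the
normal-consistent scale). If a metric's MAD is exactly 0, any deviation
exceeds the threshold — degenerate inputs are filtered aggressively rather
than silently passed. Doublet scores and mitochondrial content need
external tooling/annotation and are out of scope, as is per-cell-type
blocked filtering.

Normalization: size factor per cell = total / mean(totals) (mean-centered
size factors), value = log2(count/sf + 1). A common scale factor on all
counts therefore passes through as a global additive log2 shift — which
gene-wise centering removes before projection, so θ is unaffected.

## Reference learning and projection

Genes are restricted to the supplied cell-cycle set (ID match first, then
symbol), ranked by unbiased sample variance of log2 expression, and the
top 500 kept (all, if fewer). PCA is gene-wise mean-centered only (no
unit-variance scaling). Signs are fixed per component by making the
largest-magnitude loading positive; the convention is recorded in the
reference metadata. Batch integration, when needed, is the caller's
responsibility before learning; the `integrated` flag only records the
claim.

Projection centers each matched gene by its mean *in the projected
dataset* (so reference training means are not stored), and drops
unmatched reference rows without imputation or weight renormalization.
Fewer than 50 matched genes is fatal; fewer than 200 (when the reference
is larger) warns, since the embedding's shape degrades with heavy gene
loss. θ = atan2(P₂, P₁) mapped to [0, 2π) — the two-argument form, since
the plain ratio P₂/P₁ is quadrant-ambiguous; the half-open interval is
used throughout. Cells projecting exactly to the origin (e.g. a fully
degenerate projection where all matched genes are constant) get θ = NaN
with a warning rather than an error, so one pathological cell cannot kill
a run.

## Five-stage assignment

Stage order is the fixed cycle G1S→S→G2→G2M→MG1→G1S. Per stage, markers
are pruned to genes with Pearson correlation > 0.2 against the per-cell
mean of their own list (0.15 is suggested in the error message for very
shallow data, where co-expression is weaker). Scores are per-stage mean
log2 expression, z-scored across cells then across the 5 stages (sample
standard deviation, n−1; configurable nowhere because nothing downstream
is sensitive to the choice at n ≥ 3 — it cancels in the argmax and shifts
the margin scale by √(n/(n−1))). A label is kept only if the runner-up
stage is cyclically adjacent and the top-two margin exceeds 0.3; exact
ties give NA rather than an arbitrary winner. With batch labels the whole
prune→score→assign pipeline runs per batch (batches with < 3 cells are
all-NA), making labels invariant to batch-constant location/scale shifts.

## Circular statistics

**Periodic loess.** The response is fitted against [θ−2π, θ, θ+2π] with
[y, y, y]; fitted values are reported on the middle window and R² =
1 − SS_res/SS_total uses middle-copy residuals only (NaN, flagged, for a
constant response; negative values are reported as computed). Local
regression uses tricube weights over the nearest ceil(span·n) points and
a local quadratic (degree 2), matching R's `loess`; the implementation
agrees with R (`surface="direct"`) to 10⁻⁶ on a frozen fixture. The span
is a fraction of the *tripled* data: the default 0.3 gives a ≈0.9-period
window, which resolves single-period structure (noiseless cosine R² =
0.996, null R² ≈ 0.01, seam gap |ŷ(0⁺) − ŷ(2π⁻)| ≈ 10⁻³). A span of 0.75
on tripled data would smooth over several periods and cannot track the
signal (R² = 0.18). Span and degree are exposed in the CLI.

**Circular correlation.** `circular_corr` is the parametric coefficient
ρ = Σ sin(θ₁−μ₁)sin(θ₂−μ₂) / √(Σsin²(θ₁−μ₁)·Σsin²(θ₂−μ₂)) with μ_i the
von Mises ML circular means (atan2 of mean resultant components; no
concentration parameter is needed). It is exactly 1 for a rotated copy
and −1 for a reflected one — *when the circular mean is identified*. For
near-uniform marginals the mean direction is unidentified: the sample μ
tracks any rotation applied to the data, so ρ becomes numerically
unstable, and maximizing it over rotation offsets is a no-op (the
re-estimated mean absorbs the offset). Since angles read off an embedding
are only defined up to rotation and reflection, recovery on simulations —
where θ is uniform by design — is instead scored by
`aligned_circular_rho`, which uses the Fisher–Lee *rank* circular
correlation: both vectors are replaced by uniform rank angles 2π·rank/n
and the rotation-invariant statistic (4/n²)(AB − CD) is maximized over
reflection only. It equals 1 for any circular order-preserving
transformation — including the monotone polar-angle distortion of an
eccentric ellipse — and stays near 0 when recovery genuinely fails (e.g.
two peak-location families separated by π, where library-size weighting
collapses the embedding to one dimension). The literal
grid-search-over-offsets variant of the parametric coefficient remains
available as `method="grid"` for concentrated data.

**Silhouette.** Distance d(i,j) = 1 − cos(θ_i − θ_j); a(i) is the mean
distance to same-label cells (defined as 0 for singletons, giving
s(i) = 0 exactly), b(i) the minimum over other labels of the mean
distance, s(i) = (b−a)/max(a,b). Because the cycle is continuous, stages
border each other without gaps; a mean silhouette above 0 indicates
agreement between labels and angular position, and values far below
cluster-separation levels are expected and normal. Note the index depends
only on the partition — relabeling groups cannot change it.

**Proliferation index.** Fraction of cells with θ strictly inside
(0.25π, 1.5π), the S/G2/M arc; endpoints excluded as printed, NaN
positions excluded from the denominator. Under uniform θ the expected
fraction is 1.25π/2π = 0.625.

## Numerical and design choices

- Single RNG stream per run, seeded once; simulators are bit-reproducible
  given their config.
- SVD-based PCA (LAPACK), deterministic up to the recorded sign
  convention; eigenvalues sorted descending, ties in variable-gene
  variance broken by input row order.
- Reference CSVs are written with full round-trip precision and read with
  `float_precision="round_trip"`; read∘write is the identity.
- Problem sizes in the test-suite experiments follow the simulator
  defaults (100×1000 Gaussian, 100×5000 counts, 500×2000 for robustness),
  which keep every experiment in seconds on one core.

## Known limitations

- The projection is linear and the reference fixed; datasets whose
  cell-cycle genes are dominated by other processes (differentiation
  trajectories, strong batch structure) can project without an ellipse,
  in which case θ is not interpretable — inspect the internal controls
  (periodic-loess R² of canonical cycle genes, log2-total dynamics).
- A population of purely non-cycling cells concentrates near the
  embedding origin, where the polar angle is undefined or meaningless.
- No multi-species gene mapping beyond case-insensitive symbol matching.
- Stage marker lists are user-supplied; the package ships only synthetic
  fixtures, not curated biological lists or a pre-trained biological
  reference (which would require external training data).
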