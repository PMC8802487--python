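# cyclepos

Continuous cell-cycle position inference for single-cell RNA-seq, by
projection onto a fixed 2-D reference embedding.

## The problem

Cell cycle is a major, continuous source of transcriptional variation in
proliferating tissue, yet most tools reduce it to a handful of discrete
stages. `cyclepos` assigns every cell a *cell-cycle position*
θ ∈ [0, 2π): a polar angle on an embedding in which the cycle appears as
an ellipse. It is aimed at anyone analyzing scRNA-seq of proliferating
populations — for annotating progenitors in atlases, regressing cycle out
of downstream analyses, or studying cycle-coupled expression dynamics.

## The model

Assume each cell-cycle gene *g* has single-peaked periodic mean expression

    f_g(θ) = A_g · cos(θ − d_g)

with amplitude A_g and peak location d_g. Writing f_g in the basis
(cos θ, sin θ) shows that the population covariance of such genes is
governed by the 2×2 operator

    (1/G) Σ_g A_g² [ cos²d_g          cos d_g sin d_g ]
                   [ cos d_g sin d_g  sin²d_g         ]

whose top-2 eigenstructure *is* the PCA of the data. As long as genes peak
at ≥ 2 distinct locations not separated by π, this operator has rank 2,
the PC scores trace an ellipse, and the polar angle of a cell's score
recovers its position on the cycle — note that PCA needs no time ordering,
so shuffled cells give the same components.

In practice the embedding is learned **once**, on a training dataset where
cell cycle dominates (PCA of the top 500 most variable genes within a
cell-cycle gene set, gene-wise mean-centered). The resulting o×2 weight
matrix **R** is then transferred: for any new dataset,

    P = Ẽᵗ · R,    θ = atan2(P₂, P₁) mod 2π

where Ẽ is the new data restricted to the reference genes (matched by
stable ID, then symbol) and centered by its own gene means. No refitting,
no batch alignment at projection time.

The package also provides:

- **simulators** — the cosine-Gaussian model above, and a gamma-Poisson
  (negative binomial) count model with cosine means, library-size
  weighting and biological coefficient of variation, with known true θ;
- **a five-stage assigner** (G1S/S/G2/G2M/MG1) from marker lists:
  correlation-based list pruning, row-then-column z-scored stage scores,
  cyclic-adjacency and score-margin filters, run per batch;
- **circular statistics** as internal controls: periodic loess (fit on
  three concatenated copies, R² on the middle copy), the von Mises ML
  circular correlation ρ, a rank-based rotation-invariant variant for
  scoring recovery, an angular-distance silhouette, and a proliferation
  index (fraction of cells with 0.25π < θ < 1.5π, i.e. S/G2/M).

## Worked example

Simulate the canonical two-family cosine dataset (100 genes, 1000 cells,
σ = 0.2), learn a reference on it, project it through its own embedding
and score recovery of the true positions:

```bash
$ cyclepos pipeline --genes 100 --cells 1000 --seed 1 --out-dir demo
aligned circular rho (true vs inferred): 0.9974
```

The aligned circular ρ of 0.9974 says the inferred angles reproduce the
simulated cell-cycle positions almost perfectly, up to the rotation and
reflection that any embedding leaves undetermined. `demo/theta.csv` holds
the per-cell results:

```
cell_id,pc1,pc2,theta,n_genes_matched
cell_0,3.6392220810634592,2.5763882003398715,0.6160418009981686,100
cell_1,3.740074948755944,2.7892812696923994,0.6407962380293324,100
```

`pc1`/`pc2` are the cell's coordinates in the reference embedding, `theta`
its polar angle, and `n_genes_matched` how many reference genes were found
in the dataset (all 100 here). Each output CSV comes with a `.json`
sidecar carrying the package version and a hash of the resolved
configuration, so runs are reproducible bit for bit.

The same flow works on counts from the negative-binomial simulator or on
your own data:

```bash
cyclepos simulate --model nb --genes 100 --cells 5000 --seed 2 --out-dir sim
cyclepos normalize --matrix sim/matrix.csv --out norm.csv
cyclepos learn-ref --matrix norm.csv --out ref.csv
cyclepos project --matrix norm.csv --reference ref.csv --out theta.csv
cyclepos stats --theta theta.csv --theta2 sim/theta_true.csv --out stats.json
```

For real data you would pass a cell-cycle gene-set file to `learn-ref`
(e.g. the GO:0007049 members) — or, more typically, skip `learn-ref`
entirely and `project` through a previously learned reference.

## Library use

```python
from cyclepos import (simulate_cosine_gaussian, learn_reference,
                      estimate_cycle_position, aligned_circular_rho)
from cyclepos.simulate import two_family_config

data = simulate_cosine_gaussian(two_family_config(seed=1))
ref = learn_reference(data.matrix, list(data.matrix.gene_keys()))
pos = estimate_cycle_position(data.matrix, ref)
print(aligned_circular_rho(data.theta_true, pos.theta).rho)  # 0.997...
```

See `docs/methods.md` for the statistical details, parameter defaults and
known limitations.
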