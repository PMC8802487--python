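"""Synthetic periodic expression data with known cell-cycle position.

Two generative models share the same mean structure: gene g has mean
``A_g * cos(theta - L_g)`` over the cycle position theta, with amplitude
``A_g`` and peak location ``L_g``.

* The *cosine-Gaussian* model adds i.i.d. Gaussian noise to the mean and is
  treated as continuous (log-scale) expression.  It is the minimal setting
  in which PCA provably recovers the circular ordering.
* The *gamma-Poisson* (negative binomial) model maps the shifted mean
  through library-size weighting, draws a per-gene-and-cell rate from a
  Gamma distribution with biological coefficient of variation ``B``, and
  samples counts from a Poisson — the standard scRNA-seq noise model.

The closed-form theory lives here too: for cosine means, the 2x2 operator

    (1/G) sum_g A_g^2 [[cos^2 L_g,       cos L_g sin L_g],
                       [cos L_g sin L_g, sin^2 L_g      ]]

determines the principal components of the population; its eigenvectors,
pushed back to gene space, are the loadings empirical PCA converges to.
Two distinct peak locations not separated by pi make it rank 2, which is
what lets the polar angle of the scores track theta.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matrix import GeneExpressionMatrix

TWO_PI = 2.0 * np.pi


@dataclass
class SimulationConfig:
    """Parameters of one simulated dataset.

    ``positivity_offset`` (the constant c added to the cosine mean in the
    count model) defaults to ``max(amplitudes)``, the smallest value that
    keeps every mean non-negative.
    """

    amplitudes: np.ndarray
    locations: np.ndarray
    n_cells: int
    theta_mode: str = "grid"  # or "uniform_random"
    noise_sd: float = 0.2
    library_size: float = 2000.0
    bcv: float = 0.1
    positivity_offset: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        self.locations = np.asarray(self.locations, dtype=float)
        if self.amplitudes.shape != self.locations.shape:
            raise ValueError("amplitudes and locations must have equal length")
        if self.amplitudes.size == 0:
            raise ValueError("at least one gene is required")
        if np.any(self.amplitudes <= 0):
            raise ValueError("amplitudes must be positive")
        if self.n_cells <= 0:
            raise ValueError("n_cells must be positive")
        if self.theta_mode not in ("grid", "uniform_random"):
            raise ValueError("theta_mode must be 'grid' or 'uniform_random'")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.positivity_offset is None:
            self.positivity_offset = float(self.amplitudes.max())
        if self.positivity_offset < self.amplitudes.max():
            raise ValueError(
                "positivity_offset must be >= max amplitude so the count-model "
                "mean stays non-negative"
            )

    @property
    def n_genes(self) -> int:
        return self.amplitudes.size


@dataclass
class SimulatedDataset:
    """A simulated matrix together with the true per-cell angle."""

    matrix: GeneExpressionMatrix
    theta_true: np.ndarray
    config: SimulationConfig


@dataclass
class TheorySpec:
    """Closed-form second-moment structure of the cosine model."""

    cov_operator: np.ndarray  # 2x2 symmetric PSD
    eigenvalues: np.ndarray  # descending, length 2
    eigenvectors: np.ndarray  # columns q1, q2, orthonormal


def _gene_annotations(n_genes: int) -> tuple[np.ndarray, np.ndarray]:
    ids = np.array([f"SIMG{i:05d}" for i in range(n_genes)], dtype=object)
    symbols = np.array([f"Sim{i}" for i in range(n_genes)], dtype=object)
    return ids, symbols


def _draw_theta(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    if config.theta_mode == "grid":
        return np.arange(config.n_cells) * TWO_PI / config.n_cells
    return rng.uniform(0.0, TWO_PI, size=config.n_cells)


def _mean_matrix(config: SimulationConfig, theta: np.ndarray) -> np.ndarray:
    """Genes x cells matrix of A_g * cos(theta_j - L_g)."""
    return config.amplitudes[:, None] * np.cos(
        theta[None, :] - config.locations[:, None]
    )


def simulate_cosine_gaussian(config: SimulationConfig) -> SimulatedDataset:
    """Cosine mean plus i.i.d. Gaussian noise; continuous expression.

    ``theta_mode="grid"`` places cells on an equidistant grid over
    [0, 2*pi) in order; ``"uniform_random"`` draws them uniformly.
    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    theta = _draw_theta(config, rng)
    values = _mean_matrix(config, theta)
    if config.noise_sd > 0:
        values = values + rng.normal(0.0, config.noise_sd, size=values.shape)
    ids, symbols = _gene_annotations(config.n_genes)
    cells = np.array([f"cell_{j}" for j in range(config.n_cells)], dtype=object)
    mat = GeneExpressionMatrix(
        values=values,
        cell_ids=cells,
        gene_ids=ids,
        gene_symbols=symbols,
        value_kind="log2norm",
    )
    return SimulatedDataset(matrix=mat, theta_true=theta, config=config)


def simulate_nb(config: SimulationConfig) -> SimulatedDataset:
    """Gamma-Poisson counts with cosine-shaped means.

    Per cell j: ``lam0_g = A_g cos(theta_j - L_g) + c`` (c the positivity
    offset); library-size weighting ``lam'_g = l * lam0_g / sum_g lam0_g``;
    ``lam_g ~ Gamma(shape=1/B^2, scale=lam'_g * B^2)`` so ``E[lam_g] =
    lam'_g``; counts ``y_g ~ Poisson(lam_g)``.  The per-cell expected total
    is exactly the library size ``l``.
    """
    rng = np.random.default_rng(config.seed)
    theta = _draw_theta(config, rng)
    lam0 = _mean_matrix(config, theta) + config.positivity_offset
    col_sums = lam0.sum(axis=0)
    lam_prime = config.library_size * lam0 / col_sums[None, :]
    shape = 1.0 / config.bcv**2
    lam = rng.gamma(shape, lam_prime * config.bcv**2)
    counts = rng.poisson(lam).astype(np.int64)
    ids, symbols = _gene_annotations(config.n_genes)
    cells = np.array([f"cell_{j}" for j in range(config.n_cells)], dtype=object)
    mat = GeneExpressionMatrix(
        values=counts,
        cell_ids=cells,
        gene_ids=ids,
        gene_symbols=symbols,
        value_kind="counts",
    )
    return SimulatedDataset(matrix=mat, theta_true=theta, config=config)


def covariance_operator(amplitudes, locations) -> np.ndarray:
    """The 2x2 operator governing PCA of cosine-mean data.

    ``(1/G) sum_g A_g^2 * u(L_g) u(L_g)^t`` with ``u(d) = (cos d, sin d)``.
    Its trace equals ``mean(A^2)``.
    """
    amplitudes = np.asarray(amplitudes, dtype=float)
    locations = np.asarray(locations, dtype=float)
    if amplitudes.size == 0 or amplitudes.shape != locations.shape:
        raise ValueError("amplitudes and locations must be equal-length, non-empty")
    c, s = np.cos(locations), np.sin(locations)
    a2 = amplitudes**2
    g = amplitudes.size
    return np.array(
        [
            [np.sum(a2 * c * c), np.sum(a2 * c * s)],
            [np.sum(a2 * c * s), np.sum(a2 * s * s)],
        ]
    ) / g


def expected_pcs(amplitudes, locations) -> TheorySpec:
    """Eigenstructure of :func:`covariance_operator`.

    Eigenvalues sorted descending; each eigenvector's sign is fixed so its
    first component of largest magnitude is positive.
    """
    cov = covariance_operator(amplitudes, locations)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    for i in range(2):
        lead = np.argmax(np.abs(evecs[:, i]))
        if evecs[lead, i] < 0:
            evecs[:, i] = -evecs[:, i]
    return TheorySpec(cov_operator=cov, eigenvalues=evals, eigenvectors=evecs)


def expected_gene_loadings(amplitudes, locations) -> np.ndarray:
    """Gene-space loadings (G x 2) that empirical PCA converges to.

    The gene-space principal directions of noise-free cosine data are
    ``M q_i / ||M q_i||`` where ``M`` has rows ``A_g (cos L_g, sin L_g)``
    and ``q_i`` are the eigenvectors of the 2x2 operator.  Signs follow the
    largest-absolute-loading-positive convention.
    """
    amplitudes = np.asarray(amplitudes, dtype=float)
    locations = np.asarray(locations, dtype=float)
    spec = expected_pcs(amplitudes, locations)
    m = amplitudes[:, None] * np.stack([np.cos(locations), np.sin(locations)], axis=1)
    loadings = m @ spec.eigenvectors
    for i in range(2):
        norm = np.linalg.norm(loadings[:, i])
        if norm > 0:
            loadings[:, i] /= norm
        lead = np.argmax(np.abs(loadings[:, i]))
        if loadings[lead, i] < 0:
            loadings[:, i] = -loadings[:, i]
    return loadings


# -- canned configurations ------------------------------------------------


def two_family_config(
    n_genes: int = 100,
    n_cells: int = 1000,
    noise_sd: float = 0.2,
    locations: tuple[float, float] = (0.2, 1.2),
    amplitudes: tuple[float, float] = (0.5, 1.0),
    theta_mode: str = "grid",
    seed: int = 0,
) -> SimulationConfig:
    """Two equal-size families of genes with shared peak locations.

    Defaults: half the genes peak at 0.2 with amplitude 0.5, half at 1.2
    with amplitude 1.0, sigma 0.2, 1000 grid cells — the canonical
    demonstration that PCA of periodic genes recovers the circle.
    """
    half = n_genes // 2
    amps = np.concatenate(
        [np.full(half, amplitudes[0]), np.full(n_genes - half, amplitudes[1])]
    )
    locs = np.concatenate(
        [np.full(half, locations[0]), np.full(n_genes - half, locations[1])]
    )
    return SimulationConfig(
        amplitudes=amps,
        locations=locs,
        n_cells=n_cells,
        theta_mode=theta_mode,
        noise_sd=noise_sd,
        seed=seed,
    )


def spread_peak_config(
    n_genes: int = 100,
    n_locations: int = 100,
    amplitude: float = 3.0,
    n_cells: int = 5000,
    library_size: float = 2000.0,
    bcv: float = 0.1,
    theta_mode: str = "uniform_random",
    seed: int = 0,
) -> SimulationConfig:
    """Count-model configuration with peak locations spread over the circle.

    ``n_locations`` distinct peak locations, equally spaced on [0, 2*pi),
    are assigned to genes round-robin.  Defaults are the count-model study
    conditions: 100 genes, 100 locations, amplitude 3, library size 2000,
    BCV 0.1, 5000 cells with uniform-random theta.
    """
    locs = (np.arange(n_genes) % n_locations) * TWO_PI / n_locations
    return SimulationConfig(
        amplitudes=np.full(n_genes, amplitude),
        locations=locs,
        n_cells=n_cells,
        theta_mode=theta_mode,
        library_size=library_size,
        bcv=bcv,
        seed=seed,
    )
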