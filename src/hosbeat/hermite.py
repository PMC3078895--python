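"""Orthonormal Hermite basis modelling with GA-optimised width.

A 201-sample signal x(t) on the grid t = -100..100 is approximated as a
linear combination of N orthonormal Hermite basis functions

    phi_n(t, sigma) = (sigma 2^n n! sqrt(pi))^(-1/2) H_n(t/sigma) exp(-t^2 / (2 sigma^2))

where H_n is the physicists' Hermite polynomial and sigma (in samples)
dilates the Gaussian envelope.  Coefficients are the minimum-norm
least-squares solution of the 201-equation, N-unknown system X = Phi A,
obtained via an SVD-based pseudo-inverse.  Fit quality is the normalised
approximation error E = ||x - Phi a||^2 / ||x||^2.

The width is optimised per signal by a small genetic algorithm: each
generation holds 10 widths, the 2 fittest (lowest E) become parents, 8
offspring are produced by affine crossover, and offspring mutate with
probability 0.9.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .beats import GRID

DEFAULT_ORDER = 26

# affine crossover weights: six interpolants and two extrapolants, giving
# eight distinct offspring from two parents
CROSSOVER_ALPHAS = (-0.25, 0.0, 0.2, 0.4, 0.6, 0.8, 1.0, 1.25)


def hermite_polynomial(n: int, t: float) -> float:
    """Physicists' Hermite polynomial H_n(t) by the three-term recursion
    H_{n+1} = 2 t H_n - 2 n H_{n-1}, H_0 = 1, H_1 = 2t."""
    if n < 0:
        raise ValueError("polynomial degree must be non-negative")
    h_prev, h = 1.0, 2.0 * t
    if n == 0:
        return h_prev
    for k in range(1, n):
        h_prev, h = h, 2.0 * t * h - 2.0 * k * h_prev
    return h


@dataclass(frozen=True)
class HermiteBasis:
    """Sampled basis: ``matrix[i, n] = phi_n(grid[i], sigma)``."""

    order: int
    sigma: float
    grid: np.ndarray
    matrix: np.ndarray


@dataclass(frozen=True)
class HermiteFit:
    """Least-squares Hermite model of one signal: N coefficients, the width
    sigma they were fitted at, and the normalised error E."""

    coefficients: np.ndarray
    sigma: float
    error: float
    order: int


def basis_matrix(order: int, sigma: float, grid: np.ndarray | None = None) -> HermiteBasis:
    """Sample N orthonormal Hermite basis functions on the grid.

    Columns are built with the normalised recursion
    phi_n = sqrt(2/n) u phi_{n-1} - sqrt((n-1)/n) phi_{n-2},  u = t/sigma,
    which avoids explicit factorials and is stable to high order.
    """
    if order < 1:
        raise ValueError("basis order must be >= 1")
    if sigma <= 0:
        raise ValueError("width parameter sigma must be positive")
    grid = GRID if grid is None else np.asarray(grid, dtype=float)
    u = grid / sigma
    m = np.empty((len(grid), order))
    m[:, 0] = np.pi ** (-0.25) / np.sqrt(sigma) * np.exp(-0.5 * u * u)
    if order > 1:
        m[:, 1] = np.sqrt(2.0) * u * m[:, 0]
    for n in range(2, order):
        m[:, n] = np.sqrt(2.0 / n) * u * m[:, n - 1] - np.sqrt((n - 1) / n) * m[:, n - 2]
    return HermiteBasis(order=order, sigma=float(sigma), grid=grid, matrix=m)


def normalized_error(signal, reconstruction) -> float:
    """E = ||signal - reconstruction||^2 / ||signal||^2 (0 for an all-zero
    signal with an all-zero reconstruction)."""
    signal = np.asarray(signal, dtype=float)
    reconstruction = np.asarray(reconstruction, dtype=float)
    if signal.shape != reconstruction.shape:
        raise ValueError("signal and reconstruction must have equal length")
    denom = float(signal @ signal)
    num = float((signal - reconstruction) @ (signal - reconstruction))
    if denom == 0.0:
        return 0.0
    return num / denom


def fit(signal, basis: HermiteBasis) -> HermiteFit:
    """Least-squares coefficients via a rank-revealing pseudo-inverse
    (SVD, relative cutoff 1e-12)."""
    signal = np.asarray(signal, dtype=float)
    if signal.shape != (basis.matrix.shape[0],):
        raise ValueError("signal length must match the basis grid")
    if not np.all(np.isfinite(signal)):
        raise ValueError("signal must be finite")
    coef, *_ = np.linalg.lstsq(basis.matrix, signal, rcond=1e-12)
    recon = basis.matrix @ coef
    return HermiteFit(coefficients=coef, sigma=basis.sigma,
                      error=normalized_error(signal, recon), order=basis.order)


def reconstruct(fit_result: HermiteFit, grid: np.ndarray | None = None) -> np.ndarray:
    """Signal reconstruction Phi a from a stored fit."""
    basis = basis_matrix(fit_result.order, fit_result.sigma, grid)
    return basis.matrix @ fit_result.coefficients


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm settings for the width search.

    Each generation holds ``population`` widths; the ``parents`` fittest
    survive and ``offspring`` new widths are produced by affine crossover
    (fixed weight set) and multiplicative log-normal mutation applied with
    probability ``mutation_prob``.  Stops after ``generations`` or when the
    best cost improves by less than ``tol`` (relative) over ``patience``
    consecutive generations.
    """

    population: int = 10
    parents: int = 2
    offspring: int = 8
    mutation_prob: float = 0.9
    sigma_bounds: tuple[float, float] = (2.0, 60.0)
    generations: int = 30
    tol: float = 1e-6
    patience: int = 5
    mutation_scale: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.parents + self.offspring != self.population:
            raise ValueError("parents + offspring must equal the population size")
        if not 0.0 <= self.mutation_prob <= 1.0:
            raise ValueError("mutation probability must be in [0, 1]")
        lo, hi = self.sigma_bounds
        if not (0 < lo < hi):
            raise ValueError("sigma bounds must satisfy 0 < low < high")


def optimize_width(signal, order: int, config: GAConfig | None = None,
                   track_population: list | None = None) -> HermiteFit:
    """GA search for the width sigma minimising the normalised error E.

    Elitist: the two parents carry over unchanged, so the returned fit is
    never worse than the best member of any earlier generation.
    Deterministic for a fixed ``config.seed``.  If ``track_population`` is
    given, the population of each generation is appended to it.
    """
    config = GAConfig() if config is None else config
    signal = np.asarray(signal, dtype=float)
    lo, hi = config.sigma_bounds
    rng = np.random.default_rng(config.seed)

    def cost(sig: float) -> HermiteFit:
        return fit(signal, basis_matrix(order, sig))

    pop = rng.uniform(lo, hi, size=config.population)
    best: HermiteFit | None = None
    stall = 0
    for _ in range(config.generations):
        if track_population is not None:
            track_population.append(pop.copy())
        fits = sorted((cost(s) for s in pop), key=lambda f: f.error)
        gen_best = fits[0]
        if best is None:
            best = gen_best
        elif gen_best.error < best.error:
            if best.error == 0.0 or (best.error - gen_best.error) / best.error < config.tol:
                stall += 1
            else:
                stall = 0
            best = gen_best
        else:
            stall += 1
        if stall >= config.patience:
            break
        p1, p2 = fits[0].sigma, fits[1].sigma
        children = np.array([a * p1 + (1.0 - a) * p2 for a in CROSSOVER_ALPHAS])
        mutate = rng.random(config.offspring) < config.mutation_prob
        factors = np.exp(config.mutation_scale * rng.standard_normal(config.offspring))
        children = np.where(mutate, children * factors, children)
        children = np.clip(children, lo, hi)
        pop = np.concatenate(([p1, p2], children))
    return best


def model_cumulant(values, order: int = DEFAULT_ORDER,
                   config: GAConfig | None = None) -> HermiteFit:
    """Hermite model of one 201-point cumulant slice (or any 201-point
    signal) at the GA-optimised width.  Default order 26 gives a
    201-equation, 26-parameter system."""
    values = getattr(values, "values", values)
    return optimize_width(values, order, config)
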