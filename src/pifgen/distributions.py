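"""Parametric distributions over atomic coordinates and types.

Coordinates are modelled per atom as isotropic Gaussians (or Laplace as an
alternative heavy-tailed family) in 3D; atom types as Dirichlet distributions
over the (K-1)-simplex.  Observed data enter the framework as Dirac
distributions: the zero-spread limit of the continuous family, and a one-hot
concentration vector sitting on a simplex vertex for the discrete family.

Closed-form KL divergences for both families are provided as loss oracles.
All divergences are in nats.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import digamma, gammaln

__all__ = [
    "GaussianParams",
    "LaplaceParams",
    "DirichletParams",
    "SimplexPoint",
    "make_dirac_continuous",
    "make_dirac_discrete",
    "sample_gaussian",
    "sample_laplace",
    "sample_dirichlet",
    "kl_gaussian",
    "kl_dirichlet_exact",
]


@dataclass(frozen=True)
class GaussianParams:
    """Isotropic Gaussian N(mu, epsilon^2 I) over a 3D coordinate (Å).

    ``epsilon`` is the standard deviation shared by the three axes;
    ``epsilon == 0`` denotes a Dirac at ``mu``.
    """

    mu: np.ndarray
    epsilon: float

    def __post_init__(self) -> None:
        mu = np.asarray(self.mu, dtype=float)
        if not np.all(np.isfinite(mu)):
            raise ValueError("mu must be finite")
        if not np.isfinite(self.epsilon) or self.epsilon < 0:
            raise ValueError("epsilon must be a finite nonnegative scalar")
        object.__setattr__(self, "mu", mu)

    @property
    def is_dirac(self) -> bool:
        return self.epsilon == 0.0


@dataclass(frozen=True)
class LaplaceParams:
    """Factorised Laplace(mu, b) over a 3D coordinate (Å); b == 0 is a Dirac."""

    mu: np.ndarray
    b: float

    def __post_init__(self) -> None:
        mu = np.asarray(self.mu, dtype=float)
        if not np.all(np.isfinite(mu)):
            raise ValueError("mu must be finite")
        if not np.isfinite(self.b) or self.b < 0:
            raise ValueError("b must be a finite nonnegative scalar")
        object.__setattr__(self, "mu", mu)

    @property
    def is_dirac(self) -> bool:
        return self.b == 0.0


@dataclass(frozen=True)
class DirichletParams:
    """Dirichlet concentration vector over K atom types.

    Interior points require every component strictly positive; the single
    admissible boundary case is a one-hot vector, interpreted as a Dirac at
    the corresponding simplex vertex (the data endpoint).
    """

    alpha: np.ndarray

    def __post_init__(self) -> None:
        alpha = np.asarray(self.alpha, dtype=float)
        if alpha.ndim != 1 or alpha.size < 2:
            raise ValueError("alpha must be a vector of length K >= 2")
        if not np.all(np.isfinite(alpha)) or np.any(alpha < 0):
            raise ValueError("alpha components must be finite and nonnegative")
        if alpha.sum() <= 0:
            raise ValueError("sum(alpha) must be positive")
        if np.any(alpha == 0) and not _is_one_hot(alpha):
            raise ValueError(
                "alpha with zero components is only valid as a one-hot Dirac"
            )
        object.__setattr__(self, "alpha", alpha)

    @property
    def K(self) -> int:
        return self.alpha.size

    @property
    def is_dirac(self) -> bool:
        return _is_one_hot(self.alpha)


@dataclass(frozen=True)
class SimplexPoint:
    """A point on the probability simplex (a sampled type distribution)."""

    p: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if p.ndim != 1 or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("p must be nonnegative and sum to 1 within 1e-9")
        object.__setattr__(self, "p", p)


def _is_one_hot(alpha: np.ndarray) -> bool:
    return np.count_nonzero(alpha) == 1 and alpha.max() == 1.0


# --- Dirac embeddings -------------------------------------------------------


def make_dirac_continuous(x_data) -> GaussianParams:
    """Embed an observed coordinate as the zero-spread Gaussian limit."""
    x = np.asarray(x_data, dtype=float)
    if x.shape != (3,) or not np.all(np.isfinite(x)):
        raise ValueError("x_data must be a finite 3-vector")
    return GaussianParams(mu=x, epsilon=0.0)


def make_dirac_discrete(type_index: int, K: int) -> DirichletParams:
    """Embed an observed atom type as a one-hot concentration (simplex vertex)."""
    if K < 2:
        raise ValueError("K must be >= 2")
    if not (0 <= int(type_index) < K) or int(type_index) != type_index:
        raise ValueError(f"type_index {type_index} out of range [0, {K})")
    alpha = np.zeros(K)
    alpha[int(type_index)] = 1.0
    return DirichletParams(alpha=alpha)


# --- Samplers ----------------------------------------------------------------


def sample_gaussian(params: GaussianParams, rng: np.random.Generator) -> np.ndarray:
    if params.epsilon == 0.0:
        return params.mu.copy()
    return rng.normal(loc=params.mu, scale=params.epsilon)


def sample_laplace(params: LaplaceParams, rng: np.random.Generator) -> np.ndarray:
    if params.b == 0.0:
        return params.mu.copy()
    return rng.laplace(loc=params.mu, scale=params.b)


def sample_dirichlet(params: DirichletParams, rng: np.random.Generator) -> SimplexPoint:
    """Draw a type-probability vector.

    A one-hot concentration is a boundary Dirac: the vertex is returned
    exactly rather than going through gamma variates (which would be 0/0).
    Zero components of a one-hot alpha receive probability exactly 0.
    """
    if params.is_dirac:
        return SimplexPoint(p=params.alpha.copy())
    return SimplexPoint(p=rng.dirichlet(params.alpha))


# --- KL divergences (loss oracles) -------------------------------------------


def kl_gaussian(p: GaussianParams, q: GaussianParams) -> float:
    """KL(p || q) for isotropic 3D Gaussians, in nats.

    Defined for q.epsilon > 0.  p may be a Dirac only in the degenerate sense
    p.epsilon > 0 is required as well, since the differential entropy of a
    Dirac diverges; callers handle the Dirac endpoint separately.
    """
    if q.epsilon <= 0:
        raise ValueError("KL undefined against a Dirac (q.epsilon must be > 0)")
    if p.epsilon <= 0:
        raise ValueError("KL of a Dirac is divergent (p.epsilon must be > 0)")
    d = p.mu.size
    var_ratio = (p.epsilon / q.epsilon) ** 2
    sq = float(np.sum((p.mu - q.mu) ** 2)) / q.epsilon**2
    return 0.5 * (d * var_ratio + sq - d + d * np.log(1.0 / var_ratio))


def kl_laplace_equal_scale(delta: float, b: float) -> float:
    """KL(Laplace(mu1,b) || Laplace(mu2,b)) with delta = |mu1 - mu2|, in nats.

    Closed form: |Δ|/b + exp(-|Δ|/b) - 1.
    """
    if b <= 0:
        raise ValueError("b must be positive")
    u = abs(delta) / b
    return u + np.expm1(-u)


def kl_dirichlet_exact(p: DirichletParams, q: DirichletParams) -> float:
    """Closed-form KL(Dir(p.alpha) || Dir(q.alpha)) in nats.

    Both concentration vectors must be strictly positive (interior of the
    parameter space); boundary Diracs have no density.
    """
    a, b = p.alpha, q.alpha
    if a.size != b.size:
        raise ValueError("dimension mismatch")
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("KL requires strictly positive concentrations")
    a0, b0 = a.sum(), b.sum()
    return float(
        gammaln(a0)
        - gammaln(b0)
        - np.sum(gammaln(a) - gammaln(b))
        + np.sum((a - b) * (digamma(a) - digamma(a0)))
    )
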