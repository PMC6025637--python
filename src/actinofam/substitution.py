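"""Empirical amino-acid substitution model with discrete-gamma rate heterogeneity.

The model is a general time-reversible Markov process on the 20 amino acids,
parameterised by a symmetric exchangeability matrix S and stationary
frequencies pi.  The instantaneous rate matrix is

    Q_ij = S_ij * pi_j   (i != j),      Q_ii = -sum_{j != i} Q_ij,

rescaled so that the expected substitution rate at stationarity,
-sum_i pi_i Q_ii, equals 1; branch lengths and pairwise distances are then
expressed in expected substitutions per site.

Among-site rate variation follows a gamma distribution with shape alpha and
mean 1, discretised into k equal-probability categories, each category
represented by its conditional mean rate (the mean-per-category scheme of
Yang 1994).  The probability-weighted mean of the category rates is exactly 1
for every alpha and k.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaincc
from scipy.stats import gamma as _gamma_dist

from .jtt_data import AMINO_ACIDS, AA_INDEX, jtt_exchangeabilities, jtt_frequencies

__all__ = [
    "AMINO_ACIDS",
    "AA_INDEX",
    "SubstitutionModel",
    "discrete_gamma_rates",
    "jtt_model",
]


def discrete_gamma_rates(alpha: float, k: int) -> np.ndarray:
    """Mean rates of ``k`` equal-probability categories of a Gamma(alpha, mean 1).

    Category boundaries are the i/k quantiles of Gamma(shape=alpha,
    scale=1/alpha); each category rate is the conditional mean of the
    distribution on its interval, so the equal-weight average of the returned
    rates is exactly 1.
    """
    if alpha <= 0:
        raise ValueError(f"gamma shape must be positive, got {alpha}")
    if k < 1:
        raise ValueError(f"need at least one rate category, got {k}")
    if k == 1:
        return np.ones(1)
    quantiles = _gamma_dist.ppf(np.arange(1, k) / k, a=alpha, scale=1.0 / alpha)
    # E[X; X in (a,b)] for Gamma(alpha, 1/alpha) is the regularised
    # incomplete-gamma difference gammainc(alpha+1, alpha*b) - gammainc(alpha+1, alpha*a);
    # written with the upper tail for numerical symmetry at the last category.
    upper = np.concatenate([gammaincc(alpha + 1.0, alpha * quantiles), [0.0]])
    lower = np.concatenate([[1.0], gammaincc(alpha + 1.0, alpha * quantiles)])
    return k * (lower - upper)


@dataclass
class SubstitutionModel:
    """Reversible amino-acid rate matrix plus discrete-gamma rates.

    Parameters
    ----------
    exchangeabilities
        Symmetric 20x20 matrix S with zero diagonal.
    frequencies
        Stationary distribution pi (length 20, sums to 1).
    gamma_shape
        Gamma shape alpha; ``None`` or ``inf`` means rate-homogeneous.
    n_categories
        Number of equal-probability discrete-gamma categories.
    """

    exchangeabilities: np.ndarray
    frequencies: np.ndarray
    gamma_shape: float | None = 1.7014
    n_categories: int = 8
    name: str = "custom"

    # derived, filled in __post_init__
    rate_matrix: np.ndarray = field(init=False, repr=False)
    category_rates: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        s = np.asarray(self.exchangeabilities, dtype=float)
        pi = np.asarray(self.frequencies, dtype=float)
        if s.shape != (20, 20) or not np.allclose(s, s.T):
            raise ValueError("exchangeability matrix must be symmetric 20x20")
        if pi.shape != (20,) or np.any(pi <= 0):
            raise ValueError("frequencies must be 20 positive values")
        pi = pi / pi.sum()
        q = s * pi[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -np.sum(pi * np.diag(q))  # expected rate at stationarity
        q /= mu
        self.frequencies = pi
        self.rate_matrix = q
        if self.gamma_shape is None or np.isinf(self.gamma_shape):
            self.gamma_shape = None
            self.category_rates = np.ones(self.n_categories)
        else:
            self.category_rates = discrete_gamma_rates(self.gamma_shape, self.n_categories)
        # Symmetrised eigendecomposition: B = D^1/2 Q D^-1/2 is symmetric for
        # a reversible Q, so eigh gives a stable spectral form for P(t).
        sqrt_pi = np.sqrt(pi)
        b = q * (sqrt_pi[:, None] / sqrt_pi[None, :])
        eigval, eigvec = np.linalg.eigh((b + b.T) / 2.0)
        self._eigval = eigval
        self._left = eigvec.T * sqrt_pi[None, :]          # U^T D^1/2
        self._right = (eigvec.T / sqrt_pi[None, :]).T      # D^-1/2 U

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Q t); rows sum to 1, P(0) = I, rows -> pi as t -> inf."""
        if t < 0:
            raise ValueError("time must be non-negative")
        return (self._right * np.exp(self._eigval * t)[None, :]) @ self._left

    def mixture_transition(self, t: float) -> np.ndarray:
        """Equal-weight average of P(r_c t) over the gamma rate categories."""
        rates = self.category_rates
        p = np.zeros((20, 20))
        for r in rates:
            p += self.transition_matrix(r * t)
        return p / len(rates)

    def encode(self, sequence: str) -> np.ndarray:
        """Map a protein string onto model state indices; -1 for non-standard."""
        return np.array([AA_INDEX.get(a, -1) for a in sequence], dtype=np.int64)


def jtt_model(gamma_shape: float | None = 1.7014, n_categories: int = 8) -> SubstitutionModel:
    """The JTT model, optionally with discrete-gamma rate heterogeneity.

    The default shape parameter (1.7014) and the complete-deletion gap policy
    used elsewhere in the package reproduce the divergence settings of the
    actinoporin family study this pipeline is built around.
    """
    return SubstitutionModel(
        exchangeabilities=jtt_exchangeabilities(),
        frequencies=jtt_frequencies(),
        gamma_shape=gamma_shape,
        n_categories=n_categories,
        name="JTT",
    )
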