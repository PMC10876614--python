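"""Nucleotide substitution models (JC, HKY, GTR) with discrete-gamma rates.

The general time-reversible (GTR) rate matrix is parameterized by six
exchangeabilities (AC, AG, AT, CG, CT, GT) and the stationary base
frequencies, normalized so the expected rate is one substitution per site.
Among-site rate variation uses Yang's discrete gamma: ``n`` equal-probability
categories whose rates are the within-bin means of a Gamma(shape, shape)
density, hence mean-normalized to 1. Transition probabilities come from the
symmetric eigendecomposition of the reversible generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaincinv, gammainc

STATES = "ACGT"
N_STATES = 4

#: IUPAC nucleotide codes -> compatible state indicator over (A, C, G, T)
IUPAC_PARTIALS: dict[str, tuple[int, int, int, int]] = {
    "A": (1, 0, 0, 0), "C": (0, 1, 0, 0), "G": (0, 0, 1, 0), "T": (0, 0, 0, 1),
    "U": (0, 0, 0, 1),
    "R": (1, 0, 1, 0), "Y": (0, 1, 0, 1), "S": (0, 1, 1, 0), "W": (1, 0, 0, 1),
    "K": (0, 0, 1, 1), "M": (1, 1, 0, 0),
    "B": (0, 1, 1, 1), "D": (1, 0, 1, 1), "H": (1, 1, 0, 1), "V": (1, 1, 1, 0),
    "N": (1, 1, 1, 1), "?": (1, 1, 1, 1), "-": (1, 1, 1, 1),
}

_PAIRS = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))  # AC AG AT CG CT GT


def discrete_gamma_rates(shape: float, n_categories: int) -> np.ndarray:
    """Mean rates of ``n`` equal-probability bins of Gamma(shape, shape).

    The returned rates average exactly to 1 (mean normalization), so the
    overall expected substitution rate is unchanged by rate heterogeneity.
    """
    if shape <= 0:
        raise ValueError("gamma shape must be positive")
    if n_categories < 1:
        raise ValueError("need at least one rate category")
    if n_categories == 1:
        return np.ones(1)
    k = n_categories
    probs = np.arange(1, k) / k
    # bin boundaries on the rate axis (Gamma with mean 1: shape=a, rate=a)
    bounds = gammaincinv(shape, probs) / shape
    bounds = np.concatenate(([0.0], bounds, [np.inf]))
    # mean within each bin via the incomplete-gamma identity
    upper = gammainc(shape + 1.0, bounds[1:] * shape)
    lower = gammainc(shape + 1.0, bounds[:-1] * shape)
    rates = (upper - lower) * k
    return rates / rates.mean()


@dataclass
class SubstitutionModel:
    """Reversible nucleotide model with optional discrete-gamma rates.

    Parameters
    ----------
    exchangeabilities : 6 non-negative reals (AC, AG, AT, CG, CT, GT)
    base_frequencies : 4 positive reals summing to 1 (A, C, G, T)
    gamma_shape : positive shape of the gamma rate distribution, or None
        for rate homogeneity.
    n_rate_categories : number of discrete gamma categories (ignored when
        gamma_shape is None).
    """

    exchangeabilities: np.ndarray = field(
        default_factory=lambda: np.ones(6)
    )
    base_frequencies: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    gamma_shape: float | None = None
    n_rate_categories: int = 4

    def __post_init__(self):
        self.exchangeabilities = np.asarray(self.exchangeabilities, dtype=float)
        self.base_frequencies = np.asarray(self.base_frequencies, dtype=float)
        if self.exchangeabilities.shape != (6,) or (self.exchangeabilities < 0).any():
            raise ValueError("need 6 non-negative exchangeabilities")
        if self.exchangeabilities.sum() <= 0:
            raise ValueError("exchangeabilities cannot all be zero")
        if self.base_frequencies.shape != (4,) or (self.base_frequencies <= 0).any():
            raise ValueError("need 4 positive base frequencies")
        if not np.isclose(self.base_frequencies.sum(), 1.0, atol=1e-6):
            raise ValueError("base frequencies must sum to 1")
        self.base_frequencies = self.base_frequencies / self.base_frequencies.sum()
        if self.gamma_shape is not None and self.gamma_shape <= 0:
            raise ValueError("gamma shape must be positive")
        self._decompose()

    # -- constructors -------------------------------------------------------
    @classmethod
    def jc(cls, gamma_shape: float | None = None, n_rate_categories: int = 4):
        return cls(np.ones(6), np.full(4, 0.25), gamma_shape, n_rate_categories)

    @classmethod
    def hky(cls, kappa: float, base_frequencies,
            gamma_shape: float | None = None, n_rate_categories: int = 4):
        ex = np.array([1.0, kappa, 1.0, 1.0, kappa, 1.0])
        return cls(ex, base_frequencies, gamma_shape, n_rate_categories)

    @classmethod
    def gtr(cls, exchangeabilities, base_frequencies,
            gamma_shape: float | None = None, n_rate_categories: int = 4):
        return cls(np.asarray(exchangeabilities, dtype=float),
                   np.asarray(base_frequencies, dtype=float),
                   gamma_shape, n_rate_categories)

    # -- rate matrix and transition probabilities ---------------------------
    @property
    def rate_matrix(self) -> np.ndarray:
        """Normalized generator Q with zero row sums, mean rate 1."""
        return self._Q

    def _decompose(self):
        pi = self.base_frequencies
        Q = np.zeros((4, 4))
        for rate, (i, j) in zip(self.exchangeabilities, _PAIRS):
            Q[i, j] = rate * pi[j]
            Q[j, i] = rate * pi[i]
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mean_rate = -(pi * np.diag(Q)).sum()
        Q /= mean_rate
        self._Q = Q
        sqrt_pi = np.sqrt(pi)
        # similarity transform diag(sqrt(pi)) Q diag(1/sqrt(pi)) is symmetric
        # for reversible Q; eigh then gives a stable spectral decomposition
        B = (Q * sqrt_pi[:, None]) / sqrt_pi[None, :]
        eigval, eigvec = np.linalg.eigh((B + B.T) / 2.0)
        self._eigval = eigval
        self._right = eigvec / sqrt_pi[:, None]       # diag(1/sqrt(pi)) U
        self._left = eigvec.T * sqrt_pi[None, :]      # U' diag(sqrt(pi))

    def transition_probs(self, t: float, rate: float = 1.0) -> np.ndarray:
        """P(t) = exp(Q * t * rate); rows sum to 1."""
        if t < 0:
            raise ValueError("branch length must be non-negative")
        P = (self._right * np.exp(self._eigval * t * rate)) @ self._left
        np.clip(P, 0.0, 1.0, out=P)
        return P

    def transition_probs_stack(self, t: float, rates: np.ndarray) -> np.ndarray:
        """P(t * r) for several rates at once; shape (len(rates), 4, 4)."""
        if t < 0:
            raise ValueError("branch length must be non-negative")
        expv = np.exp(np.outer(np.asarray(rates), self._eigval) * t)  # (c, 4)
        P = (self._right[None, :, :] * expv[:, None, :]) @ self._left
        np.clip(P, 0.0, 1.0, out=P)
        return P

    @property
    def category_rates(self) -> np.ndarray:
        if self.gamma_shape is None:
            return np.ones(1)
        return discrete_gamma_rates(self.gamma_shape, self.n_rate_categories)

    @property
    def n_categories(self) -> int:
        return 1 if self.gamma_shape is None else self.n_rate_categories

    def to_dict(self) -> dict:
        return {
            "exchangeabilities": self.exchangeabilities.tolist(),
            "base_frequencies": self.base_frequencies.tolist(),
            "gamma_shape": self.gamma_shape,
            "n_rate_categories": self.n_rate_categories,
        }
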