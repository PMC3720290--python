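"""Binomial natural-abundance model and the forward convolution.

A fragment with ``n`` labelable atoms, each independently heavy with
probability ``p1``, shows isotopomer groups M+0..M+n with binomial
probabilities.  The observed mass pattern of a labelled sample is the
discrete convolution of the (unknown) isotopomer-group distribution with
this natural-abundance distribution; :func:`forward_convolve` implements
that generative model.
"""

from __future__ import annotations

from dataclasses import dataclass

import math

import numpy as np
from scipy.special import gammaln, xlogy

from .errors import InputError, ShapeError

__all__ = [
    "IsotopePair",
    "NaturalAbundanceDistribution",
    "IsotopomerDistribution",
    "CARBON_13",
    "NITROGEN_15",
    "natural_abundance_distribution",
    "forward_convolve",
]

_SUM_TOL = 1e-12


@dataclass(frozen=True)
class IsotopePair:
    """Abundances of the light (``p0``) and heavy (``p1``) isotope of one element.

    Parameters
    ----------
    p0 : float
        Fraction of the light isotope (e.g. 12C).
    p1 : float
        Fraction of the heavy isotope (e.g. 13C).
    """

    p0: float
    p1: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p0 <= 1.0 and 0.0 <= self.p1 <= 1.0):
            raise InputError(
                f"isotope abundances must lie in [0, 1], got p0={self.p0}, p1={self.p1}"
            )
        if abs(self.p0 + self.p1 - 1.0) > _SUM_TOL:
            raise InputError(
                f"isotope abundances must sum to 1, got p0 + p1 = {self.p0 + self.p1!r}"
            )

    @classmethod
    def from_heavy(cls, p1: float) -> "IsotopePair":
        """Build a pair from the heavy-isotope fraction alone."""
        p1 = float(p1)
        if not 0.0 <= p1 <= 1.0:
            raise InputError(f"heavy-isotope abundance must lie in [0, 1], got {p1}")
        return cls(p0=1.0 - p1, p1=p1)


#: Default 13C natural abundance used throughout (per-atom heavy fraction).
CARBON_13 = IsotopePair.from_heavy(0.0111)

#: Suggested 15N natural abundance for nitrogen-labelling experiments.
NITROGEN_15 = IsotopePair.from_heavy(0.00364)


@dataclass(frozen=True)
class NaturalAbundanceDistribution:
    """Binomial isotopomer-group probabilities A0..An for ``n_atoms`` atoms."""

    values: np.ndarray
    n_atoms: int

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or len(values) != self.n_atoms + 1:
            raise ShapeError(
                f"expected {self.n_atoms + 1} entries for {self.n_atoms} atoms, "
                f"got {values.shape}"
            )
        if np.any(values < 0):
            raise InputError("natural-abundance probabilities must be non-negative")
        if abs(values.sum() - 1.0) > _SUM_TOL:
            raise InputError(
                f"natural-abundance probabilities must sum to 1, got {values.sum()!r}"
            )

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class IsotopomerDistribution:
    """Molar fractions of isotopomer groups; index = number of heavy atoms."""

    fractions: np.ndarray
    n_atoms: int

    def __post_init__(self) -> None:
        fractions = np.asarray(self.fractions, dtype=float)
        object.__setattr__(self, "fractions", fractions)
        if fractions.ndim != 1 or len(fractions) != self.n_atoms + 1:
            raise ShapeError(
                f"expected {self.n_atoms + 1} fractions for {self.n_atoms} atoms, "
                f"got {fractions.shape}"
            )
        if np.any(fractions < 0):
            raise InputError("isotopomer fractions must be non-negative")
        total = fractions.sum()
        if total <= 0:
            raise InputError("isotopomer fractions must not all be zero")
        if abs(total - 1.0) > 1e-9:
            raise InputError(f"isotopomer fractions must sum to 1, got {total!r}")

    def __len__(self) -> int:
        return len(self.fractions)


def natural_abundance_distribution(
    n_atoms: int, isotopes: IsotopePair = CARBON_13
) -> NaturalAbundanceDistribution:
    """Binomial natural-abundance distribution for ``n_atoms`` labelable atoms.

    Entry ``i`` equals ``C(n, i) * p0**(n-i) * p1**i``, the probability that
    exactly ``i`` of the ``n`` atoms are the heavy isotope.

    Parameters
    ----------
    n_atoms : int
        Number of labelable atoms (>= 1).
    isotopes : IsotopePair
        Light/heavy isotope abundances; defaults to 13C at 0.0111.

    Returns
    -------
    NaturalAbundanceDistribution
    """
    if not isinstance(n_atoms, (int, np.integer)) or isinstance(n_atoms, bool):
        raise InputError(f"n_atoms must be an integer, got {n_atoms!r}")
    if n_atoms < 1:
        raise InputError(f"n_atoms must be positive, got {n_atoms}")
    n = int(n_atoms)
    p0, p1 = isotopes.p0, isotopes.p1
    if n <= 1000:
        # exact integer coefficients; the largest, C(1000, 500) ~ 2.7e299,
        # still converts to float without overflow
        values = np.array(
            [math.comb(n, i) * p0 ** (n - i) * p1**i for i in range(n + 1)]
        )
    else:
        i = np.arange(n + 1)
        log_values = (
            gammaln(n + 1)
            - gammaln(i + 1)
            - gammaln(n - i + 1)
            + xlogy(n - i, p0)
            + xlogy(i, p1)
        )
        values = np.exp(log_values)
        values /= values.sum()  # exp(log) roundoff grows with n; renormalize
    return NaturalAbundanceDistribution(values=values, n_atoms=n)


def forward_convolve(
    dist: IsotopomerDistribution | np.ndarray,
    na: NaturalAbundanceDistribution | np.ndarray,
) -> np.ndarray:
    """Predict a relative mass pattern from an isotopomer distribution.

    Output ``k`` is ``sum_j dist[j] * na[k - j]`` over valid ``j``; the output
    has length ``len(dist) + len(na) - 1`` and sums to the product of the
    input sums.

    Both arguments accept the domain types or plain vectors (the plain-vector
    form is what the synthetic generator and tests use for arbitrary inputs).
    """
    d = np.asarray(getattr(dist, "fractions", dist), dtype=float)
    a = np.asarray(getattr(na, "values", na), dtype=float)
    if d.size == 0 or a.size == 0:
        raise InputError("forward_convolve requires non-empty inputs")
    return np.convolve(d, a)
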