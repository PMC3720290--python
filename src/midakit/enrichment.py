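"""Molar percentages, isotopomer-group labels, and absolute enrichment."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError, ShapeError

__all__ = [
    "IsotopomerResult",
    "normalize_to_percent",
    "absolute_enrichment",
    "isotopomer_labels",
    "summarize",
]


@dataclass(frozen=True)
class IsotopomerResult:
    """Per-group percentages and enrichments for one fragment.

    ``abs_enrichment_labelled_raw`` is the unnormalized weighted sum (a
    diagnostic mirroring the raw fitted vector); the headline enrichment
    figures are computed on normalized fractions.
    """

    labels: tuple[str, ...]
    natural_percent: np.ndarray
    labelled_percent: np.ndarray
    abs_enrichment_natural: float
    abs_enrichment_labelled: float
    abs_enrichment_labelled_raw: float

    def __post_init__(self) -> None:
        for name in ("natural_percent", "labelled_percent"):
            vec = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, vec)
            if abs(vec.sum() - 100.0) > 1e-9:
                raise InputError(f"{name} must sum to 100, got {vec.sum()!r}")
        for name in ("abs_enrichment_natural", "abs_enrichment_labelled"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0 + 1e-12:
                raise InputError(f"{name} must lie in [0, 1], got {value!r}")


def normalize_to_percent(abundances: np.ndarray) -> np.ndarray:
    """Scale a non-negative vector so it sums to 100.

    Raises
    ------
    InputError
        If the input is all zeros or contains negatives.
    """
    x = np.asarray(abundances, dtype=float)
    if np.any(x < 0):
        raise InputError("abundances must be non-negative; clamp before normalizing")
    total = x.sum()
    if total <= 0:
        raise InputError("cannot normalize an all-zero abundance vector")
    return 100.0 * x / total


def absolute_enrichment(fractions: np.ndarray, n_fragment_atoms: int) -> float:
    """Average heavy fraction per atom: ``sum_i fractions[i] * i / n``.

    ``fractions`` must be the normalized isotopomer-group distribution of a
    fragment with ``n_fragment_atoms`` labelable atoms; for a binomial
    distribution this recovers the per-atom heavy-isotope probability.
    """
    f = np.asarray(fractions, dtype=float)
    if f.ndim != 1 or len(f) != n_fragment_atoms + 1:
        raise ShapeError(
            f"expected {n_fragment_atoms + 1} fractions for "
            f"{n_fragment_atoms} atoms, got {f.shape}"
        )
    return float(np.dot(f, np.arange(len(f))) / n_fragment_atoms)


def isotopomer_labels(n_atoms: int) -> tuple[str, ...]:
    """Notation strings for groups 0..n.

    Group 0 is all-light (``[000]`` for n=3), group n all-heavy (``[111]``);
    intermediate group k is positionally ambiguous and printed ``[XXX] k``.
    """
    if n_atoms < 1:
        raise InputError(f"n_atoms must be >= 1, got {n_atoms}")
    labels = ["[" + "0" * n_atoms + "]"]
    for k in range(1, n_atoms):
        labels.append("[" + "X" * n_atoms + f"] {k}")
    labels.append("[" + "1" * n_atoms + "]")
    return tuple(labels)


def summarize(
    natural: np.ndarray, fitted: np.ndarray, n_fragment_atoms: int
) -> IsotopomerResult:
    """Assemble the full per-fragment result from a natural-abundance
    distribution and a (clamped) fitted abundance vector."""
    na = np.asarray(getattr(natural, "values", natural), dtype=float)
    ra = np.asarray(getattr(fitted, "clamped", fitted), dtype=float)
    na_pct = normalize_to_percent(na)
    ra_pct = normalize_to_percent(ra)
    return IsotopomerResult(
        labels=isotopomer_labels(n_fragment_atoms),
        natural_percent=na_pct,
        labelled_percent=ra_pct,
        abs_enrichment_natural=absolute_enrichment(na_pct / 100.0, n_fragment_atoms),
        abs_enrichment_labelled=absolute_enrichment(ra_pct / 100.0, n_fragment_atoms),
        abs_enrichment_labelled_raw=float(
            np.dot(ra, np.arange(len(ra))) / n_fragment_atoms
        ),
    )
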