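"""Abundance matrices and the least-squares spectral deconvolution.

The correction matrix is lower-triangular Toeplitz: column ``j`` is the
natural-abundance generator shifted down by ``j`` rows, so matrix-vector
multiplication is discrete convolution and the (pseudo)inverse undoes the
natural-abundance contribution of each isotopomer group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ConditioningError, InputError, ShapeError
from .isotope_model import CARBON_13, IsotopePair, natural_abundance_distribution

__all__ = [
    "AbundanceMatrix",
    "ObservedSpectrum",
    "FittedAbundances",
    "build_abundance_matrix",
    "least_squares_solve",
    "clamp_negatives",
    "correct_spectrum",
]

logger = logging.getLogger(__name__)

#: Relative singular-value cutoff below which the system counts as rank deficient.
DEFAULT_RCOND = 1e-12


@dataclass(frozen=True)
class AbundanceMatrix:
    """Convolution matrix whose columns are shifted copies of ``generator``."""

    entries: np.ndarray
    generator: np.ndarray

    def __post_init__(self) -> None:
        entries = np.atleast_2d(np.asarray(self.entries, dtype=float))
        generator = np.asarray(self.generator, dtype=float)
        object.__setattr__(self, "entries", entries)
        object.__setattr__(self, "generator", generator)
        m, k = entries.shape
        if m < k:
            raise ShapeError(f"matrix must have rows >= columns, got {m}x{k}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.entries.shape


@dataclass(frozen=True)
class ObservedSpectrum:
    """Experimental relative intensities at integer mass offsets (0 = monoisotopic)."""

    intensities: np.ndarray
    offsets: np.ndarray

    def __post_init__(self) -> None:
        intensities = np.asarray(self.intensities, dtype=float)
        offsets = np.asarray(self.offsets, dtype=int)
        object.__setattr__(self, "intensities", intensities)
        object.__setattr__(self, "offsets", offsets)
        if intensities.ndim != 1 or offsets.ndim != 1:
            raise ShapeError("intensities and offsets must be 1-D")
        if len(intensities) != len(offsets):
            raise ShapeError(
                f"length mismatch: {len(intensities)} intensities vs "
                f"{len(offsets)} offsets"
            )
        if len(intensities) == 0:
            raise InputError("spectrum must contain at least one peak")
        if np.any(intensities < 0):
            raise InputError("intensities must be non-negative")
        if np.any(np.diff(offsets) <= 0):
            raise InputError("offsets must be strictly increasing")

    def __len__(self) -> int:
        return len(self.intensities)


@dataclass(frozen=True)
class FittedAbundances:
    """Least-squares solution for the isotopomer-group abundances.

    ``raw`` is the unconstrained solution, ``clamped`` has negatives set to
    zero, and ``reconstruction`` is the model-predicted intensity at each
    observed offset (matrix times ``clamped``).  ``condition`` is the 2-norm
    condition estimate of the solved matrix.
    """

    raw: np.ndarray
    clamped: np.ndarray
    reconstruction: np.ndarray
    condition: float = float("nan")
    offsets: np.ndarray | None = field(default=None, compare=False)
    observed: np.ndarray | None = field(default=None, compare=False)


def build_abundance_matrix(
    generator: np.ndarray, n_rows: int, n_cols: int
) -> AbundanceMatrix:
    """Build the lower-triangular Toeplitz convolution matrix.

    ``entry(i, j) = generator[i - j]`` when ``0 <= i - j < len(generator)``
    and 0 otherwise; each column is the zero-padded generator shifted down.

    Raises
    ------
    ShapeError
        If ``n_rows < n_cols`` (the system would be underdetermined).
    """
    g = np.asarray(getattr(generator, "values", generator), dtype=float).ravel()
    if g.size == 0:
        raise InputError("generator must be non-empty")
    if n_cols < 1:
        raise ShapeError(f"need at least one column, got {n_cols}")
    if n_rows < n_cols:
        raise ShapeError(f"matrix must have rows >= columns, got {n_rows}x{n_cols}")
    entries = np.zeros((n_rows, n_cols))
    for j in range(n_cols):
        stop = min(j + g.size, n_rows)
        entries[j:stop, j] = g[: stop - j]
    return AbundanceMatrix(entries=entries, generator=g)


def least_squares_solve(
    A: AbundanceMatrix,
    P: ObservedSpectrum | np.ndarray,
    rcond: float = DEFAULT_RCOND,
) -> FittedAbundances:
    """Solve ``min ||A x - P||_2`` via the Moore-Penrose pseudoinverse.

    For a square nonsingular triangular matrix this coincides with forward
    substitution; for the usual overdetermined case it solves the normal
    equations in a numerically stable way (SVD).

    Raises
    ------
    ConditioningError
        If any retained singular value falls below ``rcond`` times the
        largest one; the error carries the condition estimate.
    """
    intensities = np.asarray(getattr(P, "intensities", P), dtype=float).ravel()
    offsets = getattr(P, "offsets", None)
    entries = A.entries
    m, k = entries.shape
    if len(intensities) != m:
        raise ShapeError(
            f"observed vector has {len(intensities)} entries but matrix has {m} rows"
        )
    u, s, vt = np.linalg.svd(entries, full_matrices=False)
    if s[0] == 0.0 or s[-1] <= rcond * s[0]:
        cond = np.inf if s[-1] == 0.0 else s[0] / s[-1]
        raise ConditioningError("abundance matrix is rank deficient", cond)
    condition = s[0] / s[-1]
    logger.info("least-squares solve: %dx%d system, condition %.3e", m, k, condition)
    raw = vt.T @ ((u.T @ intensities) / s)
    clamped = clamp_negatives(raw)
    if np.any(raw < 0):
        logger.info(
            "clamped %d negative group(s) to zero: %s",
            int(np.sum(raw < 0)),
            np.flatnonzero(raw < 0).tolist(),
        )
    reconstruction = entries @ clamped
    return FittedAbundances(
        raw=raw,
        clamped=clamped,
        reconstruction=reconstruction,
        condition=condition,
        offsets=None if offsets is None else np.asarray(offsets, dtype=int),
        observed=intensities,
    )


def clamp_negatives(x: np.ndarray) -> np.ndarray:
    """Elementwise ``max(x, 0)``; order and length preserved."""
    return np.maximum(np.asarray(x, dtype=float), 0.0)


def correct_spectrum(
    record,
    isotopes: IsotopePair = CARBON_13,
    *,
    extra_carbons: int = 0,
    m0: int | None = None,
    max_heavy_atoms: int | None = None,
    two_stage: bool = False,
    rcond: float = DEFAULT_RCOND,
) -> FittedAbundances:
    """Natural-abundance-correct one metabolite record.

    Composes the binomial natural-abundance model, the Toeplitz abundance
    matrix (one row per observed offset, ``n_fragment_carbons + 1`` columns)
    and the pseudoinverse solve.

    Parameters
    ----------
    record : MetaboliteRecord
        Raw observation (m/e values, intensities, carbon counts).
    isotopes : IsotopePair
        Light/heavy abundances for the natural-abundance generator.
    extra_carbons : int
        Derivatization-agent carbons added to the natural-abundance generator
        only; the isotopomer-group count stays at the fragment's carbons.
    m0 : int, optional
        Override for the monoisotopic mass (default: nearest integer to the
        smallest observed m/e).
    max_heavy_atoms : int, optional
        Upper end of the usable mass window, as offsets above ``m0``.  By
        default all peaks at or above ``m0`` are used, because natural
        abundance spreads each group's signal up to ``n`` mass units higher.
    two_stage : bool
        Rebuild the matrix from the stage-one corrected abundances and solve
        a second time (diagnostic mode; the default single solve is the
        well-posed pipeline).
    """
    from .spectra_io import estimate_mass_window, map_offsets  # cycle-free at runtime

    intensities = np.asarray(record.intensities, dtype=float)
    if not np.any(intensities > 0):
        raise InputError(f"record {record.name!r} has all-zero intensities")

    window_m0 = m0 if m0 is not None else round(float(min(record.mz_values)))
    if max_heavy_atoms is None:
        # span the whole observed range so no high-mass peak is dropped
        max_heavy_atoms = max(
            round(float(max(record.mz_values))) - window_m0,
            record.n_carbons_fragment,
        )
    window = estimate_mass_window(record, max_heavy_atoms=max_heavy_atoms, m0=m0)
    spectrum = map_offsets(record, window)

    n_groups = record.n_carbons_fragment + 1
    if len(spectrum) < n_groups:
        raise ShapeError(
            f"record {record.name!r}: {len(spectrum)} usable peaks but "
            f"{n_groups} isotopomer groups; the system is underdetermined"
        )
    na = natural_abundance_distribution(
        record.n_carbons_fragment + extra_carbons, isotopes
    )
    entries = _rows_at_offsets(na.values, spectrum.offsets, n_groups)
    fitted = least_squares_solve(
        AbundanceMatrix(entries=entries, generator=na.values), spectrum, rcond=rcond
    )
    if two_stage:
        entries2 = _rows_at_offsets(fitted.clamped, spectrum.offsets, n_groups)
        fitted = least_squares_solve(
            AbundanceMatrix(entries=entries2, generator=fitted.clamped),
            spectrum,
            rcond=rcond,
        )
    return fitted


def _rows_at_offsets(
    generator: np.ndarray, offsets: np.ndarray, n_cols: int
) -> np.ndarray:
    """Toeplitz rows evaluated at (possibly non-contiguous) integer offsets."""
    g = np.asarray(generator, dtype=float)
    entries = np.zeros((len(offsets), n_cols))
    for row, off in enumerate(np.asarray(offsets, dtype=int)):
        for j in range(n_cols):
            i = off - j
            if 0 <= i < g.size:
                entries[row, j] = g[i]
    return entries
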