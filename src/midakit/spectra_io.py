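"""Reading, writing, and merging '#'-separated ".ls"-style metabolite records.

Dialect (normative for this package — the format has no public standard):
one record per non-empty line, five TAB-separated fields in this order::

    name <TAB> m/e#m/e#... <TAB> intensity#intensity#... <TAB> C_metabolite <TAB> C_fragment

Numeric lists use '#' separators with a tolerated trailing '#'.  Decimal
marks follow the requested locale: ``"dot"``, ``"comma"``, or ``"auto"``
(a token containing ',' and no '.' is read as comma-decimal).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .deconvolution import ObservedSpectrum
from .errors import FormatError, InputError, MergeConflictError

__all__ = [
    "MetaboliteRecord",
    "MassWindow",
    "parse_ls_record",
    "write_ls_record",
    "parse_ls_file",
    "write_ls_file",
    "read_ls_path",
    "merge_records",
    "estimate_mass_window",
    "map_offsets",
]

logger = logging.getLogger(__name__)

LOCALES = ("auto", "dot", "comma")


@dataclass(frozen=True)
class MetaboliteRecord:
    """One fragment's raw observation."""

    name: str
    mz_values: tuple[float, ...]
    intensities: tuple[float, ...]
    n_carbons_metabolite: int
    n_carbons_fragment: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "mz_values", tuple(float(v) for v in self.mz_values))
        object.__setattr__(
            self, "intensities", tuple(float(v) for v in self.intensities)
        )
        if not self.name:
            raise FormatError("record name must be non-empty")
        n_mz, n_int = len(self.mz_values), len(self.intensities)
        if n_mz != n_int:
            raise FormatError(
                f"record {self.name!r}: {n_mz} m/e values but {n_int} intensities"
            )
        if n_mz < 1:
            raise FormatError(f"record {self.name!r} has no peaks")
        if any(b <= a for a, b in zip(self.mz_values, self.mz_values[1:])):
            raise InputError(
                f"record {self.name!r}: m/e values must be strictly increasing"
            )
        if any(v < 0 for v in self.intensities):
            raise InputError(f"record {self.name!r}: intensities must be >= 0")
        if self.n_carbons_fragment < 1 or self.n_carbons_metabolite < 1:
            raise InputError(
                f"record {self.name!r}: carbon counts must be positive integers"
            )


@dataclass(frozen=True)
class MassWindow:
    """Usable mass range: monoisotopic m0, the M-1 position, and the top m_max."""

    m0: int
    m_minus1: int
    m_max: int

    def __post_init__(self) -> None:
        if self.m_minus1 != self.m0 - 1:
            raise InputError("m_minus1 must equal m0 - 1")
        if self.m_max < self.m0:
            raise InputError("m_max must be >= m0")


def _parse_number(token: str, locale: str, position: int, what: str) -> float:
    t = token.strip()
    if locale == "comma" or (locale == "auto" and "," in t and "." not in t):
        if "." in t:
            raise FormatError(
                f"{what} token {position}: {token!r} mixes '.' and comma locale"
            )
        t = t.replace(",", ".")
    elif "," in t:
        raise FormatError(
            f"{what} token {position}: {token!r} contains ',' under dot locale"
        )
    try:
        return float(t)
    except ValueError:
        raise FormatError(f"{what} token {position}: cannot parse {token!r}") from None


def _parse_hash_list(text: str, locale: str, what: str) -> list[float]:
    tokens = text.split("#")
    while tokens and tokens[-1].strip() == "":
        tokens.pop()
    if not tokens:
        raise FormatError(f"empty {what} list")
    return [_parse_number(tok, locale, i, what) for i, tok in enumerate(tokens)]


def parse_ls_record(text: str, locale: str = "auto") -> MetaboliteRecord:
    """Parse one record line into a validated :class:`MetaboliteRecord`."""
    if locale not in LOCALES:
        raise InputError(f"locale must be one of {LOCALES}, got {locale!r}")
    line = text.strip()
    if not line:
        raise FormatError("record text is empty")
    fields = [f.strip() for f in line.split("\t")]
    if len(fields) != 5:
        raise FormatError(
            f"expected 5 tab-separated fields (name, m/e list, intensity list, "
            f"C metabolite, C fragment), got {len(fields)}"
        )
    name, mz_text, ri_text, cm_text, cf_text = fields
    mz = _parse_hash_list(mz_text, locale, "m/e")
    ri = _parse_hash_list(ri_text, locale, "intensity")
    if len(mz) != len(ri):
        raise FormatError(
            f"record {name!r}: {len(mz)} m/e values but {len(ri)} intensities"
        )
    try:
        cm, cf = int(cm_text), int(cf_text)
    except ValueError:
        raise FormatError(
            f"record {name!r}: carbon counts must be integers, "
            f"got {cm_text!r} / {cf_text!r}"
        ) from None
    return MetaboliteRecord(
        name=name,
        mz_values=tuple(mz),
        intensities=tuple(ri),
        n_carbons_metabolite=cm,
        n_carbons_fragment=cf,
    )


def _format_number(value: float, locale: str) -> str:
    text = repr(float(value))  # shortest form that round-trips bit-exactly
    return text.replace(".", ",") if locale == "comma" else text


def write_ls_record(record: MetaboliteRecord, locale: str = "dot") -> str:
    """Serialize a record so that re-parsing yields bit-identical values."""
    if locale not in ("dot", "comma"):
        raise InputError(f"write locale must be 'dot' or 'comma', got {locale!r}")
    if not record.name:
        raise FormatError("record name must be non-empty")
    if "\t" in record.name or "#" in record.name:
        raise FormatError(f"record name {record.name!r} contains a separator character")
    mz = "#".join(_format_number(v, locale) for v in record.mz_values) + "#"
    ri = "#".join(_format_number(v, locale) for v in record.intensities) + "#"
    return "\t".join(
        [
            record.name,
            mz,
            ri,
            str(record.n_carbons_metabolite),
            str(record.n_carbons_fragment),
        ]
    )


def parse_ls_file(text: str, locale: str = "auto") -> list[MetaboliteRecord]:
    """Parse a whole .ls file: one record per non-empty line."""
    records = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        try:
            records.append(parse_ls_record(line, locale))
        except FormatError as exc:
            raise FormatError(f"line {lineno}: {exc}") from exc
    return records


def write_ls_file(records: Iterable[MetaboliteRecord], locale: str = "dot") -> str:
    return "\n".join(write_ls_record(r, locale) for r in records) + "\n"


def read_ls_path(path: str | Path, locale: str = "auto") -> list[MetaboliteRecord]:
    return parse_ls_file(Path(path).read_text(encoding="utf-8"), locale)


def merge_records(
    files: Sequence[Sequence[MetaboliteRecord]],
) -> list[MetaboliteRecord]:
    """Concatenate record collections, collapsing duplicates.

    Records with identical (name, m/e values) collapse to the later
    occurrence (kept at the first occurrence's position).  Duplicates that
    disagree on carbon counts raise :class:`MergeConflictError`.
    """
    merged: dict[tuple, MetaboliteRecord] = {}
    conflicts: list[str] = []
    total = 0
    for collection in files:
        for record in collection:
            total += 1
            key = (record.name, record.mz_values)
            previous = merged.get(key)
            if previous is not None and (
                previous.n_carbons_metabolite != record.n_carbons_metabolite
                or previous.n_carbons_fragment != record.n_carbons_fragment
            ):
                conflicts.append(record.name)
            merged[key] = record
    if conflicts:
        raise MergeConflictError(sorted(set(conflicts)))
    result = list(merged.values())
    logger.info(
        "merged %d record(s) from %d file(s) into %d (collapsed %d duplicate(s))",
        total,
        len(files),
        len(result),
        total - len(result),
    )
    return result


def estimate_mass_window(
    record: MetaboliteRecord,
    max_heavy_atoms: int | None = None,
    m0: int | None = None,
) -> MassWindow:
    """Bracket the usable mass range for a record.

    ``m0`` defaults to the nearest integer to the smallest observed m/e
    (robust to calibration drift); ``m_max = m0 + max_heavy_atoms`` with
    ``max_heavy_atoms`` defaulting to the fragment carbon count.
    """
    if m0 is None:
        m0 = round(float(min(record.mz_values)))
    if max_heavy_atoms is None:
        max_heavy_atoms = record.n_carbons_fragment
    return MassWindow(m0=int(m0), m_minus1=int(m0) - 1, m_max=int(m0) + max_heavy_atoms)


def map_offsets(record: MetaboliteRecord, window: MassWindow) -> ObservedSpectrum:
    """Map m/e readings to integer offsets above ``window.m0``.

    Peaks below m0 or above m_max are excluded and logged (a peak rounding
    exactly to m0 - 1 is flagged as the M-1 candidate).  Two peaks rounding
    to the same integer mass are a format error.
    """
    offsets, intensities = [], []
    seen: dict[int, float] = {}
    for mz, intensity in zip(record.mz_values, record.intensities):
        mass = round(mz)
        if mass in seen:
            raise FormatError(
                f"record {record.name!r}: m/e values {seen[mass]!r} and {mz!r} "
                f"both round to {mass}"
            )
        seen[mass] = mz
        offset = mass - window.m0
        if offset < 0 or mass > window.m_max:
            kind = "M-1 candidate" if mass == window.m_minus1 else "out of window"
            logger.info(
                "record %r: excluding peak m/e=%s (%s)", record.name, mz, kind
            )
            continue
        offsets.append(offset)
        intensities.append(intensity)
    if not offsets:
        raise InputError(
            f"record {record.name!r}: no peaks inside the mass window "
            f"[{window.m0}, {window.m_max}]"
        )
    return ObservedSpectrum(intensities=np.array(intensities), offsets=np.array(offsets))
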