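"""Exception hierarchy for midakit.

All input-validation problems derive from :class:`InputError` (a
``ValueError``), so callers can catch one type for "bad data" while still
distinguishing format, shape, and merge problems.
"""

from __future__ import annotations


class MidakitError(Exception):
    """Base class for all midakit errors."""


class InputError(MidakitError, ValueError):
    """Invalid user-supplied data (values, not structure of the code)."""


class FormatError(InputError):
    """Malformed text record: bad token, bad field count, list mismatch."""


class ShapeError(InputError):
    """Dimensions of vectors/matrices are incompatible."""


class MergeConflictError(InputError):
    """Records with the same identity disagree on carbon counts."""

    def __init__(self, names: list[str]):
        self.names = list(names)
        super().__init__(
            "conflicting duplicate records (same name and m/e values, "
            f"different carbon counts): {', '.join(self.names)}"
        )


class ConditioningError(MidakitError, ArithmeticError):
    """The least-squares system is rank deficient beyond tolerance."""

    def __init__(self, message: str, condition: float):
        self.condition = float(condition)
        super().__init__(f"{message} (condition estimate {condition:.3e})")
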