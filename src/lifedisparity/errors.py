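"""Exception hierarchy for the toolkit.

All exceptions derive from :class:`LifeDisparityError` so callers can catch the
package's failures with a single ``except`` clause; the subclasses additionally
derive from the matching builtin (``ValueError``, ``KeyError``) so generic code
behaves sensibly.
"""

from __future__ import annotations


class LifeDisparityError(Exception):
    """Base class for all errors raised by this package."""


class InvalidArgumentError(LifeDisparityError, ValueError):
    """An argument violates a precondition (wrong sign, wrong shape, ...)."""


class UndefinedValueError(LifeDisparityError, ValueError):
    """A quantity is mathematically undefined for the given input
    (e.g. remaining life expectancy where survival is zero)."""


class NoThresholdError(LifeDisparityError, ValueError):
    """The threshold age does not exist: life-table entropy is >= 1, so
    mortality reduction reduces disparity at no age."""

    def __init__(self, entropy: float):
        self.entropy = entropy
        super().__init__(
            f"no threshold age: life-table entropy is {entropy:.6g} >= 1 "
            "(the compression/expansion split is only defined for entropy < 1)"
        )


class AmbiguousThresholdError(LifeDisparityError, ValueError):
    """The sensitivity bracket changed sign more than once; all crossing ages
    are attached so the caller can inspect the pathology."""

    def __init__(self, crossings):
        self.crossings = list(crossings)
        super().__init__(
            "threshold age is ambiguous: the sensitivity bracket changes sign "
            f"at {len(self.crossings)} ages: {self.crossings}"
        )


class ParseError(LifeDisparityError, ValueError):
    """A text input file could not be parsed; the message names the line."""


class SchemaError(LifeDisparityError, ValueError):
    """A parsed table is structurally invalid (missing column, duplicates)."""


class LookupError_(LifeDisparityError, KeyError):
    """A requested year/population is not present in the table."""
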