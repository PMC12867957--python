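"""Exception hierarchy.

The three branches map onto distinct CLI exit codes: schema/validation
problems (2), missing lookup keys (3), and numerical failures (4).
"""


class PlastHealthError(Exception):
    """Base class for all package errors."""


class SchemaError(PlastHealthError):
    """Malformed or invariant-violating input (bad shares, missing columns...)."""


class MissingKeyError(PlastHealthError, KeyError):
    """A required lookup key (process, factor, archetype) is absent."""

    def __str__(self) -> str:  # KeyError quotes its message; keep it readable
        return Exception.__str__(self)


class NumericalError(PlastHealthError):
    """Numerical failure (non-convergent or singular system)."""
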