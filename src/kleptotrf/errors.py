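"""Exception hierarchy.

``InputError`` covers malformed user data (CLI exit code 1) and
``ConfigError`` covers bad configuration such as an unknown enzyme or an
infeasible simulation geometry (CLI exit code 2).
"""


class KleptotrfError(Exception):
    """Base class for all package errors."""


class InputError(KleptotrfError, ValueError):
    """Malformed input data (bad alphabet, schema, lengths...)."""


class ConfigError(KleptotrfError, ValueError):
    """Invalid configuration (catalogue entries, simulation geometry...)."""


class NoAmpliconError(InputError):
    """In silico PCR failed: a primer site is missing or mis-ordered."""


class UndefinedDistanceError(InputError):
    """p-distance undefined: no comparable (unambiguous, non-gap) columns."""


class UndefinedProfileError(InputError):
    """Relative abundance undefined: all peak heights are zero."""
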