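"""Exception hierarchy for mbcprimer.

Every error raised on a user-facing path derives from :class:`MbcError`, so
the CLI can turn any of them into a one-line message and a nonzero exit.
"""


class MbcError(Exception):
    """Base class for all mbcprimer errors."""


class ParseError(MbcError):
    """Input file could not be parsed (e.g. not FASTA, no records)."""


class AlignmentShapeError(MbcError):
    """Alignment records do not share a common column count."""


class ConfigurationError(MbcError):
    """Invalid parameter or target/exclusion designation."""


class AlphabetError(MbcError):
    """Sequence contains a character outside the accepted IUPAC alphabet."""


class DegeneracyError(MbcError):
    """Degenerate expansion would exceed the configured cap."""


class GeometryError(MbcError):
    """Primer pair coordinates are inconsistent (reverse not downstream)."""


class GenerationError(MbcError):
    """Synthetic fixture request is infeasible (e.g. impossible profile)."""
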