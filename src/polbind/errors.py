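"""Exception hierarchy.

All package-raised errors derive from :class:`PolbindError` so callers (and
the CLI) can distinguish validation problems from genuine bugs.
"""


class PolbindError(Exception):
    """Base class for all polbind errors."""


class ParseError(PolbindError):
    """A file could not be parsed in the declared format."""


class FormatError(PolbindError):
    """Input violates a structural requirement (ragged alignment, empty file)."""


class AlphabetError(PolbindError):
    """A sequence contains characters outside the allowed alphabet."""


class RoleError(PolbindError):
    """A required chain role (protein / nucleic) is absent or ambiguous."""


class ResidueLookupError(PolbindError):
    """A referenced residue does not exist in the structure."""


class ContractError(PolbindError):
    """A documented precondition was violated by the caller."""


class MappingError(PolbindError):
    """Coordinate systems of two inputs do not line up."""


class ValidationError(PolbindError):
    """A mutation spec disagrees with the reference sequence."""


class GrammarError(PolbindError):
    """A linker / label notation does not match its grammar."""


class ParameterizationError(PolbindError):
    """The force-field table lacks a parameter for a residue or atom."""


class DegenerateDataError(PolbindError):
    """Data carry no information about the parameter being fitted."""


class CalibrationError(PolbindError):
    """Ladder peaks cannot be matched to the known marker lengths."""


class ComparisonError(PolbindError):
    """Two fits with incompatible metadata were compared."""


class GeometryError(PolbindError):
    """A synthetic placement is infeasible."""


class SpecError(PolbindError):
    """A generator specification is internally inconsistent."""


class SchemaError(PolbindError):
    """A tabular input lacks a required column."""
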