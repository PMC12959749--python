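"""Exception hierarchy shared across the package.

Hard failures raise; recoverable data-quality issues are reported as
warning records alongside results (see :mod:`vowelspace.io`).
"""


class VowelSpaceError(Exception):
    """Base class for all package errors."""


class SchemaError(VowelSpaceError):
    """A required column is missing or a table's layout is unusable."""


class ParseError(VowelSpaceError):
    """A cell could not be parsed; message names the row and column."""


class DuplicateKeyError(VowelSpaceError):
    """Two rows share (speaker, session, vowel, repetition)."""


class EmptyInputError(VowelSpaceError):
    """An operation received no usable records."""


class InsufficientDataError(VowelSpaceError):
    """Too few observations for the requested statistic."""


class DegenerateGeometryError(VowelSpaceError):
    """Points are collinear/coincident where a 2-D shape is required."""


class MissingCornerError(VowelSpaceError):
    """A corner vowel needed for the quadrilateral area is absent."""


class CollinearityError(VowelSpaceError):
    """The regression design matrix is rank deficient."""


class DegeneratePredictorError(VowelSpaceError):
    """A predictor is constant, so its VIF is undefined."""


class PackagingError(VowelSpaceError):
    """A packaged data fixture is missing or corrupt."""
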