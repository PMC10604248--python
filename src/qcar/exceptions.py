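"""Exception hierarchy.

Everything derives from :class:`QcarError` (itself a ``ValueError``) so that
callers can catch the package's failures with a single except clause while
plain ``ValueError`` handling keeps working.
"""


class QcarError(ValueError):
    """Base class for all qcar errors."""


class ParameterError(QcarError):
    """An argument is outside its documented domain."""


class SchemaError(QcarError):
    """A table violates the composition/activity schema."""


class DomainError(QcarError):
    """A numeric input violates a mathematical precondition."""


class InsufficientDataError(QcarError):
    """Too few observations for the requested fit."""


class EmptyJoinError(QcarError):
    """Composition and activity tables share no oils."""


class EmptyFeatureError(QcarError):
    """A pretreatment step removed every component."""


class ClassDegeneracyError(QcarError):
    """A labelled dataset (or split) contains a single class."""


class DegenerateRegressionError(QcarError):
    """Regression input has zero variance in the predictor."""
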