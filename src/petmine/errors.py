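"""Exception hierarchy shared across the toolkit."""


class PetmineError(Exception):
    """Base class for all toolkit errors."""


class FormatError(PetmineError):
    """A file did not conform to its declared format."""


class AlignmentShapeError(FormatError):
    """Alignment rows of unequal length; carries the offending ids."""

    def __init__(self, message, ids=()):
        super().__init__(message)
        self.ids = list(ids)


class DuplicateIdError(FormatError):
    """The same record id occurred more than once in a collection."""


class DegenerateInputError(PetmineError):
    """Input formally valid but carrying no usable signal (e.g. all-ambiguous sequence)."""


class ConfigError(PetmineError):
    """Invalid configuration or argument combination."""


class EvaluationError(PetmineError):
    """A statistical evaluation could not be carried out (e.g. empty class in a CV fold)."""
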