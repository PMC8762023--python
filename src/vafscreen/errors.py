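"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: :class:`InputError` (and subclasses)
map to exit code 2, every other :class:`VafScreenError` to exit code 3.
"""


class VafScreenError(Exception):
    """Base class for all errors raised by vafscreen."""


class ConfigurationError(VafScreenError):
    """An invalid configuration value; the message names the offending field."""


class InputError(VafScreenError):
    """Invalid user-supplied data (tables, sequences, identifiers)."""


class SchemaError(InputError):
    """A table is missing a required column or violates its schema."""


class UndefinedFrequencyError(InputError):
    """Variant frequency requested at zero depth."""


class OutOfModelError(InputError):
    """A genomic position falls outside every block of the gene model."""


class ReferenceMismatchError(InputError):
    """The stated reference base disagrees with the sequence context."""


class UnsupportedAnnotationError(VafScreenError):
    """The variant class is outside the annotator's supported grammar."""


class InsufficientDataError(InputError):
    """Too few observations for the requested statistic."""
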