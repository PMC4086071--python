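"""Exception hierarchy.

All package errors derive from :class:`VarsieveError` so callers (and the
CLI) can catch one base class.
"""


class VarsieveError(Exception):
    """Base class for all varsieve errors."""


class VcfFormatError(VarsieveError):
    """The VCF input violates the format contract (header, duplicate keys...)."""


class ValidationError(VarsieveError):
    """A user-supplied configuration value is invalid."""


class ModelError(VarsieveError):
    """A pedigree cannot be compiled under the requested inheritance model."""


class AnnotationError(VarsieveError):
    """The annotation table is malformed."""
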