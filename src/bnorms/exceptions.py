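"""Package exception hierarchy."""


class BnormsError(Exception):
    """Base class for all package errors."""


class SchemaError(BnormsError):
    """A required column or key is missing from an input file."""


class IntegrityError(BnormsError):
    """Table-level invariant violated (duplicates, non-increasing ages, ...)."""


class MappingError(BnormsError):
    """A region of interest cannot be resolved against the atlas map."""


class ValidationError(BnormsError):
    """A parameter or value is outside its documented domain."""
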