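"""Exception hierarchy shared across the pipeline stages."""


class CTTError(Exception):
    """Base class for all ctthermo errors."""


class ParameterError(CTTError, ValueError):
    """A scalar parameter is outside its valid range."""


class FormatError(CTTError, ValueError):
    """An input file is readable but not in the expected format."""


class ValidationError(CTTError, ValueError):
    """Structured input data violates an invariant."""


class MatchingError(CTTError, ValueError):
    """Scans could not be matched with temperature samples."""


class DegenerateInputError(CTTError, ValueError):
    """Input is formally valid but carries no usable information."""


class RegistrationError(CTTError, ValueError):
    """Volumes are not on a common grid or cannot be aligned."""


class DetectionError(CTTError, ValueError):
    """No ablation border could be detected on any ray."""


class SchemaError(CTTError, ValueError):
    """A pipeline configuration failed schema validation."""
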