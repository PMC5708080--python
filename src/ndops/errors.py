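"""Exception hierarchy.

Every error raised by the framework derives from :class:`NdopsError` so callers
can catch framework failures without masking programming errors.
"""


class NdopsError(Exception):
    """Base class for all framework errors."""


class ConfigError(NdopsError):
    """Invalid container configuration (e.g. duplicate plugin ids)."""


class ManifestParseError(ConfigError):
    """Malformed plugin-manifest line; carries the 1-based line number."""

    def __init__(self, message, line_no=None):
        super().__init__(message if line_no is None else f"line {line_no}: {message}")
        self.line_no = line_no


class ServiceLookupError(NdopsError):
    """No service descriptor registered for the requested kind."""


class CycleError(ConfigError):
    """Service instantiation requested a service already being instantiated."""


class RegistrationError(NdopsError):
    """Duplicate registration in a uniqueness-enforcing registry."""


class DomainError(NdopsError):
    """A value lies outside the domain an operation accepts."""


class BoundsError(NdopsError):
    """Coordinate access outside an image's shape; carries the dimension."""

    def __init__(self, message, dimension=None):
        super().__init__(message)
        self.dimension = dimension


class CapacityError(NdopsError):
    """A layout cannot address the requested number of samples."""


class ImmutabilityError(NdopsError):
    """Write attempted on a read-only (function-backed) image."""


class MetadataError(NdopsError):
    """Dataset metadata inconsistent with its image (axes, LUT counts)."""


class ShapeError(NdopsError):
    """Operand shapes incompatible for an element-wise operation."""


class ConversionError(NdopsError):
    """No registered converter could produce the requested type."""


class UnknownOpError(NdopsError):
    """No op registered under the requested name or alias."""


class NoMatchError(NdopsError):
    """Ops exist under the name but none accepts the argument types."""

    def __init__(self, message, near_misses=()):
        super().__init__(message)
        self.near_misses = tuple(near_misses)


class ExecutionError(NdopsError):
    """An op body failed; carries the op id."""

    def __init__(self, message, op_id=None):
        super().__init__(message)
        self.op_id = op_id


class ParseError(NdopsError):
    """Text (expression, script header, image header) failed to parse."""

    def __init__(self, message, position=None, line_no=None):
        detail = message
        if line_no is not None:
            detail = f"line {line_no}: {message}"
        elif position is not None:
            detail = f"position {position}: {message}"
        super().__init__(detail)
        self.position = position
        self.line_no = line_no


class UnboundIdentifierError(NdopsError):
    """An expression referenced a name with no binding."""


class HarvestError(NdopsError):
    """A required module input could not be resolved; carries the name."""

    def __init__(self, message, param=None):
        super().__init__(message)
        self.param = param


class ModuleError(NdopsError):
    """A module body failed; wraps the cause."""


class LocationError(NdopsError):
    """Unsupported or unresolvable data location."""


class FormatError(NdopsError):
    """Image file violates its format; carries the byte offset when known."""

    def __init__(self, message, offset=None):
        super().__init__(message if offset is None else f"{message} (byte offset {offset})")
        self.offset = offset


class UnknownFormatError(NdopsError):
    """No registered format claims the location."""


class StorageError(NdopsError):
    """Cell block store unusable (sidecar mismatch, unwritable backing)."""


class UsageError(NdopsError):
    """Bad command-line arguments; may carry flag suggestions."""

    def __init__(self, message, suggestions=()):
        super().__init__(message)
        self.suggestions = tuple(suggestions)
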