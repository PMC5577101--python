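"""Typed errors raised by ecmscreen.

Every error a user can trigger with bad input derives from
:class:`EcmScreenError`, so callers (and the CLI) can distinguish user
errors from internal failures.
"""


class EcmScreenError(Exception):
    """Base class for all ecmscreen user-facing errors."""


class ImageFormatError(EcmScreenError):
    """The image file is not a single-plane unsigned-integer grayscale TIFF."""


class FilenameParseError(EcmScreenError):
    """Well/field identifiers could not be parsed from a filename."""


class PlateLayoutError(EcmScreenError):
    """The plate map is malformed (duplicate wells, unknown roles, missing controls)."""


class ParameterError(EcmScreenError):
    """An analysis parameter is out of its valid range."""


class AssayWindowError(EcmScreenError):
    """Controls do not define a usable assay window (e.g. equal control means)."""
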