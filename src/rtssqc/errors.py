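"""Exception hierarchy."""


class RTSSQCError(Exception):
    """Base class for all package errors."""


class RTSSFormatError(RTSSQCError):
    """File-level problem: not a structure set, missing sequences,
    coordinate text exceeding the DICOM decimal-string limit, ..."""


class RTSSDataError(RTSSQCError):
    """Content-level problem in an otherwise well-formed file
    (non-planar contour, unsupported geometric type, ...)."""


class ParameterError(RTSSQCError):
    """Invalid parameter for a generator or perturbation."""


class ConfigError(RTSSQCError):
    """Invalid experiment or perturbation configuration."""


class AnalysisError(RTSSQCError):
    """An analysis stage cannot produce a defined result
    (empty structures, no matching slices, ...)."""
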