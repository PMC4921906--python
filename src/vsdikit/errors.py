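"""Exception hierarchy shared across the package."""


class VSDIKitError(Exception):
    """Base class for all package errors."""


class ConfigurationError(VSDIKitError, ValueError):
    """Invalid parameter combination (bad window, unknown layer, bad kernel...)."""


class GeometryError(ConfigurationError):
    """Geometry construction or ROI placement impossible on this grid."""


class DataError(VSDIKitError, ValueError):
    """Input data violates a numeric precondition (non-positive F0, zero total...)."""


class UsageError(VSDIKitError, ValueError):
    """API misuse (empty ROI, repeated smoothing without override, n too small)."""


class ProtocolError(VSDIKitError, ValueError):
    """Acquisition series does not follow the expected pharmacological protocol."""


class SaturationError(DataError):
    """Fluorescence transduction would drive counts to or below zero."""
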