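"""Exception hierarchy shared by all portalquant modules."""


class PortalQuantError(Exception):
    """Base class for all portalquant errors."""


class ConfigError(PortalQuantError):
    """Invalid configuration, parameter set, or channel-role mapping."""


class DegenerateHistogramError(PortalQuantError):
    """Histogram has fewer than two populated bins; no threshold exists."""


class DegenerateMaskError(PortalQuantError):
    """Mask is all-foreground or all-background; signed EDT is undefined."""


class CrowdedFieldError(PortalQuantError):
    """Rejection sampling could not place all objects in the field."""


class ShapeMismatchError(PortalQuantError):
    """Two rasters that must share geometry do not."""
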