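"""Exception types shared across the pipeline."""


class OctFociError(Exception):
    """Base class for all package errors."""


class FormatError(OctFociError):
    """A file does not conform to the documented on-disk format."""


class SegmentationError(OctFociError):
    """Gross segmentation error: ILM/RPE surfaces are inverted or degenerate.

    Eyes with such surfaces are rejected outright; no downstream stage ever
    sees z_ilm >= z_rpe.
    """


class InvalidGeometryError(OctFociError):
    """A phantom configuration produces an impossible retina (thickness <= 0,
    surfaces outside the volume, ...)."""


class ConfigError(OctFociError):
    """Invalid or inconsistent configuration values."""
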