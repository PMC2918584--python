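"""Exception hierarchy shared across the pipeline stages."""


class MzflowError(Exception):
    """Base class for all mzflow errors."""


class FormatError(MzflowError):
    """Malformed input file or unparseable field."""


class ParameterError(MzflowError):
    """Invalid or contradictory algorithm parameters."""


class AlignmentModelError(MzflowError):
    """RANSAC failed to find an RT-correction model meeting the inlier floor.

    Callers are expected to fall back to plain Join alignment for the
    affected sample.
    """


class ConfigError(MzflowError):
    """Invalid pipeline configuration."""
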