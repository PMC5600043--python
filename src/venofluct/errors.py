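"""Exception types shared across the pipeline."""


class VenofluctError(Exception):
    """Base class for all package-specific errors."""


class DegenerateNoiseError(VenofluctError):
    """The corner-noise normalization reference is zero or numerically negligible."""


class RoiConflictError(VenofluctError):
    """Two regions of interest overlap where they must be disjoint."""


class EmptyBandError(VenofluctError):
    """A frequency band contains no spectral bins for the given series length."""


class PipelineValidationError(VenofluctError):
    """A pipeline configuration references missing or inconsistent inputs."""


class NoAnalyzableLocationsError(VenofluctError):
    """Every slice location was screened out; the separation regression cannot run."""
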