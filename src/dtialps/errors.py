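"""Exception hierarchy. Every pipeline stage raises a named subclass so
end-to-end errors identify the stage that failed."""


class DTIALPSError(Exception):
    """Base class for all package errors."""


class InvalidSchemeError(DTIALPSError):
    """Gradient scheme cannot support a tensor fit (e.g. < 6 directions)."""


class PhantomError(DTIALPSError):
    """Phantom specification invalid or target index not realisable."""


class FitError(DTIALPSError):
    """Tensor fit impossible (rank-deficient design, bad inputs)."""


class PlacementError(DTIALPSError):
    """ROI does not fit inside its designated tract."""


class ExtractionError(DTIALPSError):
    """ROI diffusivity extraction failed (e.g. empty mask)."""


class StatsError(DTIALPSError):
    """Degenerate input to a statistical routine."""


class ConfigError(DTIALPSError):
    """Invalid configuration (cohort targets, run config files)."""


class FormatError(DTIALPSError):
    """File contents inconsistent with the expected on-disk format."""
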