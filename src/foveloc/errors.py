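"""Exception hierarchy for the fovea-localization pipeline.

Every stage raises a subclass of :class:`FovelocError` so the pipeline
driver can abort cleanly and record the failing stage in the run report.
"""


class FovelocError(Exception):
    """Base class for all package errors."""


class ParameterError(FovelocError, ValueError):
    """An argument or configuration field violates its contract."""


class ConfigurationError(FovelocError):
    """A model/pipeline configuration is structurally invalid."""


class DataError(FovelocError):
    """Input data violates a precondition (empty, single-class, ...)."""


class NoFoveaError(FovelocError):
    """No positive B-scan run was found; sampling must not proceed."""


class DetectionError(FovelocError):
    """Scan-line or fovea detection failed on an image."""


class CalibrationError(FovelocError):
    """Stage calibration could not resolve a displacement."""


class TravelRangeError(FovelocError):
    """A planned move exceeds the stage travel limits."""


class AcquisitionError(FovelocError):
    """Acquisition watcher timed out or the store is malformed."""
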