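"""Exception hierarchy for the QA pipeline."""


class CatphanQaError(Exception):
    """Base class for all package errors."""


class ValidationError(CatphanQaError):
    """A configuration or input object violates its invariants."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class ScanLoadError(CatphanQaError):
    """A DICOM series could not be loaded into a valid volume."""


class DetectionError(CatphanQaError):
    """A phantom landmark required for analysis was not found."""


class MetricError(CatphanQaError):
    """A quality metric could not be computed from valid landmarks."""
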