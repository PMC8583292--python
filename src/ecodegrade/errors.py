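"""Exception hierarchy shared across the pipeline stages."""


class EcodegradeError(Exception):
    """Base class for all package errors."""


class DomainError(EcodegradeError):
    """An input value lies outside its declared valid domain."""


class SchemeError(EcodegradeError):
    """A scoring scheme failed validation (weights, thresholds, cut-points)."""


class MissingAttributeError(EcodegradeError):
    """A feature lacks an attribute a scoring scheme requires."""

    def __init__(self, missing, kind=None):
        self.missing = tuple(missing)
        self.kind = kind
        where = f" for kind '{kind}'" if kind else ""
        super().__init__(f"missing required attribute(s){where}: {', '.join(self.missing)}")


class GeometryError(EcodegradeError):
    """Geometry type or coordinate system does not match expectations."""


class AlignmentError(EcodegradeError):
    """Two grids or label vectors that must align do not."""


class SimulationSpecError(EcodegradeError):
    """A simulation or grid specification is invalid."""


class ClassingError(EcodegradeError):
    """Too few distinct values to form the requested number of classes."""


class EmptyValidationError(EcodegradeError):
    """No usable ground-truth points remain for validation."""


class UndefinedAUCError(EcodegradeError):
    """ROC/AUC is undefined because only one class is present."""
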