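"""Exception hierarchy.

Every error the pipeline can raise derives from :class:`FacesymError`, so
callers (and the CLI exit-code mapping) can distinguish usage problems,
data-integrity violations, missing optional capabilities, and degenerate
statistics.
"""


class FacesymError(Exception):
    """Base class for all package errors."""


class FormatError(FacesymError):
    """A file does not match the expected column/field layout."""


class IntegrityError(FacesymError):
    """Input data violate a structural invariant (duplicates, bad ids)."""


class RegistryError(FacesymError):
    """A pair registry violates its invariants."""


class DetectionError(FacesymError):
    """A landmark detector failed to find a face in an image."""


class CapabilityError(FacesymError):
    """An optional runtime dependency (e.g. a detector adapter) is missing."""


class DegenerateGeometryError(FacesymError):
    """Geometry makes an operation ill-posed (e.g. horizontal midline)."""


class AggregationError(FacesymError):
    """Units cannot be aggregated as requested (e.g. conflicting grades)."""


class SelectionError(FacesymError):
    """Feature selection cannot proceed (e.g. no non-empty subset)."""


class ConfigError(FacesymError):
    """A configuration object violates its invariants."""


class UndefinedStatisticError(FacesymError):
    """A statistic is undefined for the given input (zero variance etc.)."""
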