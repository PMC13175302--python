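"""Typed exceptions raised across the package.

Every validation failure names the offending field (and, where it exists,
the offending row) so that malformed instrument exports fail loudly and
diagnosably rather than propagating silently.
"""

from __future__ import annotations


class ValidationError(ValueError):
    """Base class for input-contract violations.

    Parameters
    ----------
    message : str
        Human-readable description.
    field : str, optional
        Name of the offending field/column.
    row : int, optional
        Zero-based row index where the violation was detected.
    """

    def __init__(self, message: str, *, field: str | None = None, row: int | None = None):
        self.field = field
        self.row = row
        parts = [message]
        if field is not None:
            parts.append(f"(field: {field})")
        if row is not None:
            parts.append(f"(row: {row})")
        super().__init__(" ".join(parts))


class MissingColumnError(ValidationError):
    """A required column is absent from a tabular input."""


class MonotonicityError(ValidationError):
    """A time axis is not strictly increasing."""


class GeometryError(ValidationError):
    """Sample geometry (height, area) is non-positive or missing."""


class NonPhysicalDeformationError(ValidationError):
    """A stretch computation produced lambda <= 0."""


class CycleCountError(ValidationError):
    """Detected compression-cycle count differs from the expected count."""

    def __init__(self, message: str, *, detected: int, expected: int,
                 turning_indices: list[int] | None = None):
        self.detected = detected
        self.expected = expected
        self.turning_indices = turning_indices or []
        super().__init__(message)


class PhaseTagError(ValidationError):
    """An operation received a curve with the wrong phase or cycle tag."""


class DegenerateDataError(ValidationError):
    """Data carry no identifiable signal (e.g. an all-zero stress curve)."""


class FilamentTopologyError(ValidationError):
    """A skeleton's parent references are dangling or cyclic."""


class GenerationError(RuntimeError):
    """A synthetic-data generator could not satisfy its spec."""
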