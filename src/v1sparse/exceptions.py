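"""Exception taxonomy shared across the package."""


class V1SparseError(Exception):
    """Base class for all package errors."""


class DomainError(V1SparseError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class ShapeError(V1SparseError, ValueError):
    """Array dimensions are inconsistent with each other."""


class PlacementError(V1SparseError, ValueError):
    """A line segment does not fit inside the requested frame."""


class ConfigError(V1SparseError, ValueError):
    """An invalid configuration value (e.g. non-positive sigma)."""


class RegularityError(V1SparseError, ValueError):
    """Plasticity parameters violate the conditions for a finite steady state."""


class InstabilityError(V1SparseError, RuntimeError):
    """A simulated weight trajectory diverged or left the positive orthant."""


class DegenerateError(V1SparseError, ValueError):
    """Degenerate input for which the requested quantity is undefined."""
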