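"""Package-wide exception types."""

from __future__ import annotations

__all__ = ["ConfigurationError", "ContactSolverError", "RollOffError"]


class ConfigurationError(ValueError):
    """Invalid or unknown configuration (preset names, parameter values)."""


class ContactSolverError(RuntimeError):
    """The contact equilibrium solve failed to converge or bracket the load."""

    def __init__(self, message: str, *, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class RollOffError(RuntimeError):
    """Contact migrated outside the articulating region of the insert.

    Raised when the contact-pressure centroid leaves the articulating
    region, or more than the allowed fraction of the contact area does.
    This aborts a simulated condition, mirroring the physical situation in
    which the femoral component rides over the edge of the insert and the
    test cannot be run.
    """

    def __init__(
        self,
        message: str,
        *,
        cycle_fraction: float | None = None,
        centroid=None,
        condition: str | None = None,
    ):
        super().__init__(message)
        self.cycle_fraction = cycle_fraction
        self.centroid = centroid
        self.condition = condition
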