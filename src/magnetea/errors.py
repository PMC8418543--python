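"""Exception hierarchy for magnetea."""


class MagneteaError(Exception):
    """Base class for all package errors."""


class ScenarioError(MagneteaError):
    """Malformed scenario document (parse failure, unknown key, bad value)."""


class ScenarioValidationError(ScenarioError):
    """A scenario violates one or more hard invariants."""

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__(
            "scenario violates %d invariant(s):\n  %s"
            % (len(self.violations), "\n  ".join(self.violations))
        )


class PricingError(MagneteaError):
    """A material referenced by the process model has no price entry."""


class SolverError(MagneteaError):
    """Root finding failed (e.g. no sign change on the price grid)."""
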