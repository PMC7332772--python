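"""Exception types shared across the pipeline."""


class DomainError(ValueError):
    """An input violates a physical or mathematical precondition."""


class StateError(ValueError):
    """A model state is physically inconsistent (e.g. fiber longer than MTU)."""


class ContractionSolveError(RuntimeError):
    """The fiber-velocity force balance has no admissible root.

    Carries the offending state for diagnosis.
    """

    def __init__(self, message: str, state: dict | None = None):
        super().__init__(message if state is None else f"{message} (state: {state})")
        self.state = state or {}


class ConfigurationError(ValueError):
    """A configuration value (file content, window, bracket) is unusable."""


class WindowError(ValueError):
    """An energy-rate fit was requested outside the admissible validation window."""
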