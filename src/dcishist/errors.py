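"""Exception types shared across the package."""


class DcishistError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(DcishistError, ValueError):
    """A natural-history or schedule parameter violates its constraints."""


class ConfigConflictError(DcishistError, ValueError):
    """Parameters contradict the active submodel configuration."""


class InputError(DcishistError, ValueError):
    """Malformed user-supplied input (tables, schedules, weights)."""


class ConsistencyError(DcishistError, ValueError):
    """Paired event logs violate the shared-woman contract."""


class DegenerateExpectedError(DcishistError, ValueError):
    """Chi-square expected value is zero or negative where observed is positive."""
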