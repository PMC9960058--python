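"""Exception hierarchy for casekin.

Every error raised by the library derives from :class:`CasekinError`, so
callers (and the CLI) can distinguish domain failures from programming
errors.  Stage-level wrappers attach the failing stage name.
"""

from __future__ import annotations


class CasekinError(Exception):
    """Base class for all casekin errors."""


class InvalidParameterError(CasekinError, ValueError):
    """A kinetic or configuration parameter is out of its valid domain."""


class InvalidGridError(CasekinError, ValueError):
    """A time or wavenumber grid violates its contract (NaN, non-monotone...)."""


class DegenerateRatesError(CasekinError, ValueError):
    """Effective rate constants coincide beyond tolerance where the
    closed form requires them distinct."""


class RootNotFoundError(CasekinError, RuntimeError):
    """No sign change found when bracketing a transcendental root.

    Carries the bracket that was scanned so the failure is diagnosable.
    """

    def __init__(self, message: str, bracket: tuple[float, float] | None = None):
        super().__init__(message)
        self.bracket = bracket


class IntegrationError(CasekinError, RuntimeError):
    """The ODE integrator failed to converge."""


class GridMismatchError(CasekinError, ValueError):
    """Two spectra do not share an identical wavenumber grid; explicit
    regridding is required (no silent interpolation)."""


class OutOfRangeError(CasekinError, ValueError):
    """A requested wavenumber/anchor/time lies outside the data span."""


class NormalizationError(CasekinError, ValueError):
    """Equal-area normalization is impossible (non-positive window area)."""


class EmptyInputError(CasekinError, ValueError):
    """An operation that needs data received an empty collection."""


class ConfigError(CasekinError, ValueError):
    """A run configuration failed schema validation.

    ``key`` names the offending entry.
    """

    def __init__(self, message: str, key: str | None = None):
        super().__init__(message if key is None else f"{key}: {message}")
        self.key = key


class StageError(CasekinError, RuntimeError):
    """Wraps an error raised inside a named pipeline stage."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage '{stage}' failed: {original}")
        self.stage = stage
        self.original = original
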