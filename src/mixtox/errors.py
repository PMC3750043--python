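"""Exception hierarchy for mixtox.

All package errors derive from :class:`MixtoxError` so callers can catch
one base class; the subclasses distinguish bad inputs from statistical or
numerical failures.
"""


class MixtoxError(Exception):
    """Base class for all mixtox errors."""


class InputError(MixtoxError, ValueError):
    """Malformed or insufficient input data (bad table, too few groups...)."""


class NotSignificantError(MixtoxError):
    """Dataset failed the Kruskal-Wallis significance gate; it must not be fitted."""


class DirectionAmbiguityError(MixtoxError):
    """Per-concentration means straddle the control level with no dominant side."""


class FitConvergenceError(MixtoxError):
    """The constrained Hill fit (or too many bootstrap refits) failed to converge."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class EffectRangeError(MixtoxError, ValueError):
    """Requested effect level lies outside a chemical's predictable range.

    This is the error that truncates concentration-addition predictions when
    a mixture contains partial-efficacy components.
    """


class NotApplicableError(MixtoxError):
    """A prediction model may not be computed for these components.

    Raised for opposing-direction mixtures (no model applies), for empty
    effective-component lists, and for independent action with stimulatory
    components.
    """
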