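"""Exception hierarchy for dcaw.

All package errors derive from :class:`DCAError` so callers can catch a
single base class; the CLI maps input errors to exit code 1 and numerical
failures to exit code 2.
"""


class DCAError(Exception):
    """Base class for all dcaw errors."""


class InputError(DCAError, ValueError):
    """Malformed or inconsistent user input (lengths, columns, labels, ranges)."""


class DomainError(DCAError, ValueError):
    """A scalar argument lies outside its mathematical domain, e.g. a
    threshold probability outside the open interval (0, 1)."""


class DegenerateDecisionsError(DCAError, RuntimeError):
    """The observed decisions are all-treat or no-treat, so the threshold
    distribution is not identifiable from (Z, p_d)."""


class FitError(DCAError, RuntimeError):
    """A risk-model fit failed (degenerate outcome, separation, non-convergence)."""


class ConfigError(DCAError, ValueError):
    """Invalid simulation or run configuration."""
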