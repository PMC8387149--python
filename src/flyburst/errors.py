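"""Exception hierarchy for flyburst.

All errors derive from :class:`FlyburstError` so callers can catch the
package's failures with a single except clause; the subclasses distinguish
malformed files, invariant violations, and unusable configurations.
"""


class FlyburstError(Exception):
    """Base class for all flyburst errors."""


class FormatError(FlyburstError, ValueError):
    """A delimited-text file is structurally wrong (e.g. a required column is missing)."""


class ParseError(FlyburstError, ValueError):
    """A cell could not be parsed; the message carries the 1-based line number."""


class ValidationError(FlyburstError, ValueError):
    """A domain invariant is violated (negative value, spike beyond trace duration, ...)."""


class ConfigError(FlyburstError, ValueError):
    """A run or simulation configuration is internally inconsistent."""


class InsufficientReferenceError(FlyburstError, ValueError):
    """Fewer than two classifiable wild-type traces: no reference band can be built."""


class DegenerateDesignError(FlyburstError, ValueError):
    """A regression design with no variation in x."""
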