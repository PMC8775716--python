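"""Exception hierarchy for fibrilmorph."""


class FibrilmorphError(Exception):
    """Base class for all package errors."""


class InvalidSpecError(FibrilmorphError, ValueError):
    """A simulation spec violates its invariants."""


class DegenerateTraceError(FibrilmorphError, ValueError):
    """A trace cannot be normalized (e.g. constant signal in minmax mode)."""


class FitFailureError(FibrilmorphError, RuntimeError):
    """A non-linear fit did not converge or produced invalid geometry."""


class BaselineError(FibrilmorphError, RuntimeError):
    """Baseline subtraction could not identify flat flanking windows."""


class FlatteningError(FibrilmorphError, ValueError):
    """A scanline is too short to fit the requested background polynomial."""


class TracingError(FibrilmorphError, RuntimeError):
    """Ridge tracing failed (no path between seeds under the cost cap)."""


class PlacementError(FibrilmorphError, RuntimeError):
    """Synthetic fibril placement failed after bounded retries."""

    def __init__(self, population_index: int, message: str | None = None):
        self.population_index = population_index
        super().__init__(
            message
            or f"could not place fibril from population {population_index} "
            "without crossing after bounded retries"
        )


class ConfigError(FibrilmorphError, ValueError):
    """Run configuration is invalid (unknown keys, bad values)."""


class ParseError(FibrilmorphError, ValueError):
    """An input file could not be parsed."""
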