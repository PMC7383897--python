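"""Exception hierarchy shared across the package."""


class SpiralSortError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(SpiralSortError, ValueError):
    """A configuration object or file is invalid."""


class InputError(SpiralSortError, ValueError):
    """User-supplied data violates a precondition."""


class MissingModelEntryError(SpiralSortError, KeyError):
    """A (cell class, flow rate) combination has no measured entry.

    Raised instead of silently extrapolating: lateral equilibrium
    positions exist only where they were measured.
    """

    def __init__(self, cell_class: str, flow_rate: float):
        self.cell_class = cell_class
        self.flow_rate = flow_rate
        super().__init__(
            f"no focusing data for class {cell_class!r} at "
            f"{flow_rate} ml/min; positions are never extrapolated"
        )
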