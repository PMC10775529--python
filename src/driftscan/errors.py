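"""Exception types shared across the pipeline."""


class DriftscanError(Exception):
    """Base class for all package errors."""


class ValidationError(DriftscanError, ValueError):
    """Invalid input values or malformed data."""


class DesignError(DriftscanError, ValueError):
    """A request that contradicts the experimental design (e.g. a single
    parent in an obligate-outcrossing mating scheme)."""
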