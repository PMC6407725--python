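"""Exception hierarchy shared by all evomedia modules."""


class EvoMediaError(Exception):
    """Base class for all package errors."""


class FormatError(EvoMediaError):
    """An input file does not have the expected columns or layout."""


class ValidationError(EvoMediaError):
    """A value violates a domain invariant (bounds, counts, signs)."""


class StateError(EvoMediaError):
    """An operation was called in the wrong campaign state."""


class ReconciliationError(EvoMediaError):
    """Provided results do not line up with the expected treatments/wells."""


class DegeneratePopulationError(EvoMediaError):
    """Selection or reproduction cannot proceed (zero wheel, no unique offspring)."""


class InfeasibleDesignError(EvoMediaError):
    """A requested design cannot be realized (capacity, volumes, targets)."""
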