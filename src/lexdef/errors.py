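"""Exception types shared across lexdef modules."""


class LexdefError(Exception):
    """Base class for all lexdef errors."""


class TableParseError(LexdefError, ValueError):
    """A cross-section fixture is malformed (bad row, order, or sign)."""


class EnergyRangeError(LexdefError, ValueError):
    """An energy lies outside the tabulated range; no extrapolation."""


class ValidationError(LexdefError, ValueError):
    """An input object violates its declared invariants."""


class CrossoverNotFoundError(LexdefError, RuntimeError):
    """No photoelectric/scattering crossover exists in the scanned range."""


class DegenerateInputError(LexdefError, ValueError):
    """An operation was asked to divide by a structurally zero quantity."""


class AlignmentError(LexdefError, ValueError):
    """Two survival curves do not share a common dose grid."""


class FitError(LexdefError, RuntimeError):
    """A model fit is singular or otherwise impossible."""


class IdentifiabilityError(LexdefError, RuntimeError):
    """Parameter recovery lacks the experimental arms it needs."""
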