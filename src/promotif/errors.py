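"""Exception hierarchy shared across the toolkit."""


class PromotifError(Exception):
    """Base class for all toolkit errors."""


class CoordinateError(PromotifError):
    """A requested genomic interval falls outside its chromosome."""


class ChromosomeNotFoundError(PromotifError, KeyError):
    """The genome has no chromosome of the requested name."""


class HighNContentError(PromotifError):
    """A window exceeds the allowed fraction of ambiguous (N) bases."""


class PlacementError(PromotifError):
    """Negative-set sampling could not place the requested windows."""


class ConfigError(PromotifError, ValueError):
    """An option value violates its contract (fractions, window sizes...)."""


class ShapeError(PromotifError, ValueError):
    """Array dimensions are inconsistent with each other."""


class DegenerateInputError(PromotifError, ValueError):
    """Input is formally valid but carries no usable signal (e.g. all-zero
    attention, zero-variance distances)."""


class AlphabetError(PromotifError, ValueError):
    """A motif contains characters outside the DNA alphabet {A,C,G,T,N}."""


class DomainError(PromotifError, ValueError):
    """Parameters lie outside the mathematical domain of a distribution."""
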