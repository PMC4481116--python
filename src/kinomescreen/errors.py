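"""Exception hierarchy for screen validation and degenerate statistics."""


class ScreenError(ValueError):
    """Base class for all kinomescreen errors."""


class LayoutError(ScreenError):
    """Invalid or incomplete plate layout."""


class LoadError(ScreenError):
    """A TSV input failed validation; the message names the offending record."""


class DegenerateControlError(ScreenError):
    """Control wells cannot serve as a denominator (zero mean or missing)."""


class DegeneratePlateError(ScreenError):
    """Plate statistics are undefined (zero scale factor or zero spread)."""


class DegenerateVarianceError(ScreenError):
    """A replicate-screen group has zero robust spread."""


class UndefinedStatisticError(ScreenError):
    """A statistic is undefined for this input (equal control means, constant profile)."""


class InsufficientDataError(ScreenError):
    """Too few observations for the requested analysis."""
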