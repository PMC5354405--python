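"""Exception types shared across the toolkit."""


class InvalidInputError(ValueError):
    """An argument violates a physical or geometric precondition."""


class NoBoilError(InvalidInputError):
    """Heating rate too low to ever reach the boiling temperature."""


class UndefinedFWHMError(InvalidInputError):
    """No temperature elevation above baseline; FWHM is undefined."""


class NoLesionFoundError(RuntimeError):
    """Segmentation could not distinguish a lesion from background."""


class DegenerateGroupError(InvalidInputError):
    """A group has zero within-group variance; ANOVA is degenerate."""
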