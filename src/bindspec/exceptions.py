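"""Exception hierarchy for bindspec."""


class BindspecError(Exception):
    """Base class for all bindspec errors."""


class InvalidReferenceError(BindspecError):
    """The free- and bound-state reference signals coincide, so the bound
    fraction is undefined."""


class DegenerateDataError(BindspecError):
    """Input carries no usable signal (e.g. an all-zero titration column or
    a flat decay trace fitted with two components)."""


class ConvergenceError(BindspecError):
    """A nonlinear fit failed to converge within the iteration budget."""


class EmptySeriesError(BindspecError):
    """Every point of a series was dropped as non-physical."""


class SplitError(BindspecError):
    """A subset split would leave fewer points than a line fit requires."""


class NonDecayError(BindspecError):
    """A Scatchard subset has non-negative slope: the data do not show the
    decreasing ratio-vs-occupancy dependence the site model predicts."""


class ParallelLinesError(BindspecError):
    """Two lines with equal slope have no unique intersection."""


class NoPeakError(BindspecError):
    """No derivative peak found inside the requested temperature window."""


class SchemaError(BindspecError):
    """A CSV or config file does not match its declared schema."""


class ConfigError(BindspecError):
    """A run configuration is invalid (unknown key, missing file...)."""
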