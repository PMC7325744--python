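"""Exception hierarchy shared across the pipeline."""


class PopdiallelError(Exception):
    """Base class for all package-specific errors."""


class FieldbookFormatError(PopdiallelError):
    """A required column is missing or the file layout is unusable."""


class ValueParseError(PopdiallelError):
    """A cell could not be parsed; message carries the 1-based row number."""


class IntegrityError(PopdiallelError):
    """A record violates a domain invariant (duplicate ids, bound Trp, ...)."""


class ConfigError(PopdiallelError):
    """Invalid analysis configuration (weights out of range, bad alpha, ...)."""


class DegenerateDesignError(PopdiallelError):
    """The requested model term is confounded or the design is empty."""


class EmptyDesignError(DegenerateDesignError):
    """No usable observations for the requested analysis."""


class DegenerateTraitError(PopdiallelError):
    """A trait cannot enter the ranking index (zero best value)."""


class CollinearityError(PopdiallelError):
    """Predictors are perfectly collinear; path coefficients undefined."""


class UndefinedRatioError(PopdiallelError):
    """All variance components are zero; heritability is undefined."""
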