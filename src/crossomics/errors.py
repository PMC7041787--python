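"""Exception hierarchy shared by all pipeline stages."""


class CrossomicsError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(CrossomicsError):
    """An input file violates its declared format."""


class ConfigError(CrossomicsError):
    """A configuration value is invalid or inconsistent."""


class DegenerateInputError(CrossomicsError):
    """Input is syntactically valid but statistically degenerate
    (e.g. zero overall variance, no positive MDS eigenvalue)."""


class ConsistencyError(CrossomicsError):
    """Two pipeline artifacts disagree (e.g. a scored gene missing from the
    annotation, a gene assigned to two modules)."""
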