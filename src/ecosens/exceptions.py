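"""Exception hierarchy shared across the package."""


class EcosensError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(EcosensError, ValueError):
    """A configuration object violates its invariants."""


class InputError(EcosensError, ValueError):
    """An input (file, table, series, tree) violates a precondition."""


class DegenerateInputError(InputError):
    """Input is structurally valid but statistically degenerate
    (constant series, perfectly collinear regressors, zero null variance)."""
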