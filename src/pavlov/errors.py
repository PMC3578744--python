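"""Exception hierarchy for the pavlov package."""


class PavlovError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(PavlovError, ValueError):
    """Invalid or infeasible task/pipeline configuration."""


class FitError(PavlovError, ValueError):
    """Regression or grid-search failure (degenerate design, too few trials)."""


class NumericalError(PavlovError, ArithmeticError):
    """Numerical breakdown: zero-likelihood observation, non-convergence."""
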