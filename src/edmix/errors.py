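"""Exception hierarchy shared across the pipeline."""


class EdmixError(Exception):
    """Base class for all package-specific errors."""


class InvalidCellError(EdmixError, ValueError):
    """Unit-cell parameters that do not describe a real lattice."""


class ReductionError(EdmixError, RuntimeError):
    """Niggli reduction failed to converge within the iteration bound."""


class ConfigurationError(EdmixError, ValueError):
    """Invalid run configuration (empty library, unknown Laue group, bad tolerance)."""


class InputError(EdmixError, ValueError):
    """Malformed input data (duplicate crystal ids, unparsable tables)."""


class UndefinedRatioError(EdmixError, ZeroDivisionError):
    """A ratio was requested with a zero denominator."""


class NoThresholdError(EdmixError, ValueError):
    """Automatic thresholding is impossible (empty or constant image)."""


class MissingCrystalError(EdmixError, ValueError):
    """No particle was found in an image when one was required."""


class UnmergeablePairError(EdmixError, ValueError):
    """Datasets share too few common reflections for relative scaling."""


class EmptyStatisticsError(EdmixError, ValueError):
    """No unique reflections within the resolution limit."""


class BudgetExceededError(EdmixError, RuntimeError):
    """Exhaustive subset enumeration would exceed the configured budget.

    Callers should fall back to the greedy strategy.
    """


class GenerationError(EdmixError, ValueError):
    """Synthetic data request that cannot be honoured (e.g. crystal larger than frame)."""


class SpecError(EdmixError, ValueError):
    """Invalid mixture specification (fractions or probabilities out of range)."""
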