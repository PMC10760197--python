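"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Invalid parameters or data (non-stochastic matrix, bad fractions, ...)."""


class ShapeError(ValueError):
    """Array dimensionality does not match what a model or metric expects."""


class UndefinedMetricError(ValueError):
    """A metric has no defined value for the given input (e.g. all-zero latents)."""


class TrainingDivergedError(RuntimeError):
    """Optimization produced a non-finite loss; carries epoch and config context."""
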