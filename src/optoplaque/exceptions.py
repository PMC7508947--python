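"""Exception hierarchy shared across the pipeline."""


class OptoPlaqueError(Exception):
    """Base class for all package errors."""


class ParameterError(OptoPlaqueError, ValueError):
    """Invalid parameter value (durations, rates, filter sizes, ...)."""


class AnalysisError(OptoPlaqueError, RuntimeError):
    """An analysis precondition failed on otherwise valid data
    (missing period, zero normalizer, empty cell, ...)."""


class PlacementError(OptoPlaqueError, RuntimeError):
    """Synthetic blob placement could not satisfy the separation
    constraint within the retry budget."""
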