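"""Exception types shared across the pipeline."""


class ParameterError(ValueError):
    """A configuration or call parameter is invalid or infeasible."""


class PackingError(RuntimeError):
    """Nuclei could not be placed without overlap at the requested density."""


class DataError(ValueError):
    """An input record violates its invariant (e.g. inconsistent fractions)."""
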