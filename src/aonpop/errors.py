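"""Exception hierarchy shared across the pipeline."""


class AonpopError(Exception):
    """Base class for pipeline errors."""


class ParameterError(AonpopError, ValueError):
    """A caller-supplied parameter is out of range or inconsistent."""


class FormatError(AonpopError, ValueError):
    """An input file or array does not conform to the expected layout."""


class SchemaError(FormatError):
    """A tabular file violates its schema (missing column, bad value)."""


class DegenerateInputError(AonpopError, ValueError):
    """The input is formally valid but leaves nothing to compute on."""


class MeasurementError(AonpopError, RuntimeError):
    """A waveform landmark (peak, inflection) could not be located."""


class DependencyError(AonpopError, RuntimeError):
    """A pipeline stage was requested before the stages it depends on."""
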