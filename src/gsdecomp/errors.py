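"""Exception hierarchy shared across the pipeline."""


class GsdecompError(Exception):
    """Base class for all package errors."""


class FormatError(GsdecompError, ValueError):
    """On-disk file does not conform to the expected TSV/JSON schema."""


class InputError(GsdecompError, ValueError):
    """Arguments are structurally invalid (shape, rank, range)."""


class SignalQualityError(GsdecompError, ValueError):
    """A physiological trace is too poor to analyse (e.g. no detectable beats)."""


class DegenerateSignalError(GsdecompError, ValueError):
    """A derived series is constant/zero where variability is required."""


class EstimationError(GsdecompError, RuntimeError):
    """An optimisation failed on every start point."""
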