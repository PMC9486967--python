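"""Exception hierarchy shared across the toolkit."""


class SrnaforgeError(Exception):
    """Base class for all toolkit errors."""


class ParseError(SrnaforgeError):
    """A sequence file could not be parsed."""


class DesignError(SrnaforgeError):
    """Seed/oligo/primer design preconditions violated."""


class AssemblyError(SrnaforgeError):
    """Digestion or ligation simulation cannot proceed."""


class PredictorUnavailableError(SrnaforgeError):
    """The external interaction predictor executable is missing."""


class AssayError(SrnaforgeError):
    """Growth/fluorescence assay input is invalid."""
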