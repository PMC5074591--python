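"""Exception hierarchy used across the package."""


class MetaboMRError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(MetaboMRError, ValueError):
    """A numeric parameter is outside its admissible range."""


class StructuralError(MetaboMRError, ValueError):
    """Dimensions or identifiers of inputs do not line up."""


class DataError(MetaboMRError, ValueError):
    """Input data violate a hard precondition (e.g. negative intensity)."""


class ConfigurationError(MetaboMRError, ValueError):
    """A requested analysis option is inconsistent with the inputs."""


class HarmonizationError(MetaboMRError, ValueError):
    """Allele sets of a genotype file and a score definition are incompatible."""


class WeakInstrumentError(MetaboMRError, ZeroDivisionError):
    """The instrument-exposure association is exactly zero; ratio undefined."""


class ConvergenceError(MetaboMRError, RuntimeError):
    """An iterative optimiser failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class ParseError(MetaboMRError, ValueError):
    """A table on disk is malformed; message carries the line number."""
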