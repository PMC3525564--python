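"""Exception types shared across the package."""


class HeteroplasmyError(Exception):
    """Base class for all package-specific errors."""


class ExtinctLineageError(HeteroplasmyError):
    """A cell or population with zero mtDNA molecules cannot be propagated."""


class UndefinedLoadError(HeteroplasmyError):
    """A mutation-load estimate was requested from a readout with no informative dots."""


class InfeasibleParameterError(HeteroplasmyError, ValueError):
    """Parameters are mutually inconsistent (e.g. mean dots exceeding unit count)."""


class EmptyHistogramError(HeteroplasmyError):
    """No cell survived the dots/cell stringency filter."""


class DatasetFormatError(HeteroplasmyError):
    """A synthetic dataset file could not be parsed."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)
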