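"""Exception hierarchy shared across the package."""


class KnnBenchError(Exception):
    """Base class for all package errors."""


class DimensionError(KnnBenchError, ValueError):
    """Operands have incompatible or empty dimensions."""


class ParameterError(KnnBenchError, ValueError):
    """A parameter is outside its admissible range or unknown."""


class DomainError(KnnBenchError, ValueError):
    """An input lies outside the mathematical domain of an operation."""


class DegenerateInputError(KnnBenchError, ValueError):
    """An input is degenerate for the requested operation (e.g. zero denominator)."""


class UnknownMetricError(KnnBenchError, KeyError):
    """A metric name is not present in the registry."""


class ProtocolError(KnnBenchError, ValueError):
    """An evaluation protocol is invalid for the given data set."""


class AlignmentError(KnnBenchError, ValueError):
    """Rankings or lists do not share a common item set."""


class IncompleteTensorError(KnnBenchError, ValueError):
    """A score tensor is missing cells required by an operation."""


class CSVFormatError(KnnBenchError, ValueError):
    """A CSV data file is malformed (missing label column, non-numeric cell, ...)."""
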