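"""Exception hierarchy for coprog."""


class CoprogError(Exception):
    """Base class for all coprog errors."""


class FormatError(CoprogError):
    """A file could not be parsed in any supported format."""


class ValidationError(CoprogError):
    """Input tables or configuration violate a structural requirement."""


class EmptySampleError(ValidationError):
    """No cells survive loading/alignment."""


class InsufficientDataError(CoprogError):
    """Too few cells (or too little rank) for the requested operation."""


class ParameterError(CoprogError):
    """An invalid parameter value (e.g. non-positive bandwidth)."""


class DimensionError(CoprogError):
    """Shapes of kernels, embeddings, or weights are inconsistent."""


class DegenerateKernelError(CoprogError):
    """A kernel carries no usable weight for the requested update."""


class DegenerateSupervisionError(CoprogError):
    """Supervision labels carry no usable signal (e.g. constant)."""


class UndefinedMetricError(CoprogError):
    """A coordination metric is undefined for the given scores/kernel."""


class InsufficientSupportError(UndefinedMetricError):
    """Too few cells remain after the kernel-support exclusion rule."""
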