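"""Exception hierarchy shared across the pipeline stages."""


class DwdcError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(DwdcError, ValueError):
    """A configuration or argument value violates its contract."""


class EmptyStructureError(DwdcError):
    """An operation that requires foreground structure received none.

    Raised e.g. when a threshold is requested on an all-zero image, or when
    deconvolution is asked to process an empty mask.
    """


class OverProcessingError(DwdcError):
    """Deconvolution diverged: total intensity grew far beyond the input.

    Guards against the runaway amplification failure mode of iterative
    Richardson-Lucy on noisy masks.
    """


class UndefinedFWHMError(DwdcError):
    """A line profile does not cross half-maximum on both sides of its peak."""
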