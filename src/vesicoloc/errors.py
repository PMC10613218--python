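"""Exception hierarchy used across the package."""


class VesicolocError(Exception):
    """Base class for all package errors."""


class FormatError(VesicolocError):
    """A file could not be read or written in the expected format."""


class DimensionError(VesicolocError):
    """An array's shape is inconsistent with the declared layout."""


class ParameterError(VesicolocError):
    """A configuration value violates its contract (e.g. degenerate range)."""


class GeometryError(VesicolocError):
    """A geometric precondition failed (empty mask, anchor outside image)."""


class GenerationError(VesicolocError):
    """Synthetic-scene generation could not satisfy placement constraints."""


class ContractError(VesicolocError):
    """Mismatched inputs to an operation (e.g. profiles on different geometry)."""


class UndersamplingError(VesicolocError):
    """A density grid would alias the Gaussian kernel (voxel size > sigma)."""
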