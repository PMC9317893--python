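"""Exception hierarchy shared across the pipeline."""


class PallidexError(Exception):
    """Base class for all package-specific errors."""


class DimensionalityError(PallidexError):
    """Image does not have exactly three spatial dimensions."""


class ValidationError(PallidexError):
    """Input violates a container invariant (non-finite voxels, negative ids, ...)."""


class GeometryError(PallidexError):
    """Grids, spacings or affines are inconsistent, or a structure does not fit."""


class ContractError(PallidexError):
    """An operation was called outside its contract."""


class AlignmentError(PallidexError):
    """Affine alignment cannot proceed (e.g. constant image)."""


class SimilarityError(PallidexError):
    """Similarity undefined (zero variance within the mask)."""


class EstimationError(PallidexError):
    """Tissue-peak estimation failed to resolve the expected classes."""


class ExtractionError(PallidexError):
    """Region-of-interest extraction found no voxels (subject unanalyzable)."""
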