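"""Exception hierarchy.

All package errors derive from :class:`LeukoSelectError` so callers can
catch one base class at the pipeline boundary.
"""


class LeukoSelectError(Exception):
    """Base class for all package errors."""


class InvalidGeometryError(LeukoSelectError):
    """A sampled cell geometry cannot be rendered inside the frame."""


class LabelParsingError(LeukoSelectError):
    """An image file carries neither a `_0`/`_1` suffix nor a manifest entry."""


class SegmentationDegenerateError(LeukoSelectError):
    """Segmentation is undefined (e.g. zero-variance image, Otsu has no threshold)."""


class EmptyRegionError(LeukoSelectError):
    """A descriptor was asked to summarize an empty pixel region."""


class TextureDegenerateError(LeukoSelectError):
    """Every co-occurrence offset was dropped (region too small)."""


class ExtractionError(LeukoSelectError):
    """Feature extraction failed for a specific sample."""

    def __init__(self, sample_id: str, message: str):
        self.sample_id = sample_id
        super().__init__(f"feature extraction failed for sample {sample_id!r}: {message}")


class BackboneUnavailableError(LeukoSelectError):
    """No pretrained deep backbone is available; use the descriptor bank."""


class FoldError(LeukoSelectError):
    """Cross-validation folds cannot be formed (class smaller than fold count)."""


class DegenerateSelectionError(LeukoSelectError):
    """A selector produced no usable candidate in its entire budget."""


class SizeGuardError(LeukoSelectError):
    """Exhaustive search refused: too many features to enumerate."""


class SplitError(LeukoSelectError):
    """A stratified train/test split cannot be formed."""


class DegenerateTrainingError(LeukoSelectError):
    """A classifier was given a single-class training set."""


class DesignError(LeukoSelectError):
    """A statistical design violates the balanced-layout contract."""
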