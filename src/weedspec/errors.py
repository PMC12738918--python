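"""Exception hierarchy for the weedspec pipeline."""


class WeedspecError(Exception):
    """Base class for all weedspec errors."""


class FormatError(WeedspecError):
    """A file is missing required metadata or is not in the expected dialect."""


class IntegrityError(WeedspecError):
    """Header metadata and binary payload disagree."""


class DegenerateReferenceError(WeedspecError):
    """White and dark calibration references coincide somewhere."""


class EmptySelectionError(WeedspecError):
    """A band/pixel selection matched nothing."""


class DegenerateThresholdError(WeedspecError):
    """Automatic thresholding is undefined (e.g. constant image)."""


class UndefinedIndexError(WeedspecError):
    """A vegetation index has a zero denominator."""


class ParameterError(WeedspecError):
    """An operation parameter is out of its valid range."""


class StratificationError(WeedspecError):
    """A class has too few samples for the requested stratified split."""


class ShapeMismatchError(WeedspecError):
    """Two arrays that must share a shape do not."""


class ConstructionError(WeedspecError):
    """A model layer chain is internally inconsistent."""


class UndefinedMetricError(WeedspecError):
    """An accuracy metric is undefined for this confusion matrix."""
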