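"""Exception hierarchy for gfpquant."""


class GfpQuantError(Exception):
    """Base class for all gfpquant errors."""


class ImageFormatError(GfpQuantError):
    """Raised for image layouts the loader cannot interpret."""


class EmptySignalError(GfpQuantError):
    """Raised when an image contains no fluorescent signal to threshold."""


class UndefinedBaselineError(GfpQuantError):
    """Raised when the 0 hpi measurement is zero, so the index denominator vanishes."""


class PairingError(GfpQuantError):
    """Raised when two records cannot be paired into a 0/72 hpi comparison."""


class PlacementError(GfpQuantError):
    """Raised when phantom disk placement cannot satisfy the separation constraint."""


class ManifestError(GfpQuantError):
    """Raised for malformed batch manifests."""
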