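"""Exception hierarchy shared across the package."""


class LakeHybridError(Exception):
    """Base class for all errors raised by lakehybrid."""


class DataError(LakeHybridError):
    """Malformed or insufficient input data."""


class EmbeddingError(LakeHybridError):
    """Invalid embedding specification or state-matrix construction failure."""


class ZeroVarianceError(EmbeddingError):
    """A coordinate has zero variance over the library and cannot be normalized."""

    def __init__(self, coordinate):
        self.coordinate = coordinate
        super().__init__(
            f"coordinate {coordinate!r} has zero variance over the library rows; "
            "cannot z-normalize"
        )


class InsufficientLibraryError(LakeHybridError):
    """Too few library points for the requested neighbor count or regression."""


class ForcingError(DataError):
    """Invalid physical forcing input."""
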