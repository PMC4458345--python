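"""Exception hierarchy for the los3d pipeline."""


class Los3dError(Exception):
    """Base class for all los3d errors."""


class InputFormatError(Los3dError):
    """An input file or array violates the supported format contract."""


class ValidationError(Los3dError):
    """In-memory data violates an invariant (shapes, ids, spacing, ...)."""


class DegenerateClumpError(Los3dError):
    """A clump is too small to carry surface-point pairs."""


class ClusteringError(Los3dError):
    """Fewer lines than requested clusters."""
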