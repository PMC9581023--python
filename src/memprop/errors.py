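"""Exception types shared across the package."""


class MempropError(Exception):
    """Base class for all package errors."""


class ParseError(MempropError):
    """A structure file could not be read."""


class EmptyModelError(MempropError):
    """No amino-acid residues remain after chain selection."""


class CoverageError(MempropError):
    """A membrane label file does not cover the structure's residues."""


class InvalidSlabError(MempropError):
    """Membrane slab with z_lo >= z_hi."""


class ConfigMismatchError(MempropError):
    """Descriptor table and potential table built under different configs."""


class EmptyCountsError(MempropError):
    """A frequency model received zero observations."""


class DegenerateFitError(MempropError):
    """Training data contains a single label class."""


class ManifestError(MempropError):
    """Feature columns do not match the model manifest."""


class ParameterError(MempropError):
    """Invalid numeric parameter (negative weight, non-positive sigma...)."""


class AlignmentError(MempropError):
    """Residue correspondence between profiles could not be established."""
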