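"""Exception hierarchy shared across the package."""


class BallhistError(Exception):
    """Base class for all package-specific errors."""


class StructureParseError(BallhistError):
    """A structure file could not be read or parsed."""


class EmptyStructureError(BallhistError):
    """A structure contains no usable (alpha-carbon-bearing) residues."""


class DegenerateSamplingError(BallhistError):
    """Every Monte-Carlo draw fell outside the protein; the histogram cannot be normalized."""


class DataError(BallhistError):
    """Invalid dataset, manifest, template or configuration content."""
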