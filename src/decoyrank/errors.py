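"""Exception hierarchy for decoyrank.

All package-specific failures derive from :class:`DecoyRankError` so callers
(and the CLI) can distinguish validation problems from data problems.
"""


class DecoyRankError(Exception):
    """Base class for all decoyrank errors."""


class FormatError(DecoyRankError):
    """A file does not conform to the expected dialect."""


class PDBFormatError(FormatError):
    pass


class PSSMFormatError(FormatError):
    pass


class ConsistencyError(DecoyRankError):
    """Structures that must agree (e.g. decoy lengths) do not."""


class DimensionMismatchError(DecoyRankError):
    """Two structures or vectors have incompatible sizes."""


class InsufficientClustersError(DecoyRankError):
    """Fewer clusters could be formed than requested.

    Mirrors the exclusion of proteins whose decoys cannot be clustered into
    the requested number of candidates.
    """

    def __init__(self, formed: int, requested: int):
        self.formed = formed
        self.requested = requested
        super().__init__(
            f"only {formed} clusters could be formed, {requested} requested"
        )


class DegenerateInputError(DecoyRankError):
    """Input is structurally valid but degenerate for the operation."""


class ConfigurationError(DecoyRankError):
    """Inconsistent or incomplete run configuration."""
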