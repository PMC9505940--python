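"""Exception hierarchy shared across the package."""


class PspGnmError(Exception):
    """Base class for all package-specific errors."""


class PotentialParseError(PspGnmError):
    """Malformed AAindex matrix record; message names the offending line."""


class UnknownResidueError(PspGnmError):
    """A residue code outside the 20 standard amino acids was looked up."""


class StructureError(PspGnmError):
    """Problems parsing or interpreting a coarse-grained structure."""


class ChainNotFoundError(StructureError):
    """Requested chain absent from the PDB file."""


class WildtypeMismatchError(PspGnmError):
    """The residue in the structure does not match the stated wildtype.

    Mirrors the benchmark curation rule that drops mutations whose wildtype
    residue is absent at the stated position in the PDB file.
    """


class UnstableModelError(PspGnmError):
    """Kirchhoff matrix has more than one zero eigenvalue (fragmented network)."""


class DegenerateInputError(PspGnmError):
    """Statistical operation received constant or empty input."""
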