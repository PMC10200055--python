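"""Exception types shared across sefkit modules.

All inherit ``ValueError`` so callers that only care about "bad input"
can catch one base class.
"""


class SefError(ValueError):
    """Base class for all sefkit input errors."""


class EmptyInputError(SefError):
    """An operation received an empty string, sequence or table."""


class MalformedInputError(SefError):
    """A string representation violates the token grammar.

    Attributes
    ----------
    offset : int
        0-based character offset where the violation was detected.
    """

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (offset {offset})")
        self.offset = offset


class ParseError(SefError):
    """A string could not be parsed into a molecule."""

    def __init__(self, smiles: str, message: str = "unparseable SMILES"):
        super().__init__(f"{message}: {smiles!r}")
        self.smiles = smiles


class DegenerateMoleculeError(SefError):
    """A molecule has no countable atoms."""


class UnknownBondTypeError(SefError):
    """A bond's type is outside the predefined bond-type list."""

    def __init__(self, bond_type: str):
        super().__init__(f"bond type {bond_type!r} is not in the predefined list")
        self.bond_type = bond_type


class CapacityError(SefError):
    """A profile does not fit in the requested padded width."""

    def __init__(self, n_atoms: int, n_max: int):
        super().__init__(
            f"molecule has {n_atoms} atoms but padded width n_max={n_max}"
        )
        self.n_atoms = n_atoms
        self.n_max = n_max


class EmptyMatrixError(SefError):
    """Featurization produced no valid rows."""
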