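"""Shannon-entropy descriptors: token entropy, per-atom fractional
entropy with padding, and bond-frequency profiles.

The scalar descriptor for a molecule is the Shannon entropy of its token
frequencies,

    S_m = -sum_i f_i * log2(f_i),        f_i = n_i / N,

in bits, where n_i counts occurrences of token i and N is the total
token count.  The fractional Shannon entropy apportions S_m to each atom
species by its atom-count fraction, analogously to partial pressures in
a gas mixture: every atom of species j carries s_j = f_j * S_m, so the
per-species values sum back to S_m exactly.  The bond profile is the
frequency vector over a fixed bond-type list together with its own
Shannon entropy.

Entropies are computed as ``log2(N) - (sum n_i*log2(n_i)) / N`` so that
frequencies enter as exact integer ratios; a table with a single unique
item returns exactly 0.0.
"""

from __future__ import annotations

import math
from collections import Counter
from collections.abc import Iterable
from dataclasses import dataclass, replace

from rdkit import Chem
from rdkit.rdBase import BlockLogs

from .errors import (
    CapacityError,
    DegenerateMoleculeError,
    EmptyInputError,
    ParseError,
    UnknownBondTypeError,
)
from .tokenize import Notation, TokenSequence, tokenize

__all__ = [
    "BOND_TYPES",
    "FrequencyTable",
    "EntropyValue",
    "FractionalEntropyProfile",
    "BondProfile",
    "token_frequencies",
    "shannon_entropy",
    "string_entropy",
    "atom_species",
    "atom_frequencies",
    "fractional_entropy",
    "pad_profile",
    "bond_profile",
    "mol_from_smiles",
]

#: Predefined bond-type list, in fixed order; frequencies align to it.
BOND_TYPES: tuple[str, ...] = (
    "SINGLE",
    "DOUBLE",
    "TRIPLE",
    "QUADRUPLE",
    "AROMATIC",
    "HYDROGEN",
    "IONIC",
)


@dataclass(frozen=True)
class FrequencyTable:
    """Occurrence counts of items (tokens, atom species, bond types)."""

    counts: dict[str, int]

    @classmethod
    def from_items(cls, items: Iterable[str]) -> "FrequencyTable":
        return cls(dict(Counter(items)))

    @property
    def total(self) -> int:
        """Total occurrences N."""
        return sum(self.counts.values())

    @property
    def unique(self) -> int:
        """Number of distinct items k with positive count."""
        return sum(1 for c in self.counts.values() if c > 0)

    def frequency(self, item: str) -> float:
        """f_i = n_i / N for one item (0.0 if absent)."""
        total = self.total
        return self.counts.get(item, 0) / total if total else 0.0


@dataclass(frozen=True)
class EntropyValue:
    """A Shannon entropy in bits and the notation it came from."""

    value: float
    source_notation: Notation = Notation.SMILES


@dataclass(frozen=True)
class FractionalEntropyProfile:
    """Per-atom fractional entropies of one molecule, in atom order."""

    atom_species: tuple[str, ...]
    per_atom: tuple[float, ...]
    padded: tuple[float, ...] | None = None

    @property
    def n_atoms(self) -> int:
        return len(self.per_atom)


@dataclass(frozen=True)
class BondProfile:
    """Bond-type frequencies over :data:`BOND_TYPES` and their entropy."""

    frequencies: tuple[float, ...]
    entropy_bits: float
    counts: dict[str, int]

    bond_types: tuple[str, ...] = BOND_TYPES


def _entropy_bits(counts: Iterable[int]) -> float:
    """-sum f log2 f over positive counts, via exact integer ratios."""
    # sorted so the float summation order, hence the result, depends only
    # on the count multiset
    counts = sorted(c for c in counts if c > 0)
    if not counts:
        raise EmptyInputError("cannot take entropy of an empty table")
    if len(counts) == 1:
        return 0.0
    total = sum(counts)
    return math.log2(total) - sum(c * math.log2(c) for c in counts) / total


def token_frequencies(seq: TokenSequence) -> FrequencyTable:
    """Count the token multiset of a sequence (order-independent)."""
    if not seq.tokens:
        raise EmptyInputError("empty token sequence")
    return FrequencyTable.from_items(seq.tokens)


def shannon_entropy(
    freqs: FrequencyTable, notation: Notation = Notation.SMILES
) -> EntropyValue:
    """Shannon entropy S = -sum f_i log2 f_i of a frequency table, in bits.

    A table with one unique item returns exactly 0.0; zero-count items
    contribute nothing.
    """
    if freqs.total == 0:
        raise EmptyInputError("frequency table has zero total")
    return EntropyValue(_entropy_bits(freqs.counts.values()), notation)


def string_entropy(text: str, notation: Notation | str = Notation.SMILES) -> EntropyValue:
    """Tokenize ``text`` under ``notation`` and return its Shannon entropy."""
    seq = tokenize(text, notation)
    return shannon_entropy(token_frequencies(seq), seq.notation)


def mol_from_smiles(smiles: str, hydrogen_mode: str = "explicit") -> Chem.Mol:
    """Parse a SMILES string into an RDKit molecule.

    hydrogen_mode controls which hydrogens become atoms:

    - ``"explicit"`` (default): only hydrogens written as ``[H]`` atom
      nodes in the string are kept; implicit hydrogens are not counted.
    - ``"all"``: all hydrogens are added as atoms.
    """
    if hydrogen_mode not in ("explicit", "all"):
        raise ValueError(f"unknown hydrogen_mode {hydrogen_mode!r}")
    params = Chem.SmilesParserParams()
    params.removeHs = False
    with BlockLogs():
        mol = Chem.MolFromSmiles(smiles, params)
    if mol is None:
        raise ParseError(smiles)
    if hydrogen_mode == "all":
        mol = Chem.AddHs(mol)
    return mol


def atom_species(smiles: str, hydrogen_mode: str = "explicit") -> tuple[str, ...]:
    """Element symbols of the counted atoms, in occurrence order.

    Aromatic atoms are reported under their element symbol (``c`` -> C).
    """
    mol = mol_from_smiles(smiles, hydrogen_mode)
    return tuple(atom.GetSymbol() for atom in mol.GetAtoms())


def atom_frequencies(smiles: str, hydrogen_mode: str = "explicit") -> FrequencyTable:
    """Occurrence counts of atom species in a molecule."""
    return FrequencyTable.from_items(atom_species(smiles, hydrogen_mode))


def fractional_entropy(
    smiles: str,
    total_entropy: EntropyValue,
    hydrogen_mode: str = "explicit",
) -> FractionalEntropyProfile:
    """Apportion a molecule's total entropy to its atoms, per species.

    Each atom of species j carries s_j = (n_j / m) * S, where n_j is the
    count of species j among the m counted atoms and S the molecule's
    total entropy.  All atoms of one species share one value; summed
    over distinct species the values reproduce S exactly.
    """
    species = atom_species(smiles, hydrogen_mode)
    if not species:
        raise DegenerateMoleculeError(f"no countable atoms in {smiles!r}")
    m = len(species)
    counts = Counter(species)
    per_species = {s: (n / m) * total_entropy.value for s, n in counts.items()}
    return FractionalEntropyProfile(
        atom_species=species,
        per_atom=tuple(per_species[s] for s in species),
    )


def pad_profile(
    profile: FractionalEntropyProfile, n_max: int
) -> FractionalEntropyProfile:
    """Zero-pad a per-atom profile to fixed length ``n_max``.

    Padding is split (n_max - m) // 2 on the left and the remainder on
    the right, so an odd surplus puts the extra zero on the right.
    """
    m = profile.n_atoms
    if n_max < m:
        raise CapacityError(m, n_max)
    left = (n_max - m) // 2
    right = n_max - m - left
    return replace(
        profile, padded=(0.0,) * left + profile.per_atom + (0.0,) * right
    )


def bond_profile(smiles: str) -> BondProfile:
    """Bond-type frequencies of a molecule and their Shannon entropy.

    Frequencies align to :data:`BOND_TYPES`; they sum to 1 for a bonded
    molecule and are all zero for an atom without bonds (entropy 0).
    """
    mol = mol_from_smiles(smiles)
    counts: dict[str, int] = {}
    for bond in mol.GetBonds():
        name = bond.GetBondType().name
        if name not in BOND_TYPES:
            raise UnknownBondTypeError(name)
        counts[name] = counts.get(name, 0) + 1
    total = sum(counts.values())
    if total == 0:
        return BondProfile((0.0,) * len(BOND_TYPES), 0.0, {})
    freqs = tuple(counts.get(t, 0) / total for t in BOND_TYPES)
    return BondProfile(freqs, _entropy_bits(counts.values()), counts)
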