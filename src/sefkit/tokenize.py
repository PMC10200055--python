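"""Lossless tokenizers for molecular string notations.

SMILES and SMARTS strings are split with the community-standard atom-wise
grammar: bracket atoms ``[...]`` are single tokens, the two-letter
organic-subset halogens ``Cl``/``Br`` are single tokens, ``%nn`` two-digit
ring closures are single tokens, and every other character (aromatic
atoms, bond symbols, branch parentheses, ring digits, dots, SMARTS
logical operators) is its own token.  InChIKey strings are tokenized
character-wise, hyphens included.

All tokenizers are lossless: ``"".join(seq.tokens) == seq.source_string``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from .errors import EmptyInputError, MalformedInputError

__all__ = [
    "Notation",
    "TokenSequence",
    "tokenize_smiles",
    "tokenize_smarts",
    "tokenize_inchikey",
    "tokenize",
]


class Notation(str, Enum):
    """String notation a token sequence was extracted from."""

    SMILES = "SMILES"
    SMARTS = "SMARTS"
    INCHIKEY = "INCHIKEY"
    BONDS = "BONDS"


@dataclass(frozen=True)
class TokenSequence:
    """Ordered tokens extracted from one string representation."""

    notation: Notation
    source_string: str
    tokens: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if "".join(self.tokens) != self.source_string:
            raise AssertionError(
                "token sequence is not lossless for "
                f"{self.source_string!r}"
            )

    def __len__(self) -> int:
        return len(self.tokens)


# two-letter element symbols of the SMILES organic subset
_DIGRAPHS = ("Cl", "Br")


def _scan(text: str, notation: Notation) -> TokenSequence:
    """Shared scanner for SMILES-like grammars."""
    if not text:
        raise EmptyInputError(f"empty {notation.value} string")
    tokens: list[str] = []
    i, n = 0, len(text)
    while i < n:
        c = text[i]
        if c == "[":
            j = text.find("]", i + 1)
            if j < 0:
                raise MalformedInputError("unbalanced '[' without ']'", i)
            tokens.append(text[i : j + 1])
            i = j + 1
        elif c == "]":
            raise MalformedInputError("unmatched ']'", i)
        elif text.startswith(_DIGRAPHS, i):
            tokens.append(text[i : i + 2])
            i += 2
        elif c == "%":
            if i + 2 >= n or not text[i + 1 : i + 3].isdigit():
                raise MalformedInputError(
                    "'%' ring closure must be followed by two digits", i
                )
            tokens.append(text[i : i + 3])
            i += 3
        else:
            tokens.append(c)
            i += 1
    return TokenSequence(notation, text, tuple(tokens))


def tokenize_smiles(smiles: str) -> TokenSequence:
    """Tokenize a SMILES string atom-wise.

    Parameters
    ----------
    smiles : str
        Non-empty SMILES string.

    Returns
    -------
    TokenSequence
        Lossless ordered tokens.

    Raises
    ------
    EmptyInputError
        If ``smiles`` is empty.
    MalformedInputError
        On an unbalanced bracket or a truncated ``%nn`` ring closure; the
        error carries the character offset.

    Examples
    --------
    >>> tokenize_smiles("[C@@H](Br)Cl").tokens
    ('[C@@H]', '(', 'Br', ')', 'Cl')
    """
    return _scan(smiles, Notation.SMILES)


def tokenize_smarts(smarts: str) -> TokenSequence:
    """Tokenize a SMARTS pattern.

    Uses the SMILES grammar; SMARTS logical operators (``&``, ``;``,
    ``,``, ``!``) and recursive-SMARTS ``$`` / ``(`` characters fall
    through as single-character tokens, and bracket expressions such as
    ``[C,N]`` remain atomic.
    """
    return _scan(smarts, Notation.SMARTS)


def tokenize_inchikey(inchikey: str) -> TokenSequence:
    """Tokenize an InChIKey character-wise, hyphens included."""
    if not inchikey:
        raise EmptyInputError("empty InChIKey string")
    return TokenSequence(Notation.INCHIKEY, inchikey, tuple(inchikey))


_DISPATCH = {
    Notation.SMILES: tokenize_smiles,
    Notation.SMARTS: tokenize_smarts,
    Notation.INCHIKEY: tokenize_inchikey,
}


def tokenize(text: str, notation: Notation | str) -> TokenSequence:
    """Tokenize ``text`` under the grammar of ``notation``."""
    notation = Notation(notation.upper() if isinstance(notation, str) else notation)
    try:
        fn = _DISPATCH[notation]
    except KeyError:
        raise ValueError(f"no tokenizer for notation {notation}") from None
    return fn(text)
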