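"""Synthetic molecule fixtures with known compositions.

Fixtures are assembled by concatenating valid SMILES fragments from a
valence-safe pool (alkyl chains, rings, heteroatom groups, terminal
halogens), so every emitted string is chemically parseable by
construction; any assembly the parser still rejects is resampled and
counted.  Each fragment's token list, atom composition and bond-type
composition are declared by hand in the pool table, so every fixture
carries exact ground truth for the tokenizer and entropy code to be
tested against: concatenation joins consecutive fragments with one
single bond, so truths are additive plus (n_fragments - 1) SINGLE
bonds.

Targets follow a declared rule — linear in the SMILES Shannon entropy,
linear in molecular weight, or a binary threshold on entropy — with
Gaussian noise of chosen sigma, exactly reproducible under a seed.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors
from rdkit.rdBase import BlockLogs

import pandas as pd

from .entropy import FrequencyTable, shannon_entropy
from .featurize import MoleculeRecord
from .tokenize import Notation

__all__ = ["Fragment", "FixtureSpec", "FixtureSet", "generate_fixtures",
           "write_fixtures", "DEFAULT_POOL", "TERMINAL_POOL"]


@dataclass(frozen=True)
class Fragment:
    """A SMILES fragment with hand-declared composition ground truth."""

    smiles: str
    tokens: tuple[str, ...]
    atoms: tuple[tuple[str, int], ...]  # (element, count)
    bonds: tuple[tuple[str, int], ...]  # (bond type, count)


def _frag(smiles, tokens, atoms, bonds=()):
    return Fragment(smiles, tuple(tokens), tuple(atoms), tuple(bonds))


#: Fragments safe at both ends of a chain (an open valence each side).
DEFAULT_POOL: tuple[Fragment, ...] = (
    _frag("C", "C", [("C", 1)]),
    _frag("CC", "CC", [("C", 2)], [("SINGLE", 1)]),
    _frag("CCC", "CCC", [("C", 3)], [("SINGLE", 2)]),
    _frag("C(C)C", ["C", "(", "C", ")", "C"], [("C", 3)], [("SINGLE", 2)]),
    _frag("CO", "CO", [("C", 1), ("O", 1)], [("SINGLE", 1)]),
    _frag("CN", "CN", [("C", 1), ("N", 1)], [("SINGLE", 1)]),
    _frag("CS", "CS", [("C", 1), ("S", 1)], [("SINGLE", 1)]),
    _frag("C(=O)", ["C", "(", "=", "O", ")"], [("C", 1), ("O", 1)],
          [("DOUBLE", 1)]),
    _frag("C=C", ["C", "=", "C"], [("C", 2)], [("DOUBLE", 1)]),
    _frag("C#C", ["C", "#", "C"], [("C", 2)], [("TRIPLE", 1)]),
    _frag("c1ccccc1", ["c", "1", "c", "c", "c", "c", "c", "1"],
          [("C", 6)], [("AROMATIC", 6)]),
    _frag("C1CCCCC1", ["C", "1", "C", "C", "C", "C", "C", "1"],
          [("C", 6)], [("SINGLE", 6)]),
)

#: Fragments only valid at the end of a chain (monovalent groups).
TERMINAL_POOL: tuple[Fragment, ...] = (
    _frag("F", "F", [("F", 1)]),
    _frag("Cl", ["Cl"], [("Cl", 1)]),
    _frag("Br", ["Br"], [("Br", 1)]),
    _frag("C#N", ["C", "#", "N"], [("C", 1), ("N", 1)], [("TRIPLE", 1)]),
    _frag("C(=O)O", ["C", "(", "=", "O", ")", "O"], [("C", 1), ("O", 2)],
          [("DOUBLE", 1), ("SINGLE", 1)]),
    _frag("C(F)(F)F", ["C", "(", "F", ")", "(", "F", ")", "F"],
          [("C", 1), ("F", 3)], [("SINGLE", 3)]),
)


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a deterministic synthetic fixture set."""

    n_molecules: int = 200
    fragment_pool: tuple[Fragment, ...] = DEFAULT_POOL
    terminal_pool: tuple[Fragment, ...] = TERMINAL_POOL
    min_fragments: int = 2
    max_fragments: int = 6
    target_rule: str = "linear_in_entropy"
    slope: float = 2.0
    intercept: float = 0.0
    noise_sigma: float = 0.01
    seed: int = 0
    max_resamples: int = 10_000

    def __post_init__(self) -> None:
        if not self.fragment_pool:
            raise ValueError("fragment pool must be non-empty")
        if self.target_rule not in (
            "linear_in_entropy",
            "linear_in_mw",
            "binary_threshold",
        ):
            raise ValueError(f"unknown target rule {self.target_rule!r}")


@dataclass
class FixtureSet:
    """Generated records plus their exact composition ground truth."""

    records: list[MoleculeRecord]
    truth: pd.DataFrame
    resamples: int = 0
    spec: FixtureSpec | None = None

    def __iter__(self):
        return iter((self.records, self.truth))


def _assemble(rng: np.random.Generator, spec: FixtureSpec):
    """Draw one molecule; returns (smiles, tokens, atoms, bonds)."""
    n_frag = int(rng.integers(spec.min_fragments, spec.max_fragments + 1))
    frags = [
        spec.fragment_pool[rng.integers(len(spec.fragment_pool))]
        for _ in range(n_frag - 1)
    ]
    tail_pool = spec.fragment_pool + spec.terminal_pool
    frags.append(tail_pool[rng.integers(len(tail_pool))])
    smiles = "".join(f.smiles for f in frags)
    tokens: list[str] = []
    atoms: Counter = Counter()
    bonds: Counter = Counter()
    for f in frags:
        tokens.extend(f.tokens)
        atoms.update(dict(f.atoms))
        bonds.update(dict(f.bonds))
    bonds["SINGLE"] += n_frag - 1  # the joins
    return smiles, tuple(tokens), dict(atoms), dict(bonds)


def generate_fixtures(spec: FixtureSpec | None = None) -> FixtureSet:
    """Generate a deterministic fixture set under ``spec.seed``.

    Each record's truth row carries the exact token multiset, atom
    counts, bond-type counts, SMILES Shannon entropy, molecular weight
    and the generated target.  Assemblies the parser rejects are
    resampled (counted in ``resamples``).
    """
    spec = spec or FixtureSpec()
    rng = np.random.default_rng(spec.seed)
    rows = []
    records = []
    resamples = 0
    while len(records) < spec.n_molecules:
        smiles, tokens, atoms, bonds = _assemble(rng, spec)
        with BlockLogs():
            mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            resamples += 1
            if resamples > spec.max_resamples:
                raise RuntimeError("fragment assembly keeps failing to parse")
            continue
        i = len(records)
        s_m = shannon_entropy(
            FrequencyTable.from_items(tokens), Notation.SMILES
        ).value
        mw = Descriptors.MolWt(mol)
        noise = float(rng.normal(0.0, spec.noise_sigma)) if spec.noise_sigma else 0.0
        if spec.target_rule == "linear_in_entropy":
            target = spec.slope * s_m + spec.intercept + noise
        elif spec.target_rule == "linear_in_mw":
            target = spec.slope * mw + spec.intercept + noise
        else:  # binary_threshold, resolved after the loop against the median
            target = s_m + noise
        records.append(
            MoleculeRecord(id=f"syn{i:04d}", smiles=smiles, target=target,
                           target_name=spec.target_rule)
        )
        rows.append(
            {
                "id": f"syn{i:04d}",
                "smiles": smiles,
                "token_counts": dict(Counter(tokens)),
                "atom_counts": atoms,
                "bond_counts": bonds,
                "shannon_smiles": s_m,
                "mw": mw,
                "target": target,
            }
        )
    truth = pd.DataFrame(rows)
    if spec.target_rule == "binary_threshold":
        cut = float(truth["target"].median())
        labels = (truth["target"].to_numpy() > cut).astype(float)
        truth["target"] = labels
        for rec, lab in zip(records, labels):
            rec.target = float(lab)
    return FixtureSet(records=records, truth=truth, resamples=resamples, spec=spec)


def write_fixtures(fixtures: FixtureSet, smi_path, truth_path) -> None:
    """Write fixtures as a .smi file plus a CSV truth table."""
    with open(smi_path, "w") as fh:
        for rec in fixtures.records:
            fh.write(f"{rec.smiles} {rec.id}\n")
    truth = fixtures.truth.copy()
    for col in ("token_counts", "atom_counts", "bond_counts"):
        truth[col] = truth[col].map(json.dumps)
    truth.to_csv(truth_path, index=False)
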