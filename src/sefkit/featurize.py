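"""Descriptor-matrix assembly for the Shannon entropy framework (SEF).

Reads molecule tables (CSV / .smi / SDF), assembles configurable
descriptor matrices — molecular weight, string-notation Shannon
entropies, the fixed-width fractional-entropy block, the bond-frequency
block, bond entropy and optional Morgan fingerprint comparator bits —
and exports per-atom node/edge tables for graph models.

The core object is :class:`ShannonFeaturizer`, a scikit-learn
transformer: ``fit`` learns the padded width of the fractional-entropy
block from the training batch (unless fixed by ``n_max``) and freezes
the column layout; ``transform`` maps SMILES strings to numeric rows.
Columns are emitted in a fixed, documented order: scalars (mw,
shannon_smiles, shannon_smarts, shannon_inchikey), then the
fractional-entropy block, then the bond block (7 frequencies +
shannon_bonds), then fingerprint bits.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors, rdFingerprintGenerator
from rdkit.Chem.inchi import MolToInchiKey
from rdkit.rdBase import BlockLogs
from sklearn.base import BaseEstimator, TransformerMixin

from . import entropy as ent
from .errors import EmptyMatrixError, ParseError, SefError
from .tokenize import Notation

logger = logging.getLogger(__name__)

__all__ = [
    "MoleculeRecord",
    "FeatureSetConfig",
    "DescriptorMatrix",
    "ShannonFeaturizer",
    "read_molecules",
    "derive_inchikey",
    "featurize_dataset",
    "atom_node_features",
    "write_matrix",
    "read_matrix",
]


@dataclass
class MoleculeRecord:
    """One molecule of a dataset: identifier, structure and target."""

    id: str
    smiles: str
    inchikey: str | None = None
    target: float | None = None
    target_name: str = ""
    is_valid: bool = True
    invalid_reason: str | None = None


@dataclass(frozen=True)
class FeatureSetConfig:
    """Which SEF feature families a descriptor matrix contains.

    frac_shannon selects the notation whose total entropy is
    apportioned per atom ("smiles", "smarts" or "inchikey"), or None to
    omit the block.  n_max fixes the padded width of that block; if
    None it is learned from the batch (max atom count).
    """

    mw: bool = True
    shannon_smiles: bool = True
    shannon_smarts: bool = False
    shannon_inchikey: bool = False
    frac_shannon: str | None = "smiles"
    bond_freq: bool = False
    shannon_bonds: bool = False
    morgan: bool = False
    morgan_radius: int = 2
    morgan_bits: int = 2048
    n_max: int | None = None
    hydrogen_mode: str = "explicit"
    canonicalize: bool = False

    def __post_init__(self) -> None:
        if not any(
            (
                self.mw,
                self.shannon_smiles,
                self.shannon_smarts,
                self.shannon_inchikey,
                self.frac_shannon,
                self.bond_freq,
                self.shannon_bonds,
                self.morgan,
            )
        ):
            raise ValueError("at least one feature family must be enabled")
        if self.frac_shannon is not None and self.frac_shannon.lower() not in (
            "smiles",
            "smarts",
            "inchikey",
        ):
            raise ValueError(f"unknown frac_shannon source {self.frac_shannon!r}")


@dataclass
class DescriptorMatrix:
    """One numeric row per valid molecule, with named columns."""

    ids: tuple[str, ...]
    feature_names: tuple[str, ...]
    values: np.ndarray
    provenance: dict = field(default_factory=dict)
    invalid: tuple[tuple[str, str], ...] = ()
    targets: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.ids), len(self.feature_names)):
            raise ValueError("matrix shape does not match ids/feature_names")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.feature_names))
        df.insert(0, "id", list(self.ids))
        if self.targets is not None:
            df["target"] = self.targets
        return df


def read_molecules(
    path: str | Path,
    format: str | None = None,
    smiles_col: str = "smiles",
    id_col: str | None = None,
    target_col: str | None = None,
    inchikey_col: str | None = None,
    target_name: str = "",
) -> list[MoleculeRecord]:
    """Read molecule records from CSV, .smi or SDF.

    Unparseable structures are retained with ``is_valid=False`` rather
    than dropped; a (n read, n valid) summary is logged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "csv":
        df = pd.read_csv(path)
        if df.empty:
            raise EmptyMatrixError(f"no rows in {path}")
        if smiles_col not in df.columns:
            raise KeyError(f"column {smiles_col!r} not found in {path}")
        records = []
        for i, row in df.iterrows():
            rec = MoleculeRecord(
                id=str(row[id_col]) if id_col else str(i),
                smiles=str(row[smiles_col]),
                inchikey=str(row[inchikey_col]) if inchikey_col else None,
                target=float(row[target_col]) if target_col else None,
                target_name=target_name or (target_col or ""),
            )
            records.append(rec)
    elif fmt == "smi":
        records = []
        lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
        if not lines:
            raise EmptyMatrixError(f"no molecules in {path}")
        for i, line in enumerate(lines):
            parts = line.split()
            records.append(
                MoleculeRecord(
                    id=parts[1] if len(parts) > 1 else str(i), smiles=parts[0]
                )
            )
    elif fmt == "sdf":
        records = []
        with BlockLogs():
            supplier = Chem.SDMolSupplier(str(path))
            for i, mol in enumerate(supplier):
                if mol is None:
                    records.append(
                        MoleculeRecord(
                            id=str(i),
                            smiles="",
                            is_valid=False,
                            invalid_reason="unparseable SDF block",
                        )
                    )
                    continue
                props = mol.GetPropsAsDict()
                records.append(
                    MoleculeRecord(
                        id=mol.GetProp("_Name") if mol.HasProp("_Name") else str(i),
                        smiles=Chem.MolToSmiles(mol),
                        target=float(props[target_col])
                        if target_col and target_col in props
                        else None,
                        target_name=target_name or (target_col or ""),
                    )
                )
        if not records:
            raise EmptyMatrixError(f"no molecules in {path}")
    else:
        raise ValueError(f"unknown format {fmt!r}")

    for rec in records:
        if not rec.is_valid:
            continue
        try:
            ent.mol_from_smiles(rec.smiles)
        except SefError as exc:
            rec.is_valid = False
            rec.invalid_reason = str(exc)
    n_valid = sum(r.is_valid for r in records)
    logger.info("read %d records from %s (%d valid)", len(records), path, n_valid)
    return records


def derive_inchikey(record: MoleculeRecord | str) -> str:
    """Standard 27-character InChIKey (14-10-1, hyphenated) of a structure."""
    smiles = record.smiles if isinstance(record, MoleculeRecord) else record
    mol = ent.mol_from_smiles(smiles)
    with BlockLogs():
        key = MolToInchiKey(mol)
    if not key:
        raise ParseError(smiles, "InChIKey generation failed")
    return key


class ShannonFeaturizer(TransformerMixin, BaseEstimator):
    """Scikit-learn transformer mapping SMILES strings to SEF descriptors.

    Parameters mirror :class:`FeatureSetConfig`; see that class for the
    meaning of each flag.  ``fit`` learns ``n_max_`` (the padded width
    of the fractional-entropy block) as the maximum atom count of the
    batch unless ``n_max`` is given, so train/test batches can share one
    width by fitting once.

    Attributes
    ----------
    n_max_ : int or None
        Padded width in use after ``fit``.
    feature_names_ : tuple of str
        Column labels, in the fixed emission order.
    """

    def __init__(
        self,
        mw: bool = True,
        shannon_smiles: bool = True,
        shannon_smarts: bool = False,
        shannon_inchikey: bool = False,
        frac_shannon: str | None = "smiles",
        bond_freq: bool = False,
        shannon_bonds: bool = False,
        morgan: bool = False,
        morgan_radius: int = 2,
        morgan_bits: int = 2048,
        n_max: int | None = None,
        hydrogen_mode: str = "explicit",
        canonicalize: bool = False,
    ):
        self.mw = mw
        self.shannon_smiles = shannon_smiles
        self.shannon_smarts = shannon_smarts
        self.shannon_inchikey = shannon_inchikey
        self.frac_shannon = frac_shannon
        self.bond_freq = bond_freq
        self.shannon_bonds = shannon_bonds
        self.morgan = morgan
        self.morgan_radius = morgan_radius
        self.morgan_bits = morgan_bits
        self.n_max = n_max
        self.hydrogen_mode = hydrogen_mode
        self.canonicalize = canonicalize

    # ------------------------------------------------------------------
    def _config(self) -> FeatureSetConfig:
        return FeatureSetConfig(
            **{
                f.name: getattr(self, f.name)
                for f in dataclasses.fields(FeatureSetConfig)
            }
        )

    @staticmethod
    def _smiles_of(x) -> str:
        return x.smiles if isinstance(x, MoleculeRecord) else str(x)

    def fit(self, X: Sequence, y=None) -> "ShannonFeaturizer":
        cfg = self._config()  # validates flags
        smiles = [self._smiles_of(x) for x in X]
        if not smiles:
            raise EmptyMatrixError("cannot fit on an empty batch")
        if cfg.frac_shannon is not None:
            if cfg.n_max is not None:
                self.n_max_ = cfg.n_max
            else:
                self.n_max_ = max(
                    len(ent.atom_species(s, cfg.hydrogen_mode)) for s in smiles
                )
        else:
            self.n_max_ = None
        self.feature_names_ = tuple(self._make_names(cfg))
        return self

    def _make_names(self, cfg: FeatureSetConfig) -> Iterable[str]:
        if cfg.mw:
            yield "mw"
        if cfg.shannon_smiles:
            yield "shannon_smiles"
        if cfg.shannon_smarts:
            yield "shannon_smarts"
        if cfg.shannon_inchikey:
            yield "shannon_inchikey"
        if cfg.frac_shannon is not None:
            src = cfg.frac_shannon.lower()
            for i in range(self.n_max_):
                yield f"frac_{src}_{i}"
        if cfg.bond_freq:
            for t in ent.BOND_TYPES:
                yield f"bond_freq_{t.lower()}"
        if cfg.shannon_bonds:
            yield "shannon_bonds"
        if cfg.morgan:
            for i in range(cfg.morgan_bits):
                yield f"morgan_{i}"

    def transform(self, X: Sequence) -> np.ndarray:
        if not hasattr(self, "feature_names_"):
            raise RuntimeError("ShannonFeaturizer must be fit before transform")
        cfg = self._config()
        rows = [self._row(self._smiles_of(x), cfg, x) for x in X]
        return np.asarray(rows, dtype=float)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.feature_names_, dtype=object)

    # ------------------------------------------------------------------
    def _row(self, smiles: str, cfg: FeatureSetConfig, x=None) -> list[float]:
        mol = ent.mol_from_smiles(smiles, cfg.hydrogen_mode)
        if cfg.canonicalize:
            smiles = Chem.MolToSmiles(Chem.RemoveHs(mol))
        row: list[float] = []
        entropies: dict[str, float] = {}

        def smiles_S() -> float:
            if "smiles" not in entropies:
                entropies["smiles"] = ent.string_entropy(smiles, Notation.SMILES).value
            return entropies["smiles"]

        def smarts_S() -> float:
            if "smarts" not in entropies:
                smarts = Chem.MolToSmarts(mol)
                entropies["smarts"] = ent.string_entropy(smarts, Notation.SMARTS).value
            return entropies["smarts"]

        def inchikey_S() -> float:
            if "inchikey" not in entropies:
                key = None
                if isinstance(x, MoleculeRecord) and x.inchikey:
                    key = x.inchikey
                else:
                    key = derive_inchikey(smiles)
                entropies["inchikey"] = ent.string_entropy(
                    key, Notation.INCHIKEY
                ).value
            return entropies["inchikey"]

        if cfg.mw:
            row.append(Descriptors.MolWt(mol))
        if cfg.shannon_smiles:
            row.append(smiles_S())
        if cfg.shannon_smarts:
            row.append(smarts_S())
        if cfg.shannon_inchikey:
            row.append(inchikey_S())
        if cfg.frac_shannon is not None:
            src = cfg.frac_shannon.lower()
            total = {"smiles": smiles_S, "smarts": smarts_S, "inchikey": inchikey_S}[
                src
            ]()
            profile = ent.fractional_entropy(
                smiles,
                ent.EntropyValue(total, Notation(src.upper())),
                cfg.hydrogen_mode,
            )
            profile = ent.pad_profile(profile, self.n_max_)
            row.extend(profile.padded)
        if cfg.bond_freq or cfg.shannon_bonds:
            bp = ent.bond_profile(smiles)
            if cfg.bond_freq:
                row.extend(bp.frequencies)
            if cfg.shannon_bonds:
                row.append(bp.entropy_bits)
        if cfg.morgan:
            gen = rdFingerprintGenerator.GetMorganGenerator(
                radius=cfg.morgan_radius, fpSize=cfg.morgan_bits
            )
            row.extend(gen.GetFingerprintAsNumPy(Chem.RemoveHs(mol)).tolist())
        return row


def featurize_dataset(
    records: Sequence[MoleculeRecord], config: FeatureSetConfig | None = None
) -> DescriptorMatrix:
    """Assemble the SEF descriptor matrix for a batch of records.

    Invalid records are excluded from the rows but listed in the
    matrix's provenance; identical config + identical input produce
    bit-identical output.
    """
    config = config or FeatureSetConfig()
    valid = [r for r in records if r.is_valid]
    invalid = tuple(
        (r.id, r.invalid_reason or "invalid") for r in records if not r.is_valid
    )
    if not valid:
        raise EmptyMatrixError("no valid records to featurize")
    fz = ShannonFeaturizer(**dataclasses.asdict(config))
    values = fz.fit(valid).transform(valid)
    targets = (
        np.asarray([r.target for r in valid], dtype=float)
        if all(r.target is not None for r in valid)
        else None
    )
    return DescriptorMatrix(
        ids=tuple(r.id for r in valid),
        feature_names=fz.feature_names_,
        values=values,
        provenance={
            "config": dataclasses.asdict(config),
            "n_max": fz.n_max_,
            "n_input": len(records),
            "n_valid": len(valid),
        },
        invalid=invalid,
        targets=targets,
    )


#: bond order used for aromatic bonds before normalization
_AROMATIC_ORDER = 1.5


def atom_node_features(
    record: MoleculeRecord | str, config: FeatureSetConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-atom node table and bond edge list for graph models.

    Nodes carry element symbol, atomic mass, the atom's fractional
    Shannon entropy and the molecule's total SMILES entropy replicated
    per node.  Edges carry 0-based atom indices, the bond type, and a
    normalized bond order (order / max order present; aromatic = 1.5
    before normalization).
    """
    config = config or FeatureSetConfig()
    smiles = record.smiles if isinstance(record, MoleculeRecord) else record
    mol = ent.mol_from_smiles(smiles, config.hydrogen_mode)
    total = ent.string_entropy(smiles, Notation.SMILES)
    profile = ent.fractional_entropy(smiles, total, config.hydrogen_mode)
    nodes = pd.DataFrame(
        {
            "atom_index": range(mol.GetNumAtoms()),
            "element": list(profile.atom_species),
            "atomic_mass": [a.GetMass() for a in mol.GetAtoms()],
            "fractional_entropy": list(profile.per_atom),
            "shannon_smiles": total.value,
        }
    )
    orders = []
    for bond in mol.GetBonds():
        order = (
            _AROMATIC_ORDER
            if bond.GetBondType().name == "AROMATIC"
            else bond.GetBondTypeAsDouble()
        )
        orders.append((bond.GetBeginAtomIdx(), bond.GetEndAtomIdx(),
                       bond.GetBondType().name, order))
    max_order = max((o for *_, o in orders), default=1.0)
    edges = pd.DataFrame(
        [
            {
                "begin": i,
                "end": j,
                "bond_type": t,
                "normalized_order": o / max_order,
            }
            for i, j, t, o in orders
        ],
        columns=["begin", "end", "bond_type", "normalized_order"],
    )
    return nodes, edges


def write_matrix(matrix: DescriptorMatrix, path: str | Path) -> Path:
    """Write a descriptor matrix as CSV (id column first); round-trips
    losslessly through :func:`read_matrix`."""
    if len(matrix.ids) == 0:
        raise EmptyMatrixError("refusing to write an empty matrix")
    path = Path(path)
    matrix.to_frame().to_csv(path, index=False)
    return path


def read_matrix(path: str | Path) -> DescriptorMatrix:
    """Read a descriptor matrix written by :func:`write_matrix`."""
    df = pd.read_csv(path)
    targets = None
    if "target" in df.columns:
        targets = df.pop("target").to_numpy(dtype=float)
    ids = tuple(str(i) for i in df.pop("id"))
    return DescriptorMatrix(
        ids=ids,
        feature_names=tuple(df.columns),
        values=df.to_numpy(dtype=float),
        targets=targets,
    )
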