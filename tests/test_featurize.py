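"""Molecule IO, descriptor-matrix assembly and node-feature export."""

import numpy as np
import pandas as pd
import pytest

from sefkit import (
    FeatureSetConfig,
    MoleculeRecord,
    ShannonFeaturizer,
    atom_node_features,
    derive_inchikey,
    featurize_dataset,
    read_matrix,
    read_molecules,
    string_entropy,
    write_matrix,
)
from sefkit.errors import EmptyMatrixError

ENTROPY_CCO = 0.9182958340544896


# ------------------------------------------------------------------ IO


def test_read_csv_records(tmp_path):
    p = tmp_path / "mols.csv"
    pd.DataFrame(
        {"name": ["m1", "m2"], "smiles": ["CCO", "not_a_smiles"], "y": [0.5, 1.0]}
    ).to_csv(p, index=False)
    recs = read_molecules(p, id_col="name", target_col="y")
    assert [r.id for r in recs] == ["m1", "m2"]
    assert recs[0].is_valid and recs[0].target == 0.5
    # invalid structures are flagged, not dropped
    assert not recs[1].is_valid and recs[1].invalid_reason


def test_read_smi_defaults_ids_to_line_numbers(tmp_path):
    p = tmp_path / "mols.smi"
    p.write_text("CCO\nc1ccccc1 benzene\nCC\n")
    recs = read_molecules(p)
    assert [r.id for r in recs] == ["0", "benzene", "2"]
    assert all(r.is_valid for r in recs)


def test_read_sdf(tmp_path):
    from rdkit import Chem

    p = tmp_path / "mols.sdf"
    w = Chem.SDWriter(str(p))
    for name, smi in [("a", "CCO"), ("b", "c1ccccc1")]:
        mol = Chem.MolFromSmiles(smi)
        mol.SetProp("_Name", name)
        w.write(mol)
    w.close()
    recs = read_molecules(p)
    assert [r.id for r in recs] == ["a", "b"] and all(r.is_valid for r in recs)


def test_missing_file_and_missing_column(tmp_path):
    with pytest.raises(FileNotFoundError):
        read_molecules(tmp_path / "nope.csv")
    p = tmp_path / "bad.csv"
    pd.DataFrame({"x": [1]}).to_csv(p, index=False)
    with pytest.raises(KeyError):
        read_molecules(p)


# ------------------------------------------------------------ InChIKey


def test_inchikey_format_and_canonical_identity():
    key = derive_inchikey("CCO")
    assert len(key) == 27 and key[14] == "-" and key[25] == "-"
    assert derive_inchikey("OCC") == key
    assert derive_inchikey("F/C=C/F") != derive_inchikey("F/C=C\\F")


# ----------------------------------------------------------- featurize


def test_single_feature_matrix():
    m = featurize_dataset(
        [MoleculeRecord("a", "C")],
        FeatureSetConfig(mw=False, frac_shannon=None, shannon_smiles=True),
    )
    assert m.feature_names == ("shannon_smiles",)
    assert m.values.tolist() == [[0.0]]


def test_shannon_plus_frac_block_worked_example():
    cfg = FeatureSetConfig(
        mw=False, shannon_smiles=True, frac_shannon="smiles", n_max=7
    )
    m = featurize_dataset([MoleculeRecord("a", "CCO")], cfg)
    s = ENTROPY_CCO
    expected = [s, 0, 0, 2 / 3 * s, 2 / 3 * s, 1 / 3 * s, 0, 0]
    assert m.values[0] == pytest.approx(expected, abs=1e-12)
    assert m.feature_names[0] == "shannon_smiles"
    assert m.feature_names[1] == "frac_smiles_0"


def test_bond_block():
    cfg = FeatureSetConfig(mw=False, shannon_smiles=False, frac_shannon=None,
                           bond_freq=True)
    m = featurize_dataset([MoleculeRecord("a", "C=CC")], cfg)
    assert m.values[0].tolist() == [0.5, 0.5, 0, 0, 0, 0, 0]


def test_config_requires_a_feature():
    with pytest.raises(ValueError):
        FeatureSetConfig(mw=False, shannon_smiles=False, frac_shannon=None)


def test_invalid_records_excluded_but_listed():
    recs = [
        MoleculeRecord("good", "CCO"),
        MoleculeRecord("bad", "xx", is_valid=False, invalid_reason="nope"),
    ]
    m = featurize_dataset(recs)
    assert m.ids == ("good",)
    assert m.invalid == (("bad", "nope"),)
    with pytest.raises(EmptyMatrixError):
        featurize_dataset([recs[1]])


def test_all_feature_families_column_order(small_fixtures):
    cfg = FeatureSetConfig(
        mw=True,
        shannon_smiles=True,
        shannon_smarts=True,
        shannon_inchikey=True,
        frac_shannon="smiles",
        bond_freq=True,
        shannon_bonds=True,
        morgan=True,
        morgan_bits=64,
    )
    m = featurize_dataset(small_fixtures.records, cfg)
    names = list(m.feature_names)
    scalars = ["mw", "shannon_smiles", "shannon_smarts", "shannon_inchikey"]
    assert names[:4] == scalars
    n_max = m.provenance["n_max"]
    assert names[4 : 4 + n_max] == [f"frac_smiles_{i}" for i in range(n_max)]
    bond_block = names[4 + n_max : 4 + n_max + 7]
    assert all(n.startswith("bond_freq_") for n in bond_block)
    assert names[4 + n_max + 7] == "shannon_bonds"
    assert names[-1] == "morgan_63"
    assert np.isfinite(m.values).all()


def test_featurizer_is_sklearn_compatible(small_fixtures):
    from sklearn.pipeline import make_pipeline
    from sklearn.ensemble import RandomForestRegressor

    smiles = [r.smiles for r in small_fixtures.records]
    y = [r.target for r in small_fixtures.records]
    fz = ShannonFeaturizer(frac_shannon="smiles")
    assert fz.get_params()["frac_shannon"] == "smiles"
    pipe = make_pipeline(
        ShannonFeaturizer(frac_shannon=None),
        RandomForestRegressor(n_estimators=5, random_state=0),
    )
    pipe.fit(smiles, y)
    assert len(pipe.predict(smiles)) == len(smiles)


def test_train_fitted_n_max_applies_to_test():
    fz = ShannonFeaturizer(mw=False, shannon_smiles=False, frac_shannon="smiles")
    fz.fit(["CCCCCC"])  # 6 atoms
    assert fz.n_max_ == 6
    assert fz.transform(["CC"]).shape == (1, 6)


def test_determinism_bit_identical(small_fixtures):
    cfg = FeatureSetConfig(bond_freq=True, shannon_bonds=True)
    a = featurize_dataset(small_fixtures.records, cfg)
    b = featurize_dataset(small_fixtures.records, cfg)
    assert np.array_equal(a.values, b.values)
    assert a.feature_names == b.feature_names


def test_canonicalize_equalizes_equivalent_smiles():
    cfg = FeatureSetConfig(mw=False, frac_shannon=None, canonicalize=True)
    a = featurize_dataset([MoleculeRecord("a", "OCC")], cfg)
    b = featurize_dataset([MoleculeRecord("b", "CCO")], cfg)
    assert a.values.tolist() == b.values.tolist()


def test_entropy_mw_correlation_reported(regression_fixtures):
    """Redundancy of shannon_smiles with MW is computed, not thresholded."""
    m = featurize_dataset(
        regression_fixtures.records, FeatureSetConfig(frac_shannon=None)
    )
    mw = m.values[:, 0]
    s = m.values[:, 1]
    r = abs(np.corrcoef(mw, s)[0, 1])
    assert np.isfinite(r) and 0.0 <= r <= 1.0


def test_small_perturbation_ordinal_stability():
    """One added atom moves the entropy less than replacing half the atoms."""
    base = "CCCCCCCC"
    one_more = "CCCCCCCCC"
    half_replaced = "CCCCOOOO"
    s0 = string_entropy(base).value
    d_small = abs(string_entropy(one_more).value - s0)
    d_large = abs(string_entropy(half_replaced).value - s0)
    assert d_small < d_large


# --------------------------------------------------------- round trip


def test_matrix_round_trip(tmp_path, small_fixtures):
    m = featurize_dataset(small_fixtures.records)
    p = write_matrix(m, tmp_path / "desc.csv")
    back = read_matrix(p)
    assert back.feature_names == m.feature_names
    assert back.ids == m.ids
    assert np.allclose(back.values, m.values)
    assert np.allclose(back.targets, m.targets)
    header = p.read_text().splitlines()[0]
    assert header.startswith("id,")


# ------------------------------------------------------- node features


def test_node_features_single_atom():
    nodes, edges = atom_node_features("C")
    assert len(nodes) == 1 and len(edges) == 0
    assert nodes.atomic_mass[0] == pytest.approx(12.011, abs=0.01)
    assert nodes.fractional_entropy[0] == 0.0


def test_node_features_edges_and_bond_order():
    nodes, edges = atom_node_features("CCO")
    assert len(nodes) == 3 and len(edges) == 2
    assert edges.normalized_order.nunique() == 1  # both single bonds
    _, edges = atom_node_features("C=CC")
    weights = sorted(edges.normalized_order)
    assert weights == [0.5, 1.0]  # orders 1 and 2 over max order 2
    nodes, _ = atom_node_features("CCO")
    assert nodes.shannon_smiles.nunique() == 1  # replicated total entropy
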