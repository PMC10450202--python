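import json

import numpy as np
import pytest

from paedomains import (
    Architecture,
    DomainCall,
    PAEMatrix,
    ResidueRange,
    StructureModel,
    read_architecture,
    read_pae,
    read_structure_model,
    write_architecture,
    write_pae,
    write_structure_model,
)
from paedomains.model_io import EmptyInputError, FormatError, SchemaVersionError
from paedomains.rigidity import ContactCall
from paedomains.synthetic import default_spec, generate_model

MINIMAL_PDB = """\
ATOM      1  N   MET A   1       0.000   0.000   0.000  1.00 91.20           N
ATOM      2  CA  MET A   1       1.458   0.000   0.000  1.00 91.20           C
ATOM      3  CA  ALA A   2       3.800   1.200   0.000  1.00 40.00           C
ATOM      4  CA  GLY A   3       7.100   2.900   0.500  1.00 88.00           C
TER
END
"""


def test_plddt_read_from_ca_b_factor(tmp_path):
    path = tmp_path / "mini.pdb"
    path.write_text(MINIMAL_PDB)
    model = read_structure_model(path)
    assert model.plddt == pytest.approx([91.2, 40.0, 88.0])
    assert model.sequence == "MAG"
    assert list(model.residue_numbers) == [1, 2, 3]


def test_missing_chain_is_empty_input(tmp_path):
    path = tmp_path / "mini.pdb"
    path.write_text(MINIMAL_PDB)
    with pytest.raises(EmptyInputError):
        read_structure_model(path, chain="Z")


def test_unreadable_file_is_format_error(tmp_path):
    path = tmp_path / "junk.pdb"
    path.write_text("not a structure\n")
    with pytest.raises((FormatError, EmptyInputError)):
        read_structure_model(path)


def test_out_of_range_b_factor_clipped(tmp_path, caplog):
    path = tmp_path / "hot.pdb"
    path.write_text(
        "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00999.9           C\n"
        "ATOM      2  CA  ALA A   2       3.800   0.000   0.000  1.00 50.00           C\n"
        "ATOM      3  CA  ALA A   3       7.600   0.000   0.000  1.00 50.00           C\n"
        "END\n"
    )
    with caplog.at_level("WARNING"):
        model = read_structure_model(path)
    assert model.plddt[0] == 100.0
    assert any("clipped" in r.message for r in caplog.records)


def test_structure_model_round_trip(tmp_path):
    spec = default_spec(seed=3)
    model, _ = generate_model(spec)
    path = tmp_path / "synthetic.pdb"
    write_structure_model(model, path)
    back = read_structure_model(path)
    assert back.sequence == model.sequence
    assert list(back.residue_numbers) == list(model.residue_numbers)
    np.testing.assert_allclose(back.ca_coords, model.ca_coords, atol=1e-3)
    np.testing.assert_allclose(back.plddt, model.plddt, atol=1e-2)


def test_write_empty_model_rejected(tmp_path):
    model = StructureModel("x", "A", np.array([1]), "A", np.zeros((1, 3)), np.array([50.0]))
    model.residue_numbers = np.array([], dtype=int)
    model.sequence = ""
    model.ca_coords = np.zeros((0, 3))
    model.plddt = np.array([])
    with pytest.raises(ValueError):
        write_structure_model(model, tmp_path / "empty.pdb")


def test_nonfinite_coordinates_rejected(tmp_path):
    model = StructureModel(
        "x", "A", np.arange(1, 4), "AAA", np.zeros((3, 3)), np.full(3, 50.0)
    )
    model.ca_coords[1, 0] = np.nan
    with pytest.raises(ValueError):
        write_structure_model(model, tmp_path / "nan.pdb")


def test_plddt_100_serialises_exactly(tmp_path):
    model = StructureModel(
        "x", "A", np.arange(1, 4), "AAA",
        np.array([[0.0, 0, 0], [3.8, 0, 0], [7.6, 0, 0]]), np.array([100.0, 50.0, 0.0]),
    )
    path = tmp_path / "m.pdb"
    write_structure_model(model, path)
    assert "100.00" in path.read_text()
    assert read_structure_model(path).plddt[0] == 100.0


# ---------------------------------------------------------------------------
# PAE


def test_pae_asymmetry_preserved(tmp_path):
    path = tmp_path / "pae.json"
    path.write_text(json.dumps({"predicted_aligned_error": [[0, 5], [7, 0]]}))
    pae = read_pae(path)
    assert pae.values[0, 1] == 5.0
    assert pae.values[1, 0] == 7.0
    assert pae.max_value == 31.75  # AFDB default when absent


def test_non_square_pae_rejected(tmp_path):
    path = tmp_path / "bad.json"
    path.write_text(json.dumps({"predicted_aligned_error": [[0, 1], [1, 0], [2, 2]]}))
    with pytest.raises(FormatError):
        read_pae(path)


def test_negative_pae_rejected(tmp_path):
    path = tmp_path / "neg.json"
    path.write_text(json.dumps({"predicted_aligned_error": [[0, -1], [1, 0]]}))
    with pytest.raises(FormatError):
        read_pae(path)


def test_pae_round_trip_exact(tmp_path):
    rng = np.random.default_rng(0)
    values = rng.uniform(0, 30, size=(40, 40))
    np.fill_diagonal(values, 0.0)
    pae = PAEMatrix(values=values)
    path = tmp_path / "pae.json"
    write_pae(pae, path)
    back = read_pae(path)
    np.testing.assert_array_equal(back.values, pae.values)
    assert back.max_value == pae.max_value


def test_pae_invariant_diagonal():
    values = np.full((3, 3), 5.0)
    with pytest.raises(ValueError):
        PAEMatrix(values=values)  # diagonal must stay <= 1 A


# ---------------------------------------------------------------------------
# architectures


def _macro_art_architecture():
    """PARP15-style layout: two Macro domains and a C-terminal ART, no contacts."""
    return Architecture(
        entry_id="PAR15_HUMAN",
        length=444,
        domains=[
            DomainCall("D1", [ResidueRange(1, 190)], label="Macro"),
            DomainCall("D2", [ResidueRange(201, 380)], label="Macro"),
            DomainCall("D3", [ResidueRange(401, 444)], label="ART"),
        ],
        disordered=[ResidueRange(191, 200), ResidueRange(381, 400)],
    )


def test_architecture_round_trip(tmp_path):
    arch = _macro_art_architecture()
    path = tmp_path / "arch.json"
    write_architecture(arch, path)
    back = read_architecture(path)
    assert back.to_json() == arch.to_json()


def test_empty_architecture_round_trip(tmp_path):
    arch = Architecture(entry_id="none", length=0)
    path = tmp_path / "empty.json"
    write_architecture(arch, path)
    assert read_architecture(path).to_json() == arch.to_json()


def test_schema_version_mismatch(tmp_path):
    arch = _macro_art_architecture()
    path = tmp_path / "arch.json"
    write_architecture(arch, path)
    payload = json.loads(path.read_text())
    payload["schema_version"] = "99"
    path.write_text(json.dumps(payload))
    with pytest.raises(SchemaVersionError):
        read_architecture(path)


def test_random_architectures_round_trip_bit_identically(tmp_path):
    rng = np.random.default_rng(7)
    for k in range(100):
        n_dom = rng.integers(0, 5)
        pos, domains, disordered = 1, [], []
        for d in range(n_dom):
            gap = int(rng.integers(5, 40))
            disordered.append(ResidueRange(pos, pos + gap - 1))
            pos += gap
            length = int(rng.integers(30, 200))
            domains.append(
                DomainCall(f"D{d + 1}", [ResidueRange(pos, pos + length - 1)])
            )
            pos += length
        disordered.append(ResidueRange(pos, pos + int(rng.integers(5, 60))))
        contacts = []
        if n_dom >= 2:
            contacts = [ContactCall("D1", "D2", float(rng.uniform(2, 25)), bool(rng.integers(2)))]
        arch = Architecture(
            entry_id=f"r{k}", length=disordered[-1].end,
            domains=domains, disordered=disordered, contacts=contacts,
        )
        path = tmp_path / "r.json"
        write_architecture(arch, path)
        first = path.read_bytes()
        write_architecture(read_architecture(path), path)
        assert path.read_bytes() == first


def test_architecture_tiling_enforced():
    with pytest.raises(ValueError):
        Architecture(
            entry_id="gap", length=100,
            domains=[DomainCall("D1", [ResidueRange(1, 50)])],
            disordered=[ResidueRange(60, 100)],
        )
    with pytest.raises(ValueError):
        Architecture(
            entry_id="overlap", length=100,
            domains=[DomainCall("D1", [ResidueRange(1, 60)])],
            disordered=[ResidueRange(50, 100)],
        )
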