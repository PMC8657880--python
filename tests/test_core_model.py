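"""Backbone model types, validation, and PDB round-trips."""

import numpy as np
import pytest

from helixfuse.fixtures import make_bundle, make_trajectory
from helixfuse.geometry import ideal_helix
from helixfuse.model import BackboneModel, MembraneSlab, ReceptorScaffold, validate_model
from helixfuse.pdbio import read_backbone, read_trajectory, write_backbone, write_trajectory


class TestRoundTrip:
    def test_coordinates_preserved_to_format_precision(self, tmp_path, bundle):
        path = tmp_path / "m.pdb"
        write_backbone(bundle, path)
        back = read_backbone(path)
        assert len(back) == len(bundle)
        assert np.abs(back.coords - bundle.coords).max() < 1e-3

    def test_helix_records_round_trip(self, tmp_path, bundle):
        path = tmp_path / "m.pdb"
        write_backbone(bundle, path)
        assert read_backbone(path).helices == bundle.helices

    def test_two_reads_identical(self, tmp_path, bundle):
        path = tmp_path / "m.pdb"
        write_backbone(bundle, path)
        a, b = read_backbone(path), read_backbone(path)
        assert np.array_equal(a.coords, b.coords)
        assert a.sequence == b.sequence

    def test_trajectory_round_trip(self, tmp_path, bundle):
        traj = make_trajectory(bundle, noise_sd=0.1, n_frames=5, seed=3)
        path = tmp_path / "t.pdb"
        write_trajectory(traj, path)
        back = read_trajectory(path)
        assert len(back) == 5
        for orig, rt in zip(traj, back):
            assert np.abs(rt.coords - orig.coords).max() < 1e-3

    def test_multi_model_file_has_model_records(self, tmp_path):
        traj = make_trajectory(ideal_helix(4), noise_sd=0.0, n_frames=3, seed=0)
        path = tmp_path / "t.pdb"
        write_trajectory(traj, path)
        text = path.read_text()
        assert text.count("MODEL") >= 3 and "ENDMDL" in text


class TestReadErrors:
    def test_missing_mainchain_atom_names_residue(self, tmp_path):
        h = ideal_helix(3)
        path = tmp_path / "m.pdb"
        write_backbone(h, path)
        # drop the O atom of residue 2
        lines = [
            ln
            for ln in path.read_text().splitlines(keepends=True)
            if not (ln.startswith("ATOM") and ln[12:16].strip() == "O" and int(ln[22:26]) == 2)
        ]
        path.write_text("".join(lines))
        with pytest.raises(ValueError, match="missing atom O at residue 2"):
            read_backbone(path)

    def test_insertion_codes_rejected(self, tmp_path):
        h = ideal_helix(3)
        path = tmp_path / "m.pdb"
        write_backbone(h, path)
        out = []
        for ln in path.read_text().splitlines(keepends=True):
            if ln.startswith("ATOM") and int(ln[22:26]) == 2:
                ln = ln[:26] + "A" + ln[27:]
            out.append(ln)
        path.write_text("".join(out))
        with pytest.raises(ValueError, match="insertion code"):
            read_backbone(path)

    def test_missing_chain(self, tmp_path):
        write_backbone(ideal_helix(3), tmp_path / "m.pdb")
        with pytest.raises(ValueError, match="chain"):
            read_backbone(tmp_path / "m.pdb", chain="B")

    def test_mixed_length_trajectory_rejected(self, tmp_path):
        path = tmp_path / "t.pdb"
        a = write_snapshot_pair(path)
        with pytest.raises(ValueError, match="differs"):
            read_trajectory(path)


def write_snapshot_pair(path):
    """Hand-assemble a 2-model PDB whose snapshots differ in length."""
    import gemmi

    from helixfuse.pdbio import _gemmi_structure

    st1 = _gemmi_structure([ideal_helix(4)], "A")
    st2 = _gemmi_structure([ideal_helix(3)], "A")
    text = st1.make_pdb_string()
    body1 = "".join(l + "\n" for l in text.splitlines() if l.startswith(("ATOM", "TER")))
    body2 = "".join(
        l + "\n" for l in st2.make_pdb_string().splitlines() if l.startswith(("ATOM", "TER"))
    )
    path.write_text(f"MODEL     1\n{body1}ENDMDL\nMODEL     2\n{body2}ENDMDL\nEND\n")


class TestValidation:
    def test_ideal_helix_valid(self):
        assert validate_model(ideal_helix(10)) == []

    def test_stretched_bond_reported(self):
        h = ideal_helix(5)
        h.coords[2, 0] += np.array([2.0, 0.0, 0.0])  # move N of residue 3
        violations = validate_model(h)
        assert any("residue 3" in v and "N-CA" in v for v in violations)

    def test_overlapping_helix_annotations_reported(self):
        h = ideal_helix(10)
        h.helices = [(1, 6), (4, 10)]
        assert any("overlap" in v for v in validate_model(h))

    def test_helix_outside_model_reported(self):
        h = ideal_helix(10)
        h.helices = [(1, 12)]
        assert any("outside" in v for v in validate_model(h))


class TestTypes:
    def test_membrane_slab_orientation_enforced(self):
        with pytest.raises(ValueError):
            MembraneSlab(z_min=5.0, z_max=5.0)

    def test_receptor_windows_must_be_disjoint(self, bundle):
        with pytest.raises(ValueError, match="disjoint"):
            ReceptorScaffold(
                model=bundle,
                tm5_range=(10, 20),
                tm6_range=(18, 30),
                slab=MembraneSlab(0.0, 10.0),
            )

    def test_sequence_length_must_match(self):
        with pytest.raises(ValueError):
            BackboneModel(coords=np.zeros((3, 4, 3)), sequence="XX")

    def test_residue_view(self):
        h = ideal_helix(3)
        res = h.residues
        assert [r.index for r in res] == [1, 2, 3]
        assert np.allclose(res[1].coords["CA"], h.coords[1, 1])


def test_bundle_length_bookkeeping():
    b = make_bundle(n_helices=4, helix_len=11, loop_len=2, seed=7)
    assert len(b) == 4 * 11 + 3 * 2
    assert len(b.helices) == 4
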