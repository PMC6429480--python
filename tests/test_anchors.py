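"""Template registry, groove superposition, anchor transfer and filtering."""

import numpy as np
import pytest

from groovedock.anchors import (
    DEFAULT_TEMPLATE_CODES,
    AnchorSpec,
    TemplateConfigurationError,
    anchor_deviation,
    anchor_spec_from_peptide,
    default_template_registry,
    extract_anchor_spec,
    groove_superpose,
    passes_anchor_filter,
)
from groovedock.geometry import Transform, superpose


class TestDefaultRegistry:
    def test_curated_codes(self):
        assert DEFAULT_TEMPLATE_CODES == {8: "2VAA", 9: "1DUZ", 10: "1I4F", 11: "2NW3"}

    def test_source_ids_without_files(self, tmp_path):
        reg = default_template_registry(str(tmp_path))
        assert reg.source_id(9) == "1DUZ"
        assert reg.source_id(8) == "2VAA"
        assert reg.source_id(10) == "1I4F"
        assert reg.source_id(11) == "2NW3"

    def test_missing_file_error_names_code(self, tmp_path):
        reg = default_template_registry(str(tmp_path))
        with pytest.raises(TemplateConfigurationError, match="1DUZ"):
            reg[9]

    def test_unsupported_length_requires_custom_template(self, tmp_path):
        reg = default_template_registry(str(tmp_path))
        assert 12 not in reg
        with pytest.raises(TemplateConfigurationError, match="custom"):
            reg[12]


class TestManifest:
    def test_manifest_round_trip(self, template9, tmp_path):
        from groovedock.anchors import load_template_manifest
        from groovedock.structure import write_pdb

        pdb_path = tmp_path / "toy9.pdb"
        pdb_path.write_text(write_pdb(template9.structure))
        manifest = tmp_path / "templates.txt"
        manifest.write_text("# length  path  chain\n9  toy9.pdb  P\n")
        reg = load_template_manifest(str(manifest))
        entry = reg[9]
        assert entry.peptide_length == 9
        assert entry.peptide_chain_id == "P"
        assert len(entry.peptide_chain()) == 9

    def test_malformed_line_rejected(self, tmp_path):
        from groovedock.anchors import TemplateConfigurationError, \
            load_template_manifest

        manifest = tmp_path / "bad.txt"
        manifest.write_text("9 only-two-fields\n")
        with pytest.raises(TemplateConfigurationError):
            load_template_manifest(str(manifest))


class TestGrooveSuperpose:
    def test_self_is_identity(self, toy9, template9):
        t = groove_superpose(template9.structure, template9)
        assert np.allclose(t.rotation, np.eye(3), atol=1e-9)
        assert np.allclose(t.translation, 0.0, atol=1e-9)

    def test_recovers_rigid_rotation(self, toy9, template9):
        moved = template9.structure.copy()
        angle = np.radians(30.0)
        rot = np.array([[np.cos(angle), -np.sin(angle), 0],
                        [np.sin(angle), np.cos(angle), 0],
                        [0, 0, 1.0]])
        shift = np.array([3.0, -2.0, 5.0])
        for a in moved.atoms():
            a.pos = rot @ a.pos + shift
        from groovedock.anchors import TemplateEntry

        moved_entry = TemplateEntry(9, moved, "P", "MOVED")
        t = groove_superpose(toy9.receptor, moved_entry)
        # moving the moved template back must land on the original groove
        orig = template9.receptor_chain().coords("CA")[:180]
        back = t.apply(moved_entry.receptor_chain().coords("CA")[:180])
        assert np.allclose(back, orig, atol=1e-6)

    def test_noisy_template_matches_superpose_oracle(self, toy9, template9, rng):
        noisy = template9.structure.copy()
        for a in noisy.atoms():
            a.pos = a.pos + rng.normal(scale=0.3, size=3)
        from groovedock.anchors import TemplateEntry

        entry = TemplateEntry(9, noisy, "P", "NOISY")
        t = groove_superpose(toy9.receptor, entry)
        fixed = toy9.receptor.chains[0].coords("CA")[:180]
        mobile = entry.receptor_chain().coords("CA")[:180]
        oracle_t, oracle_rmsd = superpose(fixed, mobile)
        fitted = t.apply(mobile)
        assert np.sqrt(np.mean(np.sum((fitted - fixed) ** 2, axis=1))) == \
            pytest.approx(oracle_rmsd, abs=1e-9)


class TestExtractAnchorSpec:
    def test_identity_transform_equals_raw_coords(self, template9):
        spec = extract_anchor_spec(template9, Transform.identity(), 9)
        pep = template9.peptide_chain()
        for slot in (1, 2, 8, 9):
            for nm in ("N", "CA", "C", "O"):
                assert np.allclose(spec.positions[(slot, nm)],
                                   pep.residues[slot - 1].atom(nm).pos)

    def test_pure_translation_is_linear(self, template9):
        shift = np.array([5.0, 0.0, 0.0])
        t = Transform(np.eye(3), shift)
        spec0 = extract_anchor_spec(template9, Transform.identity(), 9)
        spec1 = extract_anchor_spec(template9, t, 9)
        for key in spec0.positions:
            assert np.allclose(spec1.positions[key], spec0.positions[key] + shift)

    def test_pointwise_matrix_oracle(self, toy9, template9):
        t = groove_superpose(toy9.receptor, template9)
        spec = extract_anchor_spec(template9, t, 9)
        pep = template9.peptide_chain()
        for (slot, nm), pos in spec.positions.items():
            raw = pep.residues[slot - 1].atom(nm).pos
            assert np.allclose(pos, t.rotation @ raw + t.translation, atol=1e-9)

    def test_commutes_with_rigid_motion(self, toy9, template9):
        t0 = groove_superpose(toy9.receptor, template9)
        spec0 = extract_anchor_spec(template9, t0, 9)
        angle = np.radians(15.0)
        rot = np.array([[1, 0, 0],
                        [0, np.cos(angle), -np.sin(angle)],
                        [0, np.sin(angle), np.cos(angle)]])
        shift = np.array([-1.0, 4.0, 2.0])
        moved = toy9.receptor.copy()
        for a in moved.atoms():
            a.pos = rot @ a.pos + shift
        t1 = groove_superpose(moved, template9)
        spec1 = extract_anchor_spec(template9, t1, 9)
        for key in spec0.positions:
            assert np.allclose(spec1.positions[key],
                               rot @ spec0.positions[key] + shift, atol=1e-6)

    def test_wrong_length_rejected(self, template9):
        with pytest.raises(ValueError):
            extract_anchor_spec(template9, Transform.identity(), 10)


class TestAnchorSpecInvariants:
    def test_requires_all_16_positions(self, template9):
        spec = extract_anchor_spec(template9, Transform.identity(), 9)
        partial = dict(spec.positions)
        partial.pop((1, "O"))
        with pytest.raises(ValueError):
            AnchorSpec(9, partial)

    def test_ca_ca_distance_window(self, template9):
        spec = extract_anchor_spec(template9, Transform.identity(), 9)
        bad = {k: v.copy() for k, v in spec.positions.items()}
        bad[(2, "CA")] = bad[(1, "CA")] + np.array([9.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="CA-CA"):
            AnchorSpec(9, bad)


class TestAnchorFilter:
    def test_exact_pose_zero_deviation(self, toy9):
        devs = anchor_deviation(toy9.peptide, toy9.spec)
        assert set(devs) == {1, 2, 8, 9}
        assert max(devs.values()) == pytest.approx(0.0, abs=1e-12)
        assert passes_anchor_filter(toy9.peptide, toy9.spec, 2.0)

    def test_3_4_5_displacement(self, toy9):
        moved = toy9.peptide.copy()
        ca = moved.chains[0].residues[-1].atom("CA")
        ca.pos = ca.pos + np.array([0.0, 3.0, 4.0])
        devs = anchor_deviation(moved, toy9.spec)
        assert devs[9] == pytest.approx(5.0)
        assert devs[1] == pytest.approx(0.0, abs=1e-12)
        assert not passes_anchor_filter(moved, toy9.spec, 2.0)

    def test_threshold_monotonicity(self, toy9, rng):
        moved = toy9.peptide.copy()
        for res in moved.chains[0].residues:
            for a in res.atoms:
                a.pos = a.pos + rng.normal(scale=0.8, size=3)
        previous = True
        for threshold in (8.0, 4.0, 2.0, 1.0, 0.5, 0.1):
            current = passes_anchor_filter(moved, toy9.spec, threshold)
            assert previous or not current  # once false, false for smaller
            previous = current

    def test_spec_from_peptide_round_trip(self, toy9):
        spec = anchor_spec_from_peptide(toy9.peptide)
        for key, pos in toy9.spec.positions.items():
            assert np.allclose(pos, spec.positions[key])
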