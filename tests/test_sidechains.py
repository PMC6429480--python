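"""Rotamer library, sidechain construction, threading and clash counting."""

import numpy as np
import pytest

from groovedock import geometry as geom
from groovedock.loop_closure import BackboneConformation
from groovedock.sidechains import (
    CHI_ATOMS,
    build_sidechains,
    clash_count,
    load_rotamer_library,
    place_residue_atoms,
    residue_template,
    structure_bond_graph,
    thread_receptor,
)
from groovedock.structure import Atom, Chain, Residue, Structure


def _extended_backbone(n):
    dih = np.full((n, 3), 180.0)
    dih[:, 0] = -120.0
    dih[:, 1] = 140.0
    bb = geom.build_backbone(dih)
    oxy = geom.place_carbonyl_oxygens(bb)
    measured = geom.measure_backbone_dihedrals(bb)
    tab = np.array([[np.nan if v is None else v for v in t] for t in measured])
    return bb, oxy, tab


def _conformation(sequence):
    bb, oxy, tab = _extended_backbone(len(sequence))
    return BackboneConformation(sequence, tab,
                                np.concatenate([bb, oxy[:, None, :]], axis=1))


class TestRotamerLibrary:
    def test_all_standard_types_covered(self):
        lib = load_rotamer_library()
        for res in CHI_ATOMS:
            entries = lib.for_residue(res)
            assert entries
            assert sum(w for _, w in entries) == pytest.approx(1.0)
            for chis, _ in entries:
                assert len(chis) == len(CHI_ATOMS[res])

    def test_gly_ala_pro_have_empty_tuple(self):
        lib = load_rotamer_library()
        for res in ("GLY", "ALA", "PRO"):
            assert lib.for_residue(res) == [((), 1.0)]


class TestBuildSidechains:
    def test_poly_gly_has_backbone_only(self):
        conf = _conformation("GGGGGGGG")
        out = build_sidechains(conf, "GGGGGGGG", Structure())
        for res in out.chains[0].residues:
            assert sorted(a.name for a in res.atoms) == ["C", "CA", "N", "O"]

    def test_poly_ala_cb_geometry(self):
        conf = _conformation("AAAAAAAA")
        out = build_sidechains(conf, "AAAAAAAA", Structure())
        for res in out.chains[0].residues:
            cbs = [a for a in res.atoms if a.name == "CB"]
            assert len(cbs) == 1
            d = np.linalg.norm(cbs[0].pos - res.atom("CA").pos)
            assert d == pytest.approx(1.53, abs=0.02)

    def test_backbone_atoms_bit_identical(self, toy9, toy9_sequence):
        conf = _conformation(toy9_sequence)
        out = build_sidechains(conf, toy9_sequence, toy9.receptor)
        for i, res in enumerate(out.chains[0].residues):
            for k, nm in enumerate(("N", "CA", "C", "O")):
                assert np.array_equal(res.atom(nm).pos, conf.coords[i, k])

    def test_deterministic(self, toy9, toy9_sequence):
        conf = _conformation(toy9_sequence)
        a = build_sidechains(conf, toy9_sequence, toy9.receptor)
        b = build_sidechains(conf, toy9_sequence, toy9.receptor)
        for ra, rb in zip(a.chains[0].residues, b.chains[0].residues):
            for x, y in zip(ra.atoms, rb.atoms):
                assert np.array_equal(x.pos, y.pos)

    def test_chis_match_selected_rotamer(self):
        bb, _, _ = _extended_backbone(3)
        lib = load_rotamer_library()
        for res_name in ("LEU", "GLU", "LYS", "SER", "TRP"):
            for chis, _ in lib.for_residue(res_name):
                placed = place_residue_atoms(res_name, bb[1], chis)
                placed.update({nm: bb[1][k] for k, nm in enumerate(("N", "CA", "C"))})
                for k, (a, b, c, d) in enumerate(CHI_ATOMS[res_name]):
                    measured = geom.dihedral_angle(placed[a], placed[b],
                                                   placed[c], placed[d])
                    assert abs(geom.wrap_angle(measured - chis[k])) < 1e-3

    def test_bond_lengths_near_ideal(self, toy9, toy9_sequence):
        conf = _conformation(toy9_sequence)
        out = build_sidechains(conf, toy9_sequence, toy9.receptor)
        adj = structure_bond_graph(out)
        atoms = [a for a in out.atoms()]
        names, coords, _, bonds = None, None, None, None
        # every template bond within a residue deviates < 0.05 A from ideal
        for chain in out.chains:
            for res in chain.residues:
                names, coords, _, bonds = residue_template(res.name)
                local = {a.name: a.pos for a in res.atoms}
                for i, j in bonds:
                    ni, nj = names[i], names[j]
                    if ni in local and nj in local and "O" not in (ni, nj):
                        ideal = np.linalg.norm(coords[i] - coords[j])
                        actual = np.linalg.norm(local[ni] - local[nj])
                        assert abs(actual - ideal) < 0.05

    def test_greedy_beats_uniform_assignments(self, toy9, toy9_sequence):
        conf = _conformation(toy9_sequence)
        # place the backbone in the groove frame of the planted peptide
        chain = toy9.peptide.chains[0]
        bb = np.array([[r.atom(nm).pos for nm in ("N", "CA", "C")]
                       for r in chain.residues])
        oxy = np.array([r.atom("O").pos for r in chain.residues])
        measured = geom.measure_backbone_dihedrals(bb)
        tab = np.array([[np.nan if v is None else v for v in t] for t in measured])
        conf = BackboneConformation(toy9_sequence, tab,
                                    np.concatenate([bb, oxy[:, None, :]], axis=1))
        greedy = build_sidechains(conf, toy9_sequence, toy9.receptor)
        greedy_clashes = clash_count(greedy, toy9.receptor, 0.6)
        lib = load_rotamer_library()
        max_rot = max(len(lib.for_residue(r.name)) for r in greedy.chains[0].residues)
        for k in range(max_rot):
            uniform = Structure(chains=[Chain(id="P")])
            for i, res in enumerate(greedy.chains[0].residues):
                new = Residue(name=res.name, seq_id=res.seq_id)
                for j, nm in enumerate(("N", "CA", "C", "O")):
                    new.atoms.append(Atom(nm, nm[0], conf.coords[i, j].copy(), i + 1))
                rotamers = lib.for_residue(res.name)
                chis = rotamers[min(k, len(rotamers) - 1)][0]
                for nm, pos in place_residue_atoms(res.name, bb[i], chis).items():
                    new.atoms.append(Atom(nm, nm[0], pos, i + 1))
                uniform.chains[0].residues.append(new)
            assert greedy_clashes <= clash_count(uniform, toy9.receptor, 0.6)


class TestThreadReceptor:
    def test_identity_sequence_untouched(self, toy9):
        from groovedock.structure import chain_sequence

        seq = chain_sequence(toy9.receptor.chains[0])
        out = thread_receptor(toy9.receptor, seq)
        for ro, rn in zip(toy9.receptor.chains[0].residues, out.chains[0].residues):
            assert ro.name == rn.name
            for ao, an in zip(ro.atoms, rn.atoms):
                assert np.array_equal(ao.pos, an.pos)

    def test_single_mutation_local(self, toy9):
        from groovedock.structure import chain_sequence

        seq = chain_sequence(toy9.receptor.chains[0])
        mutated = seq[:10] + "V" + seq[11:]
        out = thread_receptor(toy9.receptor, mutated)
        for i, (ro, rn) in enumerate(zip(toy9.receptor.chains[0].residues,
                                         out.chains[0].residues)):
            if i == 10:
                assert rn.name == "VAL"
                assert rn.atom("CG1") is not None
                for nm in ("N", "CA", "C", "O"):
                    assert np.array_equal(ro.atom(nm).pos, rn.atom(nm).pos)
            else:
                for ao, an in zip(ro.atoms, rn.atoms):
                    assert an.name == ao.name
                    assert np.array_equal(ao.pos, an.pos)

    def test_five_mutations_clash_free(self, toy9):
        from groovedock.structure import chain_sequence

        seq = list(chain_sequence(toy9.receptor.chains[0]))
        # surface positions with open space for the new sidechains
        for pos, aa in zip((5, 30, 55, 95, 145), "VLSTV"):
            seq[pos] = aa
        out = thread_receptor(toy9.receptor, "".join(seq))
        assert clash_count(out, Structure(), 0.6) == 0

    def test_indel_unsupported(self, toy9):
        with pytest.raises(ValueError, match="indel"):
            thread_receptor(toy9.receptor, "AAA")


def _single_atom_structure(element, pos, res_name="ALA", atom_name="CB"):
    res = Residue(name=res_name, seq_id=1,
                  atoms=[Atom(atom_name, element, np.array(pos, dtype=float), 1)])
    return Structure(chains=[Chain(id="X", residues=[res])])


class TestClashCount:
    def test_disjoint_structures(self):
        a = _single_atom_structure("C", [0, 0, 0])
        b = _single_atom_structure("C", [100, 0, 0])
        assert clash_count(a, b, 0.6) == 0

    def test_two_carbons_at_one_angstrom(self):
        a = _single_atom_structure("C", [0, 0, 0])
        b = _single_atom_structure("C", [1.0, 0, 0])
        assert clash_count(a, b, 0.6) == 1  # threshold 0.6 * 3.8 = 2.28 A

    def test_matches_brute_force(self, toy9):
        from groovedock.scoring import VDW_RADII_BY_ELEMENT
        from groovedock.sidechains import _close_pairs

        factor = 0.7
        fast = clash_count(toy9.peptide, toy9.receptor, factor)
        sub = list(toy9.peptide.atoms())
        env = list(toy9.receptor.atoms())
        expected = 0
        for a in sub:
            for b in env:
                thr = factor * (VDW_RADII_BY_ELEMENT[a.element]
                                + VDW_RADII_BY_ELEMENT[b.element])
                if np.linalg.norm(a.pos - b.pos) < thr:
                    expected += 1
        adj = structure_bond_graph(toy9.peptide)
        excluded = _close_pairs(adj, max_sep=3)
        for i in range(len(sub)):
            for j in range(i + 1, len(sub)):
                if (i, j) in excluded:
                    continue
                thr = factor * (VDW_RADII_BY_ELEMENT[sub[i].element]
                                + VDW_RADII_BY_ELEMENT[sub[j].element])
                if np.linalg.norm(sub[i].pos - sub[j].pos) < thr:
                    expected += 1
        assert fast == expected
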