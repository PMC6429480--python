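"""Atom typing, empirical pair terms and torsional minimization."""

import math

import numpy as np
import pytest

from groovedock.scoring import (
    ATOM_TYPES,
    EnergyBreakdown,
    MinimizeConfig,
    ScoringWeights,
    TypingError,
    minimize_pose,
    score_interaction,
    select_flexible_sidechains,
    type_atoms,
)
from groovedock.sidechains import residue_template
from groovedock.structure import Atom, Chain, Residue, Structure


def _structure_of_atoms(entries, res_name="ALA", chain_id="X"):
    """entries: list of (atom_name, element, xyz) within one residue."""
    res = Residue(name=res_name, seq_id=1,
                  atoms=[Atom(nm, el, np.array(p, dtype=float), 1)
                         for nm, el, p in entries])
    return Structure(chains=[Chain(id=chain_id, residues=[res])])


def _carbon_pair(r):
    a = _structure_of_atoms([("CB", "C", (0.0, 0, 0))])
    b = _structure_of_atoms([("CB", "C", (r, 0, 0))], chain_id="Y")
    return type_atoms(a), type_atoms(b)


class TestTyping:
    def test_lys_nz_is_donor(self, rng):
        s = _structure_of_atoms([("NZ", "N", (0, 0, 0))], res_name="LYS")
        t = type_atoms(s)
        assert t.donor[0]
        assert not t.acceptor[0]

    def test_leu_cd1_is_hydrophobic_carbon(self):
        s = _structure_of_atoms([("CD1", "C", (0, 0, 0))], res_name="LEU")
        t = type_atoms(s)
        assert t.hydrophobic[0]
        assert t.radii[0] == pytest.approx(1.9)

    def test_all_twenty_residues_fully_typed(self):
        from groovedock.sidechains import CHI_ATOMS

        chain = Chain(id="A")
        for i, res_name in enumerate(sorted(CHI_ATOMS), start=1):
            names, coords, elements, _ = residue_template(res_name)
            res = Residue(name=res_name, seq_id=i)
            for nm, el, p in zip(names, elements, coords):
                res.atoms.append(Atom(nm, el, p + np.array([10.0 * i, 0, 0]), i))
            chain.residues.append(res)
        s = Structure(chains=[chain])
        typed = type_atoms(s)  # raises on any unmapped atom
        assert len(typed) == s.n_atoms()
        assert np.all(typed.radii >= 1.0) and np.all(typed.radii <= 2.5)

    def test_unmapped_atom_raises_with_name(self):
        s = _structure_of_atoms([("XX9", "C", (0, 0, 0))])
        with pytest.raises(TypingError, match="XX9"):
            type_atoms(s)


class TestPairTerms:
    def test_surface_contact_boundary(self):
        # two aliphatic carbons at r = 3.8 -> d = 0
        pep, rec = _carbon_pair(3.8)
        e = score_interaction(pep, rec, ScoringWeights())
        assert e.gauss1 == pytest.approx(1.0, abs=1e-12)
        assert e.repulsion == pytest.approx(0.0, abs=1e-12)
        assert e.hydrophobic == pytest.approx(1.0, abs=1e-12)
        assert e.n_pairs == 1

    def test_overlap_repulsion_quarter(self):
        pep, rec = _carbon_pair(3.3)  # d = -0.5
        e = score_interaction(pep, rec, ScoringWeights())
        assert e.repulsion == pytest.approx(0.25, abs=1e-12)

    def test_closed_forms_against_direct_evaluation(self):
        # 3-atom vs 2-atom toy spanning attraction, clash and cutoff edges
        pep = _structure_of_atoms([
            ("CB", "C", (0.0, 0.0, 0.0)),
            ("OG", "O", (0.0, 3.0, 0.0)),
            ("CA", "C", (1.5, 0.0, 0.0)),
        ], res_name="SER")
        rec = _structure_of_atoms([
            ("NZ", "N", (2.8, 0.0, 0.0)),
            ("CB", "C", (0.0, 0.0, 7.9)),
        ], res_name="LYS", chain_id="Y")
        w = ScoringWeights(w_electrostatic=1.0)
        e = score_interaction(type_atoms(pep), type_atoms(rec), w)
        expected = np.zeros(6)
        radius = {"C": 1.9, "O": 1.7, "N": 1.8}
        hydro = {"CB": True, "CA": True, "OG": False, "NZ": False}
        donor = {"NZ": True, "OG": True}
        acceptor = {"OG": True}
        charge = {"NZ": 0.25, "OG": -0.15, "CB": 0.0, "CA": 0.0}
        pep_atoms = [("CB", (0, 0, 0)), ("OG", (0, 3, 0)), ("CA", (1.5, 0, 0))]
        rec_atoms = [("NZ", (2.8, 0, 0)), ("CB", (0, 0, 7.9))]
        for pn, pp in pep_atoms:
            for rn, rp in rec_atoms:
                r = math.dist(pp, rp)
                if r > w.cutoff:
                    continue
                d = r - (radius[pn[0]] + radius[rn[0]])
                expected[0] += math.exp(-((d / 0.5) ** 2))
                expected[1] += math.exp(-(((d - 3.0) / 2.0) ** 2))
                expected[2] += d * d if d < 0 else 0.0
                if hydro[pn] and hydro[rn]:
                    expected[3] += min(1.0, max(0.0, 1.5 - d))
                is_hb = (donor.get(pn) and acceptor.get(rn)) or \
                        (acceptor.get(pn) and donor.get(rn))
                if is_hb:
                    expected[4] += min(1.0, max(0.0, -d / 0.7))
                expected[5] += charge[pn] * charge[rn] / max(r, 2.0) ** 2
        # intra-peptide pairs are all < 4 bonds apart here except unbonded
        # CA-OG (3 bonds via CB) -> excluded; no intra contribution expected
        assert np.allclose(e.terms(), expected, atol=1e-9)
        assert e.total == pytest.approx(float(w.vector() @ expected), abs=1e-9)

    def test_repulsion_smooth_at_contact(self):
        # value and first derivative vanish at d = 0
        eps = 1e-7
        lo, _ = _carbon_pair(3.8 - eps)
        hi, _ = _carbon_pair(3.8 + eps)
        w = ScoringWeights()
        e_lo = score_interaction(*_carbon_pair(3.8 - eps), w)
        e_hi = score_interaction(*_carbon_pair(3.8 + eps), w)
        assert e_lo.repulsion < 1e-13
        assert e_hi.repulsion == 0.0
        slope = (e_lo.repulsion - e_hi.repulsion) / (2 * eps)
        assert abs(slope) < 1e-6

    def test_inter_part_symmetric(self, toy9):
        w = ScoringWeights()
        pep = type_atoms(toy9.peptide)
        rec = type_atoms(toy9.receptor)
        ab = score_interaction(pep, rec, w)
        # swapping roles moves the intra-pair bookkeeping; compare after
        # subtracting each side's own intra contribution
        empty = Structure(chains=[Chain(id="Z")])
        pep_intra = score_interaction(pep, type_atoms(empty), w)
        rec_intra = score_interaction(rec, type_atoms(empty), w)
        ba = score_interaction(rec, pep, w)
        assert ab.total - pep_intra.total == pytest.approx(
            ba.total - rec_intra.total, abs=1e-9)

    def test_bit_reproducible(self, toy9):
        w = ScoringWeights()
        pep = type_atoms(toy9.peptide)
        rec = type_atoms(toy9.receptor)
        a = score_interaction(pep, rec, w)
        b = score_interaction(pep, rec, w)
        assert a.terms().tobytes() == b.terms().tobytes()

    def test_total_is_weighted_sum(self, toy9):
        w = ScoringWeights(w_electrostatic=0.2)
        e = score_interaction(type_atoms(toy9.peptide), type_atoms(toy9.receptor), w)
        assert e.total == pytest.approx(float(w.vector() @ e.terms()), abs=1e-9)

    def test_grid_equals_brute_force(self, toy9):
        w = ScoringWeights(w_electrostatic=0.3)
        pep = type_atoms(toy9.peptide)
        rec = type_atoms(toy9.receptor)
        fast = score_interaction(pep, rec, w)
        from groovedock.scoring import _pair_arrays, _pair_term_matrix, _intra_pairs

        terms = np.zeros(6)
        for i in range(len(pep)):
            for j in range(len(rec)):
                r = np.linalg.norm(pep.coords[i] - rec.coords[j])
                if r <= w.cutoff:
                    arrays = _pair_arrays(pep, rec, np.array([i]), np.array([j]))
                    terms += _pair_term_matrix(np.array([r]), *arrays)[0]
        intra = _intra_pairs(pep)
        for i, j in intra:
            r = np.linalg.norm(pep.coords[i] - pep.coords[j])
            if r <= w.cutoff:
                arrays = _pair_arrays(pep, pep, np.array([i]), np.array([j]))
                terms += _pair_term_matrix(np.array([r]), *arrays)[0]
        assert np.allclose(fast.terms(), terms, atol=1e-9)


class TestFlexibleSelection:
    def test_distant_peptide_selects_nothing(self, toy9):
        far = toy9.peptide.copy()
        for a in far.atoms():
            a.pos = a.pos + np.array([500.0, 0.0, 0.0])
        assert select_flexible_sidechains(toy9.receptor, far, 4.0) == []

    def test_infinite_radius_selects_all_rotatable(self, toy9):
        from groovedock.sidechains import thread_receptor
        from groovedock.structure import chain_sequence

        seq = list(chain_sequence(toy9.receptor.chains[0]))
        for pos in (3, 50, 120):
            seq[pos] = "L"
        rec = thread_receptor(toy9.receptor, "".join(seq))
        sel = select_flexible_sidechains(rec, toy9.peptide, np.inf)
        assert sel == [("A", 4), ("A", 51), ("A", 121)]

    def test_matches_brute_force_scan(self, toy9):
        from groovedock.sidechains import BACKBONE_NAMES, thread_receptor
        from groovedock.structure import chain_sequence

        seq = list(chain_sequence(toy9.receptor.chains[0]))
        for pos in range(0, 180, 7):
            seq[pos] = "S"
        rec = thread_receptor(toy9.receptor, "".join(seq))
        radius = 6.0
        sel = select_flexible_sidechains(rec, toy9.peptide, radius)
        pep_pts = toy9.peptide.coords()
        expected = []
        for ordinal, res in enumerate(rec.chains[0].residues, start=1):
            if res.name in ("GLY", "ALA", "PRO"):
                continue
            side = [a.pos for a in res.atoms if a.name not in BACKBONE_NAMES]
            if any(np.min(np.linalg.norm(pep_pts - p, axis=1)) <= radius
                   for p in side):
                expected.append(("A", ordinal))
        assert sel == expected


class TestMinimizePose:
    def test_relaxed_pose_is_fixed_point(self, toy9):
        w = ScoringWeights()
        e0 = score_interaction(type_atoms(toy9.peptide), type_atoms(toy9.receptor), w)
        pep, rec, e1 = minimize_pose(toy9.peptide, toy9.receptor, [], w)
        assert e1.total <= e0.total
        assert e1.total == pytest.approx(e0.total, abs=0.15)
        before = toy9.peptide.coords()
        after = pep.coords()
        assert float(np.sqrt(np.mean(np.sum((before - after) ** 2, axis=1)))) < 0.5

    def test_two_atom_clash_relaxes_to_zero_repulsion(self):
        pep = _structure_of_atoms([("CB", "C", (0.0, 0, 0))])
        rec = _structure_of_atoms([("CB", "C", (3.3, 0, 0))], chain_id="Y")
        w = ScoringWeights(w_gauss1=0, w_gauss2=0, w_hydrophobic=0, w_hbond=0)
        out = minimize_pose(pep, rec, [], w)
        assert out is not None
        _, _, e = out
        assert e.repulsion == pytest.approx(0.0, abs=1e-6)
        sep = np.linalg.norm(out[0].coords()[0] - rec.coords()[0])
        assert sep >= 3.8 - 1e-3  # surface distance d >= 0

    def test_descent_on_perturbed_poses(self, toy9):
        from groovedock.fixtures import perturb_pose

        w = ScoringWeights()
        rec_typed = type_atoms(toy9.receptor)
        for seed in range(10):
            pert = perturb_pose(toy9.peptide, 0.6 + 0.1 * seed, seed)
            e0 = score_interaction(type_atoms(pert), rec_typed, w)
            out = minimize_pose(pert, toy9.receptor, [], w,
                                MinimizeConfig(max_iters=15))
            assert out is not None
            assert out[2].total <= e0.total + 1e-9

    def test_receptor_backbone_and_rigid_sidechains_unmoved(self, toy9):
        from groovedock.fixtures import perturb_pose
        from groovedock.sidechains import BACKBONE_NAMES, thread_receptor
        from groovedock.structure import chain_sequence

        seq = list(chain_sequence(toy9.receptor.chains[0]))
        for pos in (85, 95, 105):  # floor residues near the peptide
            seq[pos] = "L"
        rec = thread_receptor(toy9.receptor, "".join(seq))
        pert = perturb_pose(toy9.peptide, 0.5, 3)
        flexible = select_flexible_sidechains(rec, pert, 8.0)
        out = minimize_pose(pert, rec, flexible, ScoringWeights(),
                            MinimizeConfig(max_iters=10))
        assert out is not None
        rec_out = out[1]
        flexible_set = set(flexible)
        for ordinal, (r0, r1) in enumerate(zip(rec.chains[0].residues,
                                               rec_out.chains[0].residues), start=1):
            for a0, a1 in zip(r0.atoms, r1.atoms):
                if a0.name in BACKBONE_NAMES or ("A", ordinal) not in flexible_set:
                    assert np.array_equal(a0.pos, a1.pos), \
                        f"moved {a0.name} of rigid residue {ordinal}"
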