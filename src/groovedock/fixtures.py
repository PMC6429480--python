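"""Synthetic test systems: an idealized binding groove with a planted peptide.

The toy receptor is a geometric idealization of a class I groove: two
poly-alanine alpha-helices running along x about 13 A apart, sitting above
an antiparallel-strand floor, 180 residues in one chain. A peptide in a
near-extended conformation is planted between the helices, clash-free and
with its terminal CA atoms clear of the receptor, so anchor transfer, loop
closure, packing, scoring and recovery are all measurable at desk scale.
These fixtures make no claim of biological realism.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import geometry as geom
from .anchors import AnchorSpec, TemplateEntry, TemplateRegistry, anchor_spec_from_peptide
from .loop_closure import BackboneConformation, backbone_clash
from .sidechains import build_sidechains, clash_count, place_residue_atoms
from .structure import Atom, Chain, Residue, Structure

__all__ = [
    "ToyComplex",
    "make_toy_complex",
    "make_toy_template",
    "fixture_template_registry",
    "perturb_pose",
    "TOY_PEPTIDE_SEQUENCES",
]

#: Planted peptide sequences per supported length: leucine termini act as
#: anchor sidechains wedged into the groove-end pockets; interiors stay
#: chi-light so minimization has few sidechain degrees of freedom.
TOY_PEPTIDE_SEQUENCES = {
    8: "LASGVLSL",
    9: "LASGVLASL",
    10: "LASGVLAASL",
    11: "LASGVLAGASL",
}

_HELIX_PHI_PSI = (-57.0, -47.0)
_STRAND_PHI_PSI = (-120.0, 140.0)
_HELIX_LEN = 40
_STRAND_LEN = 20
_HELIX_Y = 7.6
_HELIX_Z = 6.0
_PEPTIDE_Z = 6.5
#: helix CB atoms with |CA x| in this range are omitted: two shallow clefts
#: that stand in for the anchor pockets at the groove ends.
_CLEFT_X_RANGE = (6.5, 21.0)
#: extended-chain CA rise per residue used to position the groove end walls
_CA_RISE = 3.45
#: clearance between a terminal CA and the groove end wall
_WALL_CLEARANCE = 6.0
#: dihedral jitter (deg) applied to the middle residues when planting; the
#: terminal two residues at each end keep exact extended geometry (the toy
#: analogue of conserved anchor placement across solved structures)
_PLANT_JITTER = 5.0


@dataclass
class ToyComplex:
    receptor: Structure
    peptide: Structure
    spec: AnchorSpec


def _segment_backbone(n_res: int, phi: float, psi: float,
                      jitter: np.ndarray | None = None) -> np.ndarray:
    dih = np.zeros((n_res, 3))
    dih[:, 0] = phi
    dih[:, 1] = psi
    dih[:, 2] = 180.0
    if jitter is not None:
        dih[:, :2] += jitter
    return geom.build_backbone(dih)


def _orient_along_x(bb: np.ndarray, center: np.ndarray) -> np.ndarray:
    """Rigidly move a backbone so its CA principal axis runs along +x
    through `center`. Deterministic (SVD-based)."""
    cas = bb[:, 1, :]
    centroid = cas.mean(axis=0)
    u, s, vt = np.linalg.svd(cas - centroid)
    axes = vt  # rows: principal directions
    if np.dot(cas[-1] - cas[0], axes[0]) < 0:
        axes[0] = -axes[0]
    axes[2] = np.cross(axes[0], axes[1])  # right-handed
    rot = axes  # maps world coords into principal frame; use transpose layout
    flat = (bb.reshape(-1, 3) - centroid) @ rot.T
    return (flat + np.asarray(center, dtype=float)).reshape(bb.shape)


def _poly_ala_residues(bb: np.ndarray, start_seq_id: int) -> list[Residue]:
    oxy = geom.place_carbonyl_oxygens(bb)
    residues = []
    for i in range(bb.shape[0]):
        res = Residue(name="ALA", seq_id=start_seq_id + i)
        res.atoms.append(Atom("N", "N", bb[i, 0].copy()))
        res.atoms.append(Atom("CA", "C", bb[i, 1].copy()))
        res.atoms.append(Atom("C", "C", bb[i, 2].copy()))
        res.atoms.append(Atom("O", "O", oxy[i].copy()))
        cb = place_residue_atoms("ALA", bb[i])["CB"]
        res.atoms.append(Atom("CB", "C", cb))
        residues.append(res)
    return residues


def _toy_receptor(peptide_length: int) -> Structure:
    """Deterministic groove: 2 helices over a 5-strand floor, closed at both
    ends by wall segments just beyond the planted peptide's termini (the
    groove-closing walls play the role of the terminal anchor pockets).

    The wall x-position is nudged by a small deterministic offset when the
    nominal placement happens to interdigitate with the floor's zigzag."""
    last_error: Exception | None = None
    for wall_dx in (0.0, 0.9, -0.9, 1.7):
        try:
            return _assemble_toy_receptor(peptide_length, wall_dx)
        except RuntimeError as exc:
            last_error = exc
    raise RuntimeError(
        f"could not assemble a self-consistent toy receptor for "
        f"{peptide_length}-mers"
    ) from last_error


def _assemble_toy_receptor(peptide_length: int, wall_dx: float) -> Structure:
    chain = Chain(id="A")
    seq_id = 1
    lo, hi = _CLEFT_X_RANGE
    for y in (-_HELIX_Y, _HELIX_Y):
        bb = _segment_backbone(_HELIX_LEN, *_HELIX_PHI_PSI)
        bb = _orient_along_x(bb, np.array([0.0, y, _HELIX_Z]))
        residues = _poly_ala_residues(bb, seq_id)
        for res in residues:
            if lo <= abs(res.atom("CA").pos[0]) <= hi:
                res.atoms = [a for a in res.atoms if a.name != "CB"]
        chain.residues.extend(residues)
        seq_id += _HELIX_LEN
    for k in range(5):
        y = (k - 2) * 4.8
        bb = _segment_backbone(_STRAND_LEN, *_STRAND_PHI_PSI)
        bb = _orient_along_x(bb, np.array([0.0, y, 0.0]))
        chain.residues.extend(_poly_ala_residues(bb, seq_id))
        seq_id += _STRAND_LEN
    # end walls: short cross-strands running along y at both groove ends
    wall_x = _CA_RISE * (peptide_length - 1) / 2.0 + _WALL_CLEARANCE + wall_dx
    rot_z90 = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
    for sign in (-1.0, 1.0):
        for z in (3.9, 7.2):
            bb = _segment_backbone(2, *_STRAND_PHI_PSI)
            bb = _orient_along_x(bb, np.zeros(3))
            bb = (bb.reshape(-1, 3) @ rot_z90.T).reshape(bb.shape)
            bb = bb + np.array([sign * wall_x, 0.0, z])
            chain.residues.extend(_poly_ala_residues(bb, seq_id))
            seq_id += 2
    for i, res in enumerate(chain.residues, start=1):
        for a in res.atoms:
            a.residue_index = i
    receptor = Structure(chains=[chain],
                         label=f"toy groove receptor ({peptide_length}-mer)")
    _sculpt_internal_contacts(receptor)
    return receptor


def _sculpt_internal_contacts(receptor: Structure) -> None:
    """Remove CB stubs that sit closer than 0.6 x summed vdW radii to another
    receptor segment. Idealized rigid segments interpenetrate where a real,
    packed fold would not; pruning the offending sidechain stubs leaves a
    receptor whose internal geometry is self-consistent at the clash
    threshold used throughout the pipeline."""
    from .sidechains import _close_pairs, structure_bond_graph
    from .scoring import VDW_RADII_BY_ELEMENT
    from scipy.spatial import cKDTree

    chain = receptor.chains[0]
    for _ in range(5):
        atoms = [(res, a) for res in chain.residues for a in res.atoms]
        coords = np.array([a.pos for _, a in atoms])
        radii = np.array([VDW_RADII_BY_ELEMENT[a.element] for _, a in atoms])
        excluded = _close_pairs(structure_bond_graph(receptor), max_sep=3)
        tree = cKDTree(coords)
        doomed: set[int] = set()
        for i, j in tree.query_pairs(0.6 * 2 * radii.max()):
            if (min(i, j), max(i, j)) in excluded:
                continue
            if np.linalg.norm(coords[i] - coords[j]) < 0.6 * (radii[i] + radii[j]):
                for k in (i, j):
                    if atoms[k][1].name == "CB":
                        doomed.add(k)
                        break
                else:
                    raise RuntimeError(
                        "toy receptor backbone segments interpenetrate; "
                        "adjust the construction constants"
                    )
        if not doomed:
            return
        for k in doomed:
            res, atom = atoms[k]
            res.atoms = [a for a in res.atoms if a is not atom]
    raise RuntimeError("toy receptor sculpting did not converge")


_RECEPTOR_CACHE: dict[int, Structure] = {}


def _toy_receptor_cached(peptide_length: int) -> Structure:
    if peptide_length not in _RECEPTOR_CACHE:
        _RECEPTOR_CACHE[peptide_length] = _toy_receptor(peptide_length)
    return _RECEPTOR_CACHE[peptide_length]


def _min_distance_to(coords: np.ndarray, point: np.ndarray) -> float:
    return float(np.min(np.linalg.norm(coords - point, axis=1)))


def make_toy_complex(peptide_length: int, seed: int) -> ToyComplex:
    """Deterministic toy groove + planted clash-free peptide of the given length.

    The planted peptide is locally energy-relaxed in the groove before the
    anchor spec is derived, so the planted pose is a genuine minimum of the
    scoring function (as a crystal conformation is of nature's), and all
    ToyComplex invariants are re-checked afterwards.
    """
    from .scoring import minimize_pose  # deferred: scoring builds on fixtures' deps

    if peptide_length not in TOY_PEPTIDE_SEQUENCES:
        raise ValueError(f"toy peptides support lengths 8-11, got {peptide_length}")
    sequence = TOY_PEPTIDE_SEQUENCES[peptide_length]
    receptor = _toy_receptor_cached(peptide_length).copy()
    rec_coords = receptor.coords()
    rng = np.random.default_rng([seed, peptide_length])
    for _attempt in range(300):
        jitter = rng.normal(0.0, _PLANT_JITTER, size=(peptide_length, 2))
        jitter[:2] = 0.0
        jitter[-2:] = 0.0
        bb = _segment_backbone(peptide_length, *_STRAND_PHI_PSI, jitter=jitter)
        bb = _orient_along_x(bb, np.array([0.0, 0.0, _PEPTIDE_Z]))
        oxy = geom.place_carbonyl_oxygens(bb)
        dih_tab = np.full((peptide_length, 3), np.nan)
        measured = geom.measure_backbone_dihedrals(bb)
        for i, t in enumerate(measured):
            dih_tab[i] = [np.nan if v is None else v for v in t]
        conf = BackboneConformation(
            sequence, dih_tab,
            np.concatenate([bb, oxy[:, None, :]], axis=1),
        )
        if backbone_clash(conf, receptor, 0.6):
            continue
        anchor_cas = [bb[0, 1], bb[1, 1], bb[-2, 1], bb[-1, 1]]
        if min(_min_distance_to(rec_coords, ca) for ca in anchor_cas) < 4.0:
            continue
        peptide = build_sidechains(conf, sequence, receptor, chain_id="P")
        if clash_count(peptide, receptor, 0.6) > 0:
            continue
        relaxed = minimize_pose(peptide, receptor, [])
        if relaxed is None:
            continue
        peptide = relaxed[0]
        if clash_count(peptide, receptor, 0.6) > 0:
            continue
        cas = [peptide.chains[0].residues[i].atom("CA").pos
               for i in (0, 1, peptide_length - 2, peptide_length - 1)]
        if min(_min_distance_to(rec_coords, ca) for ca in cas) < 4.0:
            continue
        spec = anchor_spec_from_peptide(peptide)
        return ToyComplex(receptor=receptor, peptide=peptide, spec=spec)
    raise RuntimeError(
        f"could not plant a clash-free {peptide_length}-mer in the toy groove"
    )


def make_toy_template(peptide_length: int, seed: int) -> TemplateEntry:
    """Wrap a toy complex as a template usable for anchor transfer."""
    toy = make_toy_complex(peptide_length, seed)
    combined = Structure(
        chains=[toy.receptor.chains[0], toy.peptide.chains[0]],
        label=f"TOY{peptide_length}",
    )
    return TemplateEntry(
        peptide_length=peptide_length,
        structure=combined,
        peptide_chain_id="P",
        source_id=f"TOY{peptide_length}",
    )


def fixture_template_registry(seed: int = 0) -> TemplateRegistry:
    """Synthetic template registry covering lengths 8-11 (for tests/demos)."""
    reg = TemplateRegistry()
    for length in TOY_PEPTIDE_SEQUENCES:
        reg.add_entry(make_toy_template(length, seed))
    return reg


def perturb_pose(peptide: Structure, magnitude: float, seed: int) -> Structure:
    """Jitter all peptide atoms with RMS displacement ~= magnitude (Angstrom),
    re-idealizing the covalent geometry afterwards.

    The jitter is Cartesian; the backbone is then rebuilt from its measured
    dihedrals and sidechains re-attached at their measured chi angles, and
    the jitter amplitude is rescaled (two calibration passes) so the realized
    RMS displacement from the input matches the requested magnitude.
    """
    if magnitude < 0:
        raise ValueError("magnitude must be >= 0")
    if magnitude == 0:
        return peptide.copy()
    from .scoring import _PeptideModel  # internal-coordinate rebuild machinery

    rng = np.random.default_rng(seed)
    orig = np.array([a.pos for a in peptide.atoms()]).reshape(-1, 3)
    unit = rng.normal(size=orig.shape)
    unit /= np.sqrt(np.mean(np.sum(unit ** 2, axis=1)))  # RMS displacement 1

    ang = np.radians(geom.ANGLE_N_CA_C)
    ideal_triad = np.array([
        [0.0, 0.0, 0.0],
        [geom.BOND_N_CA, 0.0, 0.0],
        [geom.BOND_N_CA - geom.BOND_CA_C * np.cos(ang),
         geom.BOND_CA_C * np.sin(ang), 0.0],
    ])

    def realize(scale: float) -> tuple[Structure, float]:
        jittered = peptide.copy()
        for k, a in enumerate(jittered.atoms()):
            a.pos = orig[k] + scale * unit[k]
        model = _PeptideModel(jittered)
        # re-idealize the seed triad so residue 1 also has ideal geometry
        t, _ = geom.superpose(model.seed, ideal_triad)
        model.seed = t.apply(ideal_triad)
        rebuilt = model.rebuild(model.x0)
        out = jittered
        for k, a in enumerate(out.atoms()):
            a.pos = rebuilt[k]
        rms = float(np.sqrt(np.mean(np.sum((rebuilt - orig) ** 2, axis=1))))
        return out, rms

    # realized RMS behaves like sqrt(floor^2 + (k * scale)^2): the floor is the
    # re-idealization residual at zero jitter; solve for the scale directly
    _, floor = realize(0.0)
    if floor >= magnitude:
        return realize(0.0)[0]
    result, probe = realize(magnitude)
    k = np.sqrt(max(probe ** 2 - floor ** 2, 1e-12)) / magnitude
    scale = np.sqrt(max(magnitude ** 2 - floor ** 2, 0.0)) / k
    result, rms = realize(scale)
    for _ in range(2):
        if abs(rms - magnitude) <= 0.02 * magnitude or rms <= 0:
            break
        scale *= np.sqrt(max(magnitude ** 2 - floor ** 2, 1e-12)) / \
            np.sqrt(max(rms ** 2 - floor ** 2, 1e-12))
        result, rms = realize(scale)
    return result
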