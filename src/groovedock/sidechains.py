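"""Sidechain construction on sampled backbones, and receptor threading.

Each residue's heavy-atom sidechain is instantiated from ideal residue
geometry (CCD chemical-component templates via biotite), rigidly attached to
the residue's own N/CA/C frame, and set to discrete chi-angle rotamers from a
small backbone-independent library. Rotamers are chosen greedily N->C by
minimum clash count against the environment and the peptide built so far;
ties break to the higher prior weight, then the lower library index.
Downstream minimization refines chi angles continuously, so the library only
needs to provide clash-avoiding starting points (proline keeps its template
ring pucker; no rotamers are applied to it).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np
from scipy.spatial import cKDTree

from . import geometry as geom
from .loop_closure import BackboneConformation
from .structure import Atom, Chain, ONE_TO_THREE, Residue, Structure

__all__ = [
    "RotamerSet",
    "load_rotamer_library",
    "build_sidechains",
    "thread_receptor",
    "clash_count",
    "structure_bond_graph",
    "CHI_ATOMS",
    "residue_template",
]

BACKBONE_NAMES = ("N", "CA", "C", "O")

#: Standard chi-angle atom quadruples per residue type.
CHI_ATOMS: dict[str, list[tuple[str, str, str, str]]] = {
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "CYS": [("N", "CA", "CB", "SG")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
            ("CB", "CG", "SD", "CE")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "SER": [("N", "CA", "CB", "OG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "VAL": [("N", "CA", "CB", "CG1")],
    "ALA": [], "GLY": [], "PRO": [],
}


class UnknownResidueTypeError(KeyError):
    pass


@dataclass
class RotamerSet:
    """Per-residue-type chi-angle rotamers with prior weights."""

    rotamers: dict[str, list[tuple[tuple[float, ...], float]]]

    def __post_init__(self) -> None:
        for res, entries in self.rotamers.items():
            total = sum(w for _, w in entries)
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"rotamer weights for {res} sum to {total}, not 1")
            if any(w <= 0 for _, w in entries):
                raise ValueError(f"non-positive rotamer weight for {res}")
            n_chi = len(CHI_ATOMS.get(res, []))
            for chis, _ in entries:
                if len(chis) != n_chi:
                    raise ValueError(
                        f"{res} rotamer has {len(chis)} chis, expected {n_chi}"
                    )

    def for_residue(self, res_name: str) -> list[tuple[tuple[float, ...], float]]:
        try:
            return self.rotamers[res_name]
        except KeyError:
            raise UnknownResidueTypeError(f"no rotamers for residue type {res_name!r}") from None


@lru_cache(maxsize=1)
def load_rotamer_library() -> RotamerSet:
    """Parse the bundled whitespace-delimited rotamer table."""
    text = resources.files("groovedock.data").joinpath("rotamers.txt").read_text()
    table: dict[str, list[tuple[tuple[float, ...], float]]] = {}
    for raw in text.splitlines():
        line = raw.split("#")[0].strip()
        if not line:
            continue
        parts = line.split()
        res = parts[0]
        chis = tuple(float(x) for x in parts[1:5] if x != "-")
        weight = float(parts[5])
        table.setdefault(res, []).append((chis[:len(CHI_ATOMS[res])], weight))
    return RotamerSet(table)


@lru_cache(maxsize=32)
def residue_template(res_name: str):
    """Ideal heavy-atom geometry and bonds for a residue type.

    Returns (names, coords (m,3), elements, bonds set of index pairs).
    """
    import biotite.structure.info as info

    try:
        arr = info.residue(res_name)
    except Exception as exc:  # biotite raises KeyError subclasses
        raise UnknownResidueTypeError(f"unknown residue type {res_name!r}") from exc
    if arr is None:
        raise UnknownResidueTypeError(f"unknown residue type {res_name!r}")
    keep = (arr.element != "H") & (arr.atom_name != "OXT")
    idx_map = {old: new for new, old in enumerate(np.where(keep)[0])}
    names = tuple(arr.atom_name[keep])
    coords = np.array(arr.coord[keep], dtype=float)
    elements = tuple(arr.element[keep])
    bonds = set()
    for i, j, _ in arr.bonds.as_array():
        if i in idx_map and j in idx_map:
            a, b = idx_map[i], idx_map[j]
            bonds.add((min(a, b), max(a, b)))
    return names, coords, elements, frozenset(bonds)


def _template_adjacency(res_name: str) -> dict[str, set[str]]:
    names, _, _, bonds = residue_template(res_name)
    adj: dict[str, set[str]] = {n: set() for n in names}
    for i, j in bonds:
        adj[names[i]].add(names[j])
        adj[names[j]].add(names[i])
    return adj


def _chi_moving_sets(res_name: str) -> list[list[str]]:
    """For each chi, the atom names swept by rotating that chi."""
    adj = _template_adjacency(res_name)
    out = []
    for (_, b, c, _) in CHI_ATOMS[res_name]:
        seen = {b, c}
        stack = [c]
        moving = []
        while stack:
            cur = stack.pop()
            for nb in sorted(adj[cur]):
                if nb not in seen:
                    seen.add(nb)
                    moving.append(nb)
                    stack.append(nb)
        out.append(moving)
    return out


@lru_cache(maxsize=32)
def _template_local(res_name: str):
    """Template heavy-atom coordinates expressed in the N/CA/C triad frame."""
    names, coords, _, _ = residue_template(res_name)
    name_idx = {n: i for i, n in enumerate(names)}
    for req in ("N", "CA", "C"):
        if req not in name_idx:
            raise UnknownResidueTypeError(f"template {res_name} lacks backbone atom {req}")
    origin, frame = geom.triad_frame(coords[name_idx["N"]], coords[name_idx["CA"]],
                                     coords[name_idx["C"]])
    local = (coords - origin) @ frame  # rows: atom coords in frame axes
    return names, local


def place_residue_atoms(res_name: str, backbone_nca_c: np.ndarray,
                        chis: tuple[float, ...] = ()) -> dict[str, np.ndarray]:
    """All heavy sidechain atoms (incl. CB) for a residue at the given chis.

    The ideal template geometry is rigidly attached to the residue's own
    N/CA/C frame; chi angles are then set exactly by rotating the swept
    atoms about each chi bond in order.
    """
    names, local = _template_local(res_name)
    bb = np.asarray(backbone_nca_c, dtype=float)
    origin, frame = geom.triad_frame(bb[0], bb[1], bb[2])
    global_coords = origin + local @ frame.T
    placed = {n: global_coords[i] for i, n in enumerate(names)}
    chi_defs = CHI_ATOMS[res_name]
    if chis:
        moving_sets = _chi_moving_sets(res_name)
        for k, target in enumerate(chis):
            a, b, c, d = chi_defs[k]
            current = geom.dihedral_angle(placed[a], placed[b], placed[c], placed[d])
            delta = math.radians(geom.wrap_angle(target - current))
            pivot = placed[c]
            ax = pivot - placed[b]
            ax = ax / math.sqrt(ax[0] ** 2 + ax[1] ** 2 + ax[2] ** 2)
            cth, sth = math.cos(delta), math.sin(delta)
            moving = moving_sets[k]
            v = np.array([placed[nm] for nm in moving]) - pivot
            proj = v @ ax
            cross = np.empty_like(v)
            cross[:, 0] = ax[1] * v[:, 2] - ax[2] * v[:, 1]
            cross[:, 1] = ax[2] * v[:, 0] - ax[0] * v[:, 2]
            cross[:, 2] = ax[0] * v[:, 1] - ax[1] * v[:, 0]
            rotated = pivot + cth * v + sth * cross + np.outer((1.0 - cth) * proj, ax)
            for row, nm in enumerate(moving):
                placed[nm] = rotated[row]
    return {n: p for n, p in placed.items() if n not in ("N", "CA", "C", "O")}


_ELEMENT_OF = {"C": "C", "N": "N", "O": "O", "S": "S"}


def _atom_element(name: str) -> str:
    return _ELEMENT_OF.get(name[0], name[0])


def _vdw(element: str) -> float:
    from .scoring import VDW_RADII_BY_ELEMENT

    return VDW_RADII_BY_ELEMENT.get(element, 1.9)


def build_sidechains(backbone: BackboneConformation, sequence: str,
                     environment: Structure, rng: np.random.Generator | None = None,
                     clash_factor: float = 0.6, chain_id: str = "P") -> Structure:
    """Full heavy-atom peptide from a backbone, greedy clash-avoiding rotamers.

    Backbone N/CA/C/O coordinates are taken over unchanged. `rng` is accepted
    for interface symmetry; the greedy choice itself is deterministic.
    """
    if backbone.n != len(sequence):
        raise ValueError("backbone residue count does not match sequence length")
    library = load_rotamer_library()
    env_coords = []
    env_radii = []
    for a in environment.atoms():
        env_coords.append(a.pos)
        env_radii.append(_vdw(a.element))
    env_coords = np.array(env_coords).reshape(-1, 3)
    env_radii = np.array(env_radii)
    env_tree = cKDTree(env_coords) if len(env_coords) else None

    chain = Chain(id=chain_id)
    placed_coords: list[np.ndarray] = []  # peptide atoms so far (for packing)
    placed_radii: list[float] = []
    placed_resid: list[int] = []

    def count_clashes(cand: dict[str, np.ndarray], res_i: int) -> int:
        total = 0
        for nm, p in cand.items():
            r = _vdw(_atom_element(nm))
            if env_tree is not None:
                for j in env_tree.query_ball_point(p, clash_factor * (r + env_radii.max())):
                    if np.linalg.norm(p - env_coords[j]) < clash_factor * (r + env_radii[j]):
                        total += 1
            for q, rq, resq in zip(placed_coords, placed_radii, placed_resid):
                # skip short-range bonded neighborhood: own and adjacent residues'
                # backbone is within 3 bonds only of CB/CG-level atoms, which the
                # template geometry already keeps clash-free
                if abs(resq - res_i) <= 1:
                    continue
                if np.linalg.norm(p - q) < clash_factor * (r + rq):
                    total += 1
        return total

    for i, aa in enumerate(sequence):
        res_name = ONE_TO_THREE.get(aa)
        if res_name is None:
            raise UnknownResidueTypeError(f"unknown one-letter residue {aa!r}")
        res = Residue(name=res_name, seq_id=i + 1)
        for k, nm in enumerate(BACKBONE_NAMES):
            res.atoms.append(Atom(nm, _atom_element(nm), backbone.coords[i, k].copy(),
                                  residue_index=i + 1))
        rotamers = library.for_residue(res_name)
        best = None  # (clashes, -weight, index, atoms)
        for idx, (chis, weight) in enumerate(rotamers):
            cand = place_residue_atoms(res_name, backbone.coords[i, :3], chis)
            key = (count_clashes(cand, i), -weight, idx)
            if best is None or key < best[0]:
                best = (key, cand)
        assert best is not None
        for nm in sorted(best[1], key=_sidechain_order(res_name)):
            p = best[1][nm]
            res.atoms.append(Atom(nm, _atom_element(nm), p, residue_index=i + 1))
            placed_coords.append(p)
            placed_radii.append(_vdw(_atom_element(nm)))
            placed_resid.append(i)
        # backbone atoms also obstruct later residues' rotamers
        for k in range(4):
            placed_coords.append(backbone.coords[i, k])
            placed_radii.append(_vdw(_atom_element(BACKBONE_NAMES[k])))
            placed_resid.append(i)
        chain.residues.append(res)
    return Structure(chains=[chain], label="peptide")


def _sidechain_order(res_name: str):
    names, _, _, _ = residue_template(res_name)
    rank = {n: i for i, n in enumerate(names)}

    def key(nm: str) -> int:
        return rank.get(nm, len(rank))

    return key


def thread_receptor(template_receptor: Structure, target_sequence: str,
                    rng: np.random.Generator | None = None,
                    clash_factor: float = 0.6) -> Structure:
    """Copy the template backbone, rebuilding sidechains where the sequence differs.

    A lightweight stand-in for full homology modelling: indels are unsupported
    and identical positions keep their template sidechains untouched.
    """
    out = template_receptor.copy()
    chain = out.chains[0]
    if len(chain) != len(target_sequence):
        raise ValueError(
            f"unsupported indel: template has {len(chain)} residues, target "
            f"sequence has {len(target_sequence)}"
        )
    library = load_rotamer_library()
    for i, aa in enumerate(target_sequence):
        res = chain.residues[i]
        target_name = ONE_TO_THREE.get(aa)
        if target_name is None:
            raise UnknownResidueTypeError(f"unknown one-letter residue {aa!r}")
        if res.name == target_name:
            continue
        bb = res.backbone_coords(("N", "CA", "C"))
        kept = [a for a in res.atoms if a.name in BACKBONE_NAMES]
        res.name = target_name
        res.atoms = kept
        # instantiate the new sidechain once so bond separations can be
        # computed exactly, then score rotamers with the clash-count metric
        first = place_residue_atoms(target_name,
                                    bb, library.for_residue(target_name)[0][0])
        side_names = sorted(first, key=_sidechain_order(target_name))
        for nm in side_names:
            res.atoms.append(Atom(nm, _atom_element(nm), first[nm], residue_index=i + 1))
        adj = structure_bond_graph(out)
        excluded = _close_pairs(adj, max_sep=3)
        all_atoms = [a for r2 in chain.residues for a in r2.atoms]
        index_of = {id(a): k for k, a in enumerate(all_atoms)}
        side_idx = [index_of[id(a)] for a in res.atoms if a.name in side_names]
        other_idx = [k for k, a in enumerate(all_atoms)
                     if a.residue_index != i + 1 or a.name in BACKBONE_NAMES]
        other_coords = np.array([all_atoms[k].pos for k in other_idx]).reshape(-1, 3)
        other_radii = np.array([_vdw(all_atoms[k].element) for k in other_idx])
        tree = cKDTree(other_coords) if len(other_coords) else None
        best = None
        for idx, (chis, weight) in enumerate(library.for_residue(target_name)):
            cand = place_residue_atoms(target_name, bb, chis)
            clashes = 0
            if tree is not None:
                for nm, gi in zip(side_names, side_idx):
                    p = cand[nm]
                    r = _vdw(_atom_element(nm))
                    for jj in tree.query_ball_point(p, clash_factor * (r + other_radii.max())):
                        gj = other_idx[jj]
                        pair = (min(gi, gj), max(gi, gj))
                        if pair in excluded:
                            continue
                        if np.linalg.norm(p - other_coords[jj]) < \
                                clash_factor * (r + other_radii[jj]):
                            clashes += 1
            key = (clashes, -weight, idx)
            if best is None or key < best[0]:
                best = (key, cand)
        assert best is not None
        for a in res.atoms:
            if a.name in side_names:
                a.pos = best[1][a.name]
    return out


def structure_bond_graph(s: Structure) -> list[set[int]]:
    """Adjacency over global atom indices (iteration order): template bonds
    within residues plus the inter-residue C-N link along each chain."""
    index_of: dict[int, int] = {}
    flat: list[tuple[int, int, str]] = []  # (chain_idx, res_idx, name)
    k = 0
    for ci, chain in enumerate(s.chains):
        for ri, res in enumerate(chain.residues):
            for a in res.atoms:
                index_of[id(a)] = k
                flat.append((ci, ri, a.name))
                k += 1
    adj: list[set[int]] = [set() for _ in range(k)]
    k = 0
    for chain in s.chains:
        prev_c_idx = None
        for res in chain.residues:
            local = {a.name: index_of[id(a)] for a in res.atoms}
            try:
                names, _, _, bonds = residue_template(res.name)
                for i, j in bonds:
                    ni, nj = names[i], names[j]
                    if ni in local and nj in local:
                        adj[local[ni]].add(local[nj])
                        adj[local[nj]].add(local[ni])
            except UnknownResidueTypeError:
                pass
            if prev_c_idx is not None and "N" in local:
                adj[prev_c_idx].add(local["N"])
                adj[local["N"]].add(prev_c_idx)
            prev_c_idx = local.get("C")
    return adj


def _close_pairs(adj: list[set[int]], max_sep: int = 3) -> set[tuple[int, int]]:
    """All atom index pairs within max_sep bonds of each other."""
    out: set[tuple[int, int]] = set()
    for start in range(len(adj)):
        frontier = {start}
        seen = {start}
        for _ in range(max_sep):
            frontier = {nb for cur in frontier for nb in adj[cur]} - seen
            seen |= frontier
            for x in frontier:
                if x > start:
                    out.add((start, x))
    return out


def clash_count(subject: Structure, environment: Structure,
                factor: float = 0.6) -> int:
    """Heavy-atom pairs closer than factor * (r_i + r_j).

    Counts subject-vs-environment pairs plus subject-internal pairs at least
    4 bonds apart. KD-tree accelerated; identical to brute force by contract.
    """
    sub_atoms = list(subject.atoms())
    if not sub_atoms:
        return 0
    sub_coords = np.array([a.pos for a in sub_atoms])
    sub_radii = np.array([_vdw(a.element) for a in sub_atoms])
    total = 0
    env_atoms = list(environment.atoms())
    if env_atoms:
        env_coords = np.array([a.pos for a in env_atoms])
        env_radii = np.array([_vdw(a.element) for a in env_atoms])
        tree = cKDTree(env_coords)
        thr = factor * (sub_radii.max() + env_radii.max())
        for i, p in enumerate(sub_coords):
            for j in tree.query_ball_point(p, thr):
                if np.linalg.norm(p - env_coords[j]) < factor * (sub_radii[i] + env_radii[j]):
                    total += 1
    adj = structure_bond_graph(subject)
    excluded = _close_pairs(adj, max_sep=3)
    tree_s = cKDTree(sub_coords)
    thr_s = factor * 2 * sub_radii.max()
    for i, j in tree_s.query_pairs(thr_s):
        if (min(i, j), max(i, j)) in excluded:
            continue
        if np.linalg.norm(sub_coords[i] - sub_coords[j]) < factor * (sub_radii[i] + sub_radii[j]):
            total += 1
    return total
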