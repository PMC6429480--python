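"""Anchored peptide backbone sampling by randomized cyclic coordinate descent.

The peptide's first two residues are fixed exactly on the anchor positions;
phi/psi torsions of the interior are initialized from a coarse Ramachandran
basin mixture and then adjusted one at a time, each by the closed-form
rotation that minimizes the squared distance of the closing-end backbone
atoms (N, CA, C of the last two residues) to their anchor positions.
Restarts alternate the growth direction (N->C and C->N) so closure is
attempted from both ends. Accepted conformations are regenerated from their
dihedrals with NeRF, checked against the anchors, and screened by a
permissive steric filter against the rigid receptor.

Omega is held trans (180 deg); cis peptide bonds are not sampled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from . import geometry as geom
from .anchors import AnchorSpec
from .structure import Structure

__all__ = [
    "ClosureConfig",
    "BackboneConformation",
    "InfeasibleAnchorsError",
    "sample_ramachandran",
    "rcd_close",
    "backbone_clash",
    "sample_backbones",
    "MAX_SPAN_PER_RESIDUE",
]

#: Maximum straight-line span bridged per intervening peptide unit (Angstrom).
MAX_SPAN_PER_RESIDUE = 3.9

# Ramachandran basin mixture: (phi mean, psi mean, weight); spread in degrees.
_RAMA_BASINS = ((-120.0, 140.0, 0.45), (-63.0, -43.0, 0.45), (60.0, 45.0, 0.10))
_RAMA_SPREAD = 20.0
_PRO_PHI_MEAN = -65.0
_PRO_PHI_SPREAD = 8.0


class InfeasibleAnchorsError(ValueError):
    """The anchor gap cannot be bridged by the intervening residues."""


@dataclass
class ClosureConfig:
    n_samples: int = 100
    anchor_tolerance: float = 1.0
    closure_rmsd_target: float = 0.1
    max_ccd_sweeps: int = 200
    max_restarts_per_sample: int = 50
    clash_factor: float = 0.6
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_samples", "anchor_tolerance", "closure_rmsd_target",
                     "max_ccd_sweeps", "max_restarts_per_sample", "clash_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.anchor_tolerance < self.closure_rmsd_target:
            raise ValueError("anchor_tolerance must be >= closure_rmsd_target")


@dataclass
class BackboneConformation:
    """A peptide backbone: per-residue (phi, psi, omega) plus N/CA/C/O coords."""

    sequence: str
    dihedrals: np.ndarray  # (n, 3), degrees; nan where undefined
    coords: np.ndarray  # (n, 4, 3): N, CA, C, O
    closure_error: float = float("nan")

    def __post_init__(self) -> None:
        self.dihedrals = np.asarray(self.dihedrals, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.sequence)
        if self.dihedrals.shape != (n, 3) or self.coords.shape != (n, 4, 3):
            raise ValueError("inconsistent backbone array shapes")

    @property
    def n(self) -> int:
        return len(self.sequence)

    def backbone_nca_c(self) -> np.ndarray:
        return self.coords[:, :3, :]


def sample_ramachandran(residue_name: str, rng: np.random.Generator) -> tuple[float, float]:
    """Draw (phi, psi) in degrees from a coarse 3-basin mixture.

    Basins: beta (-120, 140), alpha (-63, -43), left-handed alpha (60, 45),
    weights 0.45/0.45/0.10, Gaussian spread 20 deg. Glycine mirrors the drawn
    basin with probability 1/2; proline's phi is pinned near -65.
    """
    weights = [b[2] for b in _RAMA_BASINS]
    idx = rng.choice(len(_RAMA_BASINS), p=weights)
    phi_mean, psi_mean, _ = _RAMA_BASINS[idx]
    phi = rng.normal(phi_mean, _RAMA_SPREAD)
    psi = rng.normal(psi_mean, _RAMA_SPREAD)
    if residue_name == "GLY" and rng.random() < 0.5:
        phi, psi = -phi, -psi
    if residue_name == "PRO":
        phi = _PRO_PHI_MEAN + float(np.clip(rng.normal(0.0, _PRO_PHI_SPREAD),
                                            -25.0, 25.0))
    return geom.wrap_angle(phi), geom.wrap_angle(psi)


# ---------------------------------------------------------------------------
# chain building on flat (3n, 3) arrays of N/CA/C atoms
# ---------------------------------------------------------------------------

def _check_feasible(spec: AnchorSpec) -> None:
    n = spec.n
    gap = float(np.linalg.norm(spec.positions[(2, "CA")] - spec.positions[(n - 1, "CA")]))
    max_span = MAX_SPAN_PER_RESIDUE * (n - 3)  # intervening residues + 1 virtual bonds
    if gap > max_span:
        raise InfeasibleAnchorsError(
            f"anchor CA gap {gap:.1f} A exceeds the maximum bridgeable span "
            f"{max_span:.1f} A for a {n}-mer"
        )


def _spec_junction_torsions(spec: AnchorSpec) -> dict[str, float]:
    """Torsions fully determined by the anchor atoms themselves."""
    p = spec.positions
    n = spec.n
    out = {
        # psi(1): N1-CA1-C1-N2 (1-based), all anchor atoms
        "psi1": geom.dihedral_angle(p[(1, "N")], p[(1, "CA")], p[(1, "C")], p[(2, "N")]),
        "omega1": geom.dihedral_angle(p[(1, "CA")], p[(1, "C")], p[(2, "N")], p[(2, "CA")]),
        "phi2": geom.dihedral_angle(p[(1, "C")], p[(2, "N")], p[(2, "CA")], p[(2, "C")]),
        # psi(2) from the slot-2 carbonyl oxygen: O is anti to N(3)
        "psi2": geom.wrap_angle(
            geom.dihedral_angle(p[(2, "N")], p[(2, "CA")], p[(2, "C")], p[(2, "O")]) + 180.0
        ),
        # C-terminal analogues
        "psi_nm1": geom.dihedral_angle(p[(n - 1, "N")], p[(n - 1, "CA")],
                                       p[(n - 1, "C")], p[(n, "N")]),
        "omega_nm1": geom.dihedral_angle(p[(n - 1, "CA")], p[(n - 1, "C")],
                                         p[(n, "N")], p[(n, "CA")]),
        "phi_n": geom.dihedral_angle(p[(n - 1, "C")], p[(n, "N")],
                                     p[(n, "CA")], p[(n, "C")]),
        # last-residue carbonyl direction, reused when rebuilding O(n)
        "o_n_dihedral": geom.dihedral_angle(p[(n, "N")], p[(n, "CA")],
                                            p[(n, "C")], p[(n, "O")]),
    }
    return out


def _full_torsion_table(n: int, free_dihedrals: np.ndarray, junction: dict[str, float]) -> np.ndarray:
    """(n, 3) phi/psi/omega table combining fixed junction values and free draws."""
    dih = np.array(free_dihedrals, dtype=float)
    dih[:, 2] = 180.0  # omega trans everywhere
    dih[0, 0] = np.nan
    dih[0, 1] = junction["psi1"]  # 0-based residue 0 == slot 1
    dih[0, 2] = junction["omega1"]
    dih[1, 0] = junction["phi2"]
    dih[1, 1] = junction["psi2"]
    return dih


def _build_forward_flat(n: int, dih: np.ndarray, spec: AnchorSpec) -> np.ndarray:
    """Flat (3n, 3) N/CA/C array grown N->C from the exact N-terminal anchors."""
    flat = np.zeros((3 * n, 3))
    for j, slot in ((0, 1), (1, 2)):
        for k, name in enumerate(("N", "CA", "C")):
            flat[3 * j + k] = spec.positions[(slot, name)]
    for k in range(6, 3 * n):
        j = k // 3
        which = k % 3
        if which == 0:  # N(j) via psi(j-1)
            flat[k] = geom.place_atom_nerf(flat[k - 3], flat[k - 2], flat[k - 1],
                                           geom.BOND_C_N, geom.ANGLE_CA_C_N, dih[j - 1, 1])
        elif which == 1:  # CA(j) via omega(j-1)
            flat[k] = geom.place_atom_nerf(flat[k - 3], flat[k - 2], flat[k - 1],
                                           geom.BOND_N_CA, geom.ANGLE_C_N_CA, dih[j - 1, 2])
        else:  # C(j) via phi(j)
            flat[k] = geom.place_atom_nerf(flat[k - 3], flat[k - 2], flat[k - 1],
                                           geom.BOND_CA_C, geom.ANGLE_N_CA_C, dih[j, 0])
    return flat


def _rev_index(n: int, j: int, which: int) -> int:
    """Reversed-flat index of atom `which` (0=N, 1=CA, 2=C) of 0-based residue j."""
    return 3 * (n - 1 - j) + (2 - which)


def _build_backward_flat(n: int, dih: np.ndarray, spec: AnchorSpec,
                         junction: dict[str, float]) -> np.ndarray:
    """Flat (3n, 3) array in reversed atom order (C, CA, N per residue, last first),
    grown C->N from the exact C-terminal anchors."""
    flat = np.zeros((3 * n, 3))
    for j, slot in ((n - 1, spec.n), (n - 2, spec.n - 1)):
        for which, name in enumerate(("N", "CA", "C")):
            flat[_rev_index(n, j, which)] = spec.positions[(slot, name)]
    # near-terminal torsions determined by the anchors themselves
    eff = dih.copy()
    eff[n - 2, 1] = junction["psi_nm1"]
    eff[n - 2, 2] = junction["omega_nm1"]
    eff[n - 1, 0] = junction["phi_n"]
    for k in range(6, 3 * n):
        j = n - 1 - k // 3
        which = k % 3
        if which == 0:  # C(j) via phi(j+1)
            flat[k] = geom.place_atom_nerf(flat[k - 3], flat[k - 2], flat[k - 1],
                                           geom.BOND_C_N, geom.ANGLE_C_N_CA, eff[j + 1, 0])
        elif which == 1:  # CA(j) via omega(j)
            flat[k] = geom.place_atom_nerf(flat[k - 3], flat[k - 2], flat[k - 1],
                                           geom.BOND_CA_C, geom.ANGLE_CA_C_N, eff[j, 2])
        else:  # N(j) via psi(j)
            flat[k] = geom.place_atom_nerf(flat[k - 3], flat[k - 2], flat[k - 1],
                                           geom.BOND_N_CA, geom.ANGLE_N_CA_C, eff[j, 1])
    return flat


def _free_bonds_forward(n: int) -> list[tuple[int, int, int]]:
    """(axis_a, axis_b, move_start) triples for free phi/psi rotations, N->C order."""
    bonds = []
    for j in range(2, n):
        bonds.append((3 * j, 3 * j + 1, 3 * j + 2))  # phi(j)
        if j <= n - 2:
            bonds.append((3 * j + 1, 3 * j + 2, 3 * j + 3))  # psi(j)
    return bonds


def _free_bonds_backward(n: int) -> list[tuple[int, int, int]]:
    # only bonds whose moving block lies entirely outside the seeded
    # C-terminal anchor residues (reversed-flat indices >= 6) are free
    bonds = []
    for j in range(n - 2, 1, -1):
        # phi(j) rotation moves the chain toward the N-terminus: the bond
        # N(j)-CA(j); in reversed order the moving block starts at C(j-1).
        a, b = _rev_index(n, j, 0), _rev_index(n, j, 1)
        start = _rev_index(n, j - 1, 2)
        bonds.append((b, a, start))
        if j <= n - 3:
            a, b = _rev_index(n, j, 1), _rev_index(n, j, 2)  # CA(j), C(j): psi(j)
            start = _rev_index(n, j, 0)  # moving block starts at N(j)
            bonds.append((b, a, start))
    return bonds


def _unit_axis(flat: np.ndarray, a_idx: int, b_idx: int) -> np.ndarray:
    axis = flat[b_idx] - flat[a_idx]
    return axis / math.sqrt(axis[0] ** 2 + axis[1] ** 2 + axis[2] ** 2)


def _cross_rows(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Row-wise u x v[i] for a single 3-vector u and an (k, 3) array v."""
    out = np.empty_like(v)
    out[:, 0] = u[1] * v[:, 2] - u[2] * v[:, 1]
    out[:, 1] = u[2] * v[:, 0] - u[0] * v[:, 2]
    out[:, 2] = u[0] * v[:, 1] - u[1] * v[:, 0]
    return out


def _rotate_block(flat: np.ndarray, a_idx: int, b_idx: int, start: int,
                  theta: float) -> None:
    """Rotate flat[start:] by theta about the a->b bond axis, in place."""
    axis = _unit_axis(flat, a_idx, b_idx)
    pivot = flat[b_idx]
    v = flat[start:] - pivot
    c, s = math.cos(theta), math.sin(theta)
    proj = v @ axis
    flat[start:] = pivot + c * v + s * _cross_rows(axis, v) \
        + np.outer((1.0 - c) * proj, axis)


def _target_err(flat: np.ndarray, target_idx: np.ndarray,
                target_pos: np.ndarray) -> float:
    d = flat[target_idx] - target_pos
    return float(np.sqrt(np.sum(d * d) / len(target_idx)))


def _gauss_newton(flat: np.ndarray, bonds: list[tuple[int, int, int]],
                  target_idx: np.ndarray, target_pos: np.ndarray,
                  inner_target: float, iters: int = 12) -> bool:
    """Joint small-rotation refinement of all free torsions (endgame polish)."""
    order = sorted(range(len(bonds)), key=lambda bi: bonds[bi][2])
    for _ in range(iters):
        if _target_err(flat, target_idx, target_pos) <= inner_target:
            return True
        resid = (target_pos - flat[target_idx]).ravel()
        jac = np.zeros((len(resid), len(bonds)))
        for bi, (a_idx, b_idx, start) in enumerate(bonds):
            axis = _unit_axis(flat, a_idx, b_idx)
            pivot = flat[b_idx]
            mask = target_idx >= start
            if not np.any(mask):
                continue
            arm = _cross_rows(axis, flat[target_idx[mask]] - pivot)
            jac[np.repeat(mask, 3), bi] = arm.ravel()
        dtheta, *_ = np.linalg.lstsq(jac, resid, rcond=None)
        np.clip(dtheta, -0.3, 0.3, out=dtheta)
        for bi in order:
            if dtheta[bi] != 0.0:
                a_idx, b_idx, start = bonds[bi]
                _rotate_block(flat, a_idx, b_idx, start, dtheta[bi])
    return _target_err(flat, target_idx, target_pos) <= inner_target


def _ccd(flat: np.ndarray, bonds: list[tuple[int, int, int]],
         target_idx: np.ndarray, target_pos: np.ndarray,
         cfg: ClosureConfig, rng: np.random.Generator,
         inner_target: float) -> tuple[bool, int]:
    """In-place randomized CCD sweeps with Gauss-Newton endgame polish."""
    err = _target_err(flat, target_idx, target_pos)
    if err <= inner_target:
        return True, 0
    order = np.arange(len(bonds))
    best = err
    stall = 0
    for sweep in range(1, cfg.max_ccd_sweeps + 1):
        rng.shuffle(order)
        for bi in order:
            a_idx, b_idx, start = bonds[bi]
            mask = target_idx >= start
            if not np.any(mask):
                continue
            axis = _unit_axis(flat, a_idx, b_idx)
            pivot = flat[b_idx]
            m = flat[target_idx[mask]] - pivot
            t = target_pos[mask] - pivot
            proj = m @ axis
            r_perp = m - np.outer(proj, axis)
            f = t - np.outer(proj, axis)
            s_cos = float(np.sum(f * r_perp))
            s_sin = float(np.sum(f * _cross_rows(axis, r_perp)))
            theta = math.atan2(s_sin, s_cos)
            if abs(theta) < 1e-12:
                continue
            _rotate_block(flat, a_idx, b_idx, start, theta)
        err = _target_err(flat, target_idx, target_pos)
        if err <= inner_target:
            return True, sweep
        if err < 0.6 and _gauss_newton(flat, bonds, target_idx, target_pos,
                                       inner_target):
            return True, sweep
        if err < best * 0.99:
            best = err
            stall = 0
        else:
            stall += 1
            if stall >= 12:  # converged to a non-closing local minimum
                break
    return False, cfg.max_ccd_sweeps


def _measure_table(bb: np.ndarray) -> np.ndarray:
    measured = geom.measure_backbone_dihedrals(bb)
    out = np.full((bb.shape[0], 3), np.nan)
    for i, (phi, psi, omega) in enumerate(measured):
        out[i] = [np.nan if v is None else v for v in (phi, psi, omega)]
    return out


def _finalize(sequence: str, bb: np.ndarray, spec: AnchorSpec,
              junction: dict[str, float]) -> BackboneConformation:
    """Regenerate from dihedrals via NeRF off the exact N-terminal anchors,
    attach carbonyl oxygens, and record the closure error."""
    n = len(sequence)
    dih = _measure_table(bb)
    dih[0, 1] = junction["psi1"]
    dih[0, 2] = junction["omega1"]
    dih[1, 0] = junction["phi2"]
    flat = _build_forward_flat(n, dih, spec)
    bb_final = flat.reshape(n, 3, 3)
    dih_final = _measure_table(bb_final)
    oxy = geom.place_carbonyl_oxygens(bb_final, last_o_dihedral=junction["o_n_dihedral"])
    oxy[0] = spec.positions[(1, "O")]
    oxy[1] = spec.positions[(2, "O")]
    coords = np.concatenate([bb_final, oxy[:, None, :]], axis=1)
    target = np.array([spec.positions[(s, a)]
                       for s in (n - 1, n) for a in ("N", "CA", "C")])
    built = np.array([bb_final[s - 1, k] for s in (n - 1, n) for k in range(3)])
    closure_error = geom.rmsd(built, target, fit=False)
    return BackboneConformation(sequence, dih_final, coords, closure_error)


def rcd_close(initial: BackboneConformation, spec: AnchorSpec, cfg: ClosureConfig,
              rng: np.random.Generator, direction: str = "forward") -> BackboneConformation | None:
    """Close the peptide backbone onto the anchor spec by randomized CCD.

    Returns the closed conformation, or None if the sweep budget is exhausted
    (anchors that are geometrically unreachable raise InfeasibleAnchorsError).
    """
    if direction not in ("forward", "backward"):
        raise ValueError("direction must be 'forward' or 'backward'")
    n = initial.n
    if n != spec.n:
        raise ValueError("conformation length does not match anchor spec")
    _check_feasible(spec)
    junction = _spec_junction_torsions(spec)
    dih = _full_torsion_table(n, initial.dihedrals, junction)

    if direction == "forward":
        flat = _build_forward_flat(n, dih, spec)
        bonds = _free_bonds_forward(n)
        target_idx = np.array([3 * j + k for j in (n - 2, n - 1) for k in range(3)])
        target_pos = np.array([spec.positions[(s, a)]
                               for s in (n - 1, n) for a in ("N", "CA", "C")])
        inner = cfg.closure_rmsd_target
    else:
        flat = _build_backward_flat(n, dih, spec, junction)
        bonds = _free_bonds_backward(n)
        target_idx = np.array([_rev_index(n, j, k) for j in (0, 1) for k in range(3)])
        target_pos = np.array([spec.positions[(s, a)]
                               for s in (1, 2) for a in ("N", "CA", "C")])
        # converge tighter: the forward regeneration re-anchors the N-terminus
        # exactly and re-expresses any residual at the C-terminal targets
        inner = cfg.closure_rmsd_target / 5.0
    # sort targets so boolean masking in the CCD inner loop lines up
    sort = np.argsort(target_idx)
    target_idx = target_idx[sort]
    target_pos = target_pos[sort]

    converged, _ = _ccd(flat, bonds, target_idx, target_pos, cfg, rng, inner)
    if not converged:
        return None
    if direction == "forward":
        bb = flat.reshape(n, 3, 3)
    else:
        bb = np.zeros((n, 3, 3))
        for j in range(n):
            for k in range(3):
                bb[j, k] = flat[_rev_index(n, j, k)]
    result = _finalize(initial.sequence, bb, spec, junction)
    if result.closure_error > cfg.closure_rmsd_target:
        return None
    return result


# ---------------------------------------------------------------------------
# steric screening
# ---------------------------------------------------------------------------

_BACKBONE_RADII = {"N": 1.8, "CA": 1.9, "C": 1.9, "O": 1.7}


def _receptor_heavy(receptor: Structure) -> tuple[np.ndarray, np.ndarray]:
    from .scoring import VDW_RADII_BY_ELEMENT

    coords, radii = [], []
    for a in receptor.atoms():
        r = VDW_RADII_BY_ELEMENT.get(a.element)
        if r is not None:
            coords.append(a.pos)
            radii.append(r)
    return np.array(coords).reshape(-1, 3), np.array(radii)


def _backbone_atoms_with_radii(b: BackboneConformation) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Coords, radii and bond-chain positions for N/CA/C/O backbone atoms."""
    n = b.n
    coords = b.coords.reshape(n * 4, 3)
    names = ["N", "CA", "C", "O"] * n
    radii = np.array([_BACKBONE_RADII[x] for x in names])
    # graph distance proxy: position along the N-CA-C chain; O hangs off C
    chain_pos = np.empty(n * 4)
    for j in range(n):
        chain_pos[4 * j + 0] = 3 * j
        chain_pos[4 * j + 1] = 3 * j + 1
        chain_pos[4 * j + 2] = 3 * j + 2
        chain_pos[4 * j + 3] = 3 * j + 2  # O: one bond off C
    is_oxygen = np.array([x == "O" for x in names])
    bond_extra = is_oxygen.astype(int)
    return coords, radii, chain_pos + 0.0, bond_extra


def backbone_clash(b: BackboneConformation, receptor: Structure,
                   clash_factor: float = 0.6) -> bool:
    """True iff the backbone clashes with the receptor or with itself.

    A clash is a heavy-atom pair closer than clash_factor * (r_i + r_j);
    self-pairs are only checked when at least 4 bonds apart.
    """
    pep_coords, pep_radii, chain_pos, bond_extra = _backbone_atoms_with_radii(b)
    rec_coords, rec_radii = _receptor_heavy(receptor)
    if rec_coords.size:
        tree = cKDTree(rec_coords)
        max_thr = clash_factor * (pep_radii.max() + rec_radii.max())
        for i, p in enumerate(pep_coords):
            for j in tree.query_ball_point(p, max_thr):
                if np.linalg.norm(p - rec_coords[j]) < clash_factor * (pep_radii[i] + rec_radii[j]):
                    return True
    # self clash, pairs >= 4 bonds apart
    m = len(pep_coords)
    for i in range(m):
        for j in range(i + 1, m):
            sep = abs(chain_pos[i] - chain_pos[j]) + bond_extra[i] + bond_extra[j]
            if sep < 4:
                continue
            if np.linalg.norm(pep_coords[i] - pep_coords[j]) < clash_factor * (
                    pep_radii[i] + pep_radii[j]):
                return True
    return False


# ---------------------------------------------------------------------------
# top-level sampler
# ---------------------------------------------------------------------------

def _initial_conformation(sequence: str, rng: np.random.Generator) -> BackboneConformation:
    from .structure import ONE_TO_THREE

    n = len(sequence)
    dih = np.zeros((n, 3))
    for i, aa in enumerate(sequence):
        phi, psi = sample_ramachandran(ONE_TO_THREE[aa], rng)
        dih[i] = [phi, psi, 180.0]
    coords = np.zeros((n, 4, 3))  # placeholder; rcd_close rebuilds on the spec
    return BackboneConformation(sequence, dih, coords)


def _anchor_atom_deviation(b: BackboneConformation, spec: AnchorSpec) -> float:
    """Max distance of any anchor-residue backbone atom from its spec position."""
    worst = 0.0
    for slot in spec.slots():
        for k, name in enumerate(("N", "CA", "C", "O")):
            d = float(np.linalg.norm(b.coords[slot - 1, k] - spec.positions[(slot, name)]))
            worst = max(worst, d)
    return worst


def sample_backbones(sequence: str, spec: AnchorSpec, receptor: Structure,
                     cfg: ClosureConfig) -> list[BackboneConformation]:
    """Up to cfg.n_samples closed, anchor-respecting, clash-free backbones.

    Deterministic given cfg.rng_seed; each sample draws from its own seeded
    stream so results do not depend on evaluation order.
    """
    if len(sequence) != spec.n:
        raise ValueError(f"sequence length {len(sequence)} != anchor spec length {spec.n}")
    _check_feasible(spec)
    out: list[BackboneConformation] = []
    for sample_idx in range(cfg.n_samples):
        rng = np.random.default_rng([cfg.rng_seed, sample_idx])
        for restart in range(cfg.max_restarts_per_sample):
            direction = "forward" if restart % 2 == 0 else "backward"
            initial = _initial_conformation(sequence, rng)
            closed = rcd_close(initial, spec, cfg, rng, direction=direction)
            if closed is None:
                continue
            if _anchor_atom_deviation(closed, spec) > cfg.anchor_tolerance:
                continue
            if backbone_clash(closed, receptor, cfg.clash_factor):
                continue
            out.append(closed)
            break
    return out
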