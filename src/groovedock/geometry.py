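"""Rigid superposition, RMSD, dihedral measurement and NeRF chain building.

Conventions: coordinates in Angstrom; angles exposed in degrees on the
half-open interval [-180, 180); rotations are proper (reflections excluded).
Ideal backbone covalent geometry uses Engh-Huber values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Transform",
    "DegenerateGeometryError",
    "superpose",
    "rmsd",
    "dihedral_angle",
    "place_atom_nerf",
    "triad_frame",
    "measure_backbone_dihedrals",
    "build_backbone",
    "wrap_angle",
    "BOND_N_CA",
    "BOND_CA_C",
    "BOND_C_N",
    "BOND_C_O",
    "ANGLE_N_CA_C",
    "ANGLE_CA_C_N",
    "ANGLE_C_N_CA",
    "ANGLE_CA_C_O",
]

# Engh-Huber ideal backbone geometry (Angstrom / degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.6
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8


class DegenerateGeometryError(ValueError):
    """Input geometry does not determine the requested quantity."""


def wrap_angle(deg: float) -> float:
    """Wrap an angle in degrees to [-180, 180)."""
    return (deg + 180.0) % 360.0 - 180.0


@dataclass
class Transform:
    """Proper rigid-body transform: x -> rotation @ x + translation."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-6:
            raise ValueError("rotation must be proper (det = +1)")
        if np.max(np.abs(self.rotation.T @ self.rotation - np.eye(3))) > 1e-6:
            raise ValueError("rotation must be orthonormal")

    @classmethod
    def identity(cls) -> "Transform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "Transform") -> "Transform":
        """self after other: (self.compose(other)).apply(x) == self.apply(other.apply(x))."""
        return Transform(self.rotation @ other.rotation,
                         self.rotation @ other.translation + self.translation)

    def inverse(self) -> "Transform":
        rt = self.rotation.T
        return Transform(rt, -rt @ self.translation)


def superpose(fixed: np.ndarray, mobile: np.ndarray) -> tuple[Transform, float]:
    """Least-squares optimal proper rigid transform mapping mobile onto fixed (Kabsch).

    Returns the transform and the post-fit RMSD in Angstrom.
    """
    fixed = np.asarray(fixed, dtype=float)
    mobile = np.asarray(mobile, dtype=float)
    if fixed.shape != mobile.shape or fixed.ndim != 2 or fixed.shape[1] != 3:
        raise ValueError("point sets must both be N x 3")
    n = fixed.shape[0]
    if n < 3:
        raise DegenerateGeometryError("superposition requires at least 3 points")
    cf = fixed.mean(axis=0)
    cm = mobile.mean(axis=0)
    x = fixed - cf
    y = mobile - cm
    if np.linalg.matrix_rank(x, tol=1e-8) < 2 or np.linalg.matrix_rank(y, tol=1e-8) < 2:
        raise DegenerateGeometryError("collinear point set: rotation not determined")
    h = y.T @ x
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = cf - rot @ cm
    fitted = mobile @ rot.T + trans
    value = float(np.sqrt(np.mean(np.sum((fitted - fixed) ** 2, axis=1))))
    return Transform(rot, trans), value


def rmsd(a: np.ndarray, b: np.ndarray, fit: bool = False) -> float:
    """Root-mean-square deviation between matched point sets.

    With fit=True the deviation is measured after optimal superposition.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"point counts differ: {a.shape} vs {b.shape}")
    if fit:
        return superpose(a, b)[1]
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def dihedral_angle(p1, p2, p3, p4) -> float:
    """Signed torsion about p2-p3 in degrees, IUPAC convention, in [-180, 180)."""
    # scalar math: hot path for chain measurement and sidechain placement
    b1x, b1y, b1z = p2[0] - p1[0], p2[1] - p1[1], p2[2] - p1[2]
    b2x, b2y, b2z = p3[0] - p2[0], p3[1] - p2[1], p3[2] - p2[2]
    b3x, b3y, b3z = p4[0] - p3[0], p4[1] - p3[1], p4[2] - p3[2]
    n1x = b1y * b2z - b1z * b2y
    n1y = b1z * b2x - b1x * b2z
    n1z = b1x * b2y - b1y * b2x
    n2x = b2y * b3z - b2z * b3y
    n2y = b2z * b3x - b2x * b3z
    n2z = b2x * b3y - b2y * b3x
    b2n = math.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
    if b2n < 1e-9:
        raise DegenerateGeometryError("p2 and p3 coincide")
    if (n1x * n1x + n1y * n1y + n1z * n1z) < 1e-18 or \
       (n2x * n2x + n2y * n2y + n2z * n2z) < 1e-18:
        raise DegenerateGeometryError("collinear points: torsion undefined")
    x = n1x * n2x + n1y * n2y + n1z * n2z
    cx = n1y * n2z - n1z * n2y
    cy = n1z * n2x - n1x * n2z
    cz = n1x * n2y - n1y * n2x
    y = (cx * b2x + cy * b2y + cz * b2z) / b2n
    return wrap_angle(math.degrees(math.atan2(y, x)))


def place_atom_nerf(a, b, c, bond_length: float, bond_angle: float, dihedral: float) -> np.ndarray:
    """Place atom d from reference triad (a, b, c) and internal coordinates.

    |d-c| = bond_length, angle(b,c,d) = bond_angle (deg),
    dihedral(a,b,c,d) = dihedral (deg).
    """
    # scalar math throughout: this sits in the innermost chain-building loops
    if bond_length <= 0 or not (0.0 < bond_angle < 180.0):
        raise ValueError("bond_length must be > 0 and bond_angle in (0, 180)")
    ax, ay, az = float(a[0]), float(a[1]), float(a[2])
    bx, by, bz = float(b[0]), float(b[1]), float(b[2])
    cx, cy, cz = float(c[0]), float(c[1]), float(c[2])
    bcx, bcy, bcz = cx - bx, cy - by, cz - bz
    abx, aby, abz = bx - ax, by - ay, bz - az
    nx = aby * bcz - abz * bcy
    ny = abz * bcx - abx * bcz
    nz = abx * bcy - aby * bcx
    bc_n = math.sqrt(bcx * bcx + bcy * bcy + bcz * bcz)
    n_n = math.sqrt(nx * nx + ny * ny + nz * nz)
    if bc_n < 1e-9 or n_n < 1e-9:
        raise DegenerateGeometryError("collinear reference triad")
    ux, uy, uz = bcx / bc_n, bcy / bc_n, bcz / bc_n
    nx, ny, nz = nx / n_n, ny / n_n, nz / n_n
    mx = ny * uz - nz * uy
    my = nz * ux - nx * uz
    mz = nx * uy - ny * ux
    ang = math.radians(bond_angle)
    tor = math.radians(dihedral)
    d1 = -bond_length * math.cos(ang)
    d2 = bond_length * math.sin(ang) * math.cos(tor)
    d3 = bond_length * math.sin(ang) * math.sin(tor)
    return np.array([
        cx + ux * d1 + mx * d2 + nx * d3,
        cy + uy * d1 + my * d2 + ny * d3,
        cz + uz * d1 + mz * d2 + nz * d3,
    ])


def triad_frame(n, ca, c) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal frame attached to a backbone N/CA/C triad.

    Returns (origin, E) with origin at CA and E the 3x3 matrix whose columns
    are the frame axes. Used to attach rigid template geometry to a residue.
    """
    e1x, e1y, e1z = n[0] - ca[0], n[1] - ca[1], n[2] - ca[2]
    vx, vy, vz = c[0] - ca[0], c[1] - ca[1], c[2] - ca[2]
    e3x = e1y * vz - e1z * vy
    e3y = e1z * vx - e1x * vz
    e3z = e1x * vy - e1y * vx
    norm1 = math.sqrt(e1x * e1x + e1y * e1y + e1z * e1z)
    norm3 = math.sqrt(e3x * e3x + e3y * e3y + e3z * e3z)
    if norm1 < 1e-9 or norm3 < 1e-9:
        raise DegenerateGeometryError("degenerate backbone triad")
    e1x, e1y, e1z = e1x / norm1, e1y / norm1, e1z / norm1
    e3x, e3y, e3z = e3x / norm3, e3y / norm3, e3z / norm3
    e2x = e3y * e1z - e3z * e1y
    e2y = e3z * e1x - e3x * e1z
    e2z = e3x * e1y - e3y * e1x
    origin = np.array([float(ca[0]), float(ca[1]), float(ca[2])])
    return origin, np.array([[e1x, e2x, e3x],
                             [e1y, e2y, e3y],
                             [e1z, e2z, e3z]])


def measure_backbone_dihedrals(backbone: np.ndarray) -> list[tuple[float | None, float | None, float | None]]:
    """Per-residue (phi, psi, omega) from an (n, 3, 3) array of N/CA/C coordinates.

    phi(i) = C(i-1)-N(i)-CA(i)-C(i); psi(i) = N(i)-CA(i)-C(i)-N(i+1);
    omega(i) = CA(i)-C(i)-N(i+1)-CA(i+1). Undefined terminal entries are None.
    """
    bb = np.asarray(backbone, dtype=float)
    if bb.ndim != 3 or bb.shape[1:] != (3, 3):
        raise ValueError("backbone must have shape (n_residues, 3, 3) for N, CA, C")
    if not np.all(np.isfinite(bb)):
        raise ValueError("backbone contains non-finite coordinates")
    n = bb.shape[0]
    out: list[tuple[float | None, float | None, float | None]] = []
    for i in range(n):
        phi = psi = omega = None
        if i > 0:
            phi = dihedral_angle(bb[i - 1, 2], bb[i, 0], bb[i, 1], bb[i, 2])
        if i < n - 1:
            psi = dihedral_angle(bb[i, 0], bb[i, 1], bb[i, 2], bb[i + 1, 0])
            omega = dihedral_angle(bb[i, 1], bb[i, 2], bb[i + 1, 0], bb[i + 1, 1])
        out.append((phi, psi, omega))
    return out


def build_backbone(
    dihedrals: np.ndarray,
    seed_coords: np.ndarray | None = None,
) -> np.ndarray:
    """Build N/CA/C backbone Cartesian coordinates from per-residue dihedrals (NeRF).

    dihedrals: (n, 3) array of (phi, psi, omega) in degrees. phi of residue 1
    and psi/omega of residue n are ignored (may be nan). seed_coords: (3, 3)
    N/CA/C of residue 1; defaults to a canonical placement at the origin.
    Returns an (n, 3, 3) array.
    """
    dih = np.asarray(dihedrals, dtype=float)
    if dih.ndim != 2 or dih.shape[1] != 3:
        raise ValueError("dihedrals must be (n, 3)")
    n = dih.shape[0]
    bb = np.zeros((n, 3, 3))
    if seed_coords is None:
        bb[0, 0] = np.array([0.0, 0.0, 0.0])
        bb[0, 1] = np.array([BOND_N_CA, 0.0, 0.0])
        ang = math.radians(ANGLE_N_CA_C)
        bb[0, 2] = bb[0, 1] + BOND_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    else:
        sc = np.asarray(seed_coords, dtype=float)
        if sc.shape != (3, 3):
            raise ValueError("seed_coords must be (3, 3)")
        bb[0] = sc
    for i in range(n - 1):
        psi, omega = dih[i, 1], dih[i, 2]
        phi_next = dih[i + 1, 0]
        bb[i + 1, 0] = place_atom_nerf(bb[i, 0], bb[i, 1], bb[i, 2],
                                       BOND_C_N, ANGLE_CA_C_N, psi)
        bb[i + 1, 1] = place_atom_nerf(bb[i, 1], bb[i, 2], bb[i + 1, 0],
                                       BOND_N_CA, ANGLE_C_N_CA, omega)
        bb[i + 1, 2] = place_atom_nerf(bb[i, 2], bb[i + 1, 0], bb[i + 1, 1],
                                       BOND_CA_C, ANGLE_N_CA_C, phi_next)
    return bb


def place_carbonyl_oxygens(backbone: np.ndarray, last_o_dihedral: float = 0.0,
                           psis: np.ndarray | None = None) -> np.ndarray:
    """Place O atoms in the peptide plane: dihedral N-CA-C-O = psi + 180.

    backbone: (n, 3, 3) N/CA/C. For the final residue (psi undefined) the
    N-CA-C-O dihedral is last_o_dihedral. psis, if given, supplies the psi
    angles (degrees) instead of re-measuring them. Returns (n, 3) O coords.
    """
    bb = np.asarray(backbone, dtype=float)
    n = bb.shape[0]
    oxy = np.zeros((n, 3))
    for i in range(n):
        if i < n - 1:
            psi = psis[i] if psis is not None else dihedral_angle(
                bb[i, 0], bb[i, 1], bb[i, 2], bb[i + 1, 0])
            tor = wrap_angle(psi + 180.0)
        else:
            tor = last_o_dihedral
        oxy[i] = place_atom_nerf(bb[i, 0], bb[i, 1], bb[i, 2], BOND_C_O, ANGLE_CA_C_O, tor)
    return oxy
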