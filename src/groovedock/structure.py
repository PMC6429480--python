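"""Hierarchical molecular data model and PDB reading/writing.

The model is deliberately small: Atom/Residue/Chain/Structure with Cartesian
coordinates in Angstrom. The whole pipeline is heavy-atom only, so hydrogens
are discarded on read; waters and non-peptide HETATM records are dropped
(selenomethionine is read as methionine). Residue indices exposed to
algorithms are 1-based chain ordinals; author numbering is retained only for
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "Structure",
    "PDBParseError",
    "EmptyStructureError",
    "PDBFormatError",
    "UnknownResidueError",
    "read_pdb",
    "write_pdb",
    "chain_sequence",
    "THREE_TO_ONE",
    "ONE_TO_THREE",
]


class PDBParseError(ValueError):
    """Malformed PDB text."""


class EmptyStructureError(PDBParseError):
    """Input contained no usable ATOM/HETATM records."""


class PDBFormatError(ValueError):
    """Structure cannot be represented in fixed-column PDB format."""


class UnknownResidueError(KeyError):
    """A residue is not one of the 20 standard amino acids."""


THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

_WATER_NAMES = {"HOH", "WAT", "DOD"}


@dataclass
class Atom:
    name: str
    element: str
    pos: np.ndarray
    residue_index: int = 0
    alt_loc: str = ""

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=float)
        if self.pos.shape != (3,):
            raise ValueError(f"atom position must be a 3-vector, got {self.pos.shape}")
        if not np.all(np.isfinite(self.pos)):
            raise ValueError(f"non-finite coordinates for atom {self.name!r}")
        if not self.element:
            raise ValueError(f"empty element for atom {self.name!r}")


@dataclass
class Residue:
    name: str
    seq_id: int
    atoms: list[Atom] = field(default_factory=list)
    insertion_code: str = ""

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def has_atoms(self, *names: str) -> bool:
        return all(self.atom(n) is not None for n in names)

    def backbone_coords(self, names: tuple[str, ...] = ("N", "CA", "C")) -> np.ndarray:
        coords = []
        for n in names:
            a = self.atom(n)
            if a is None:
                raise KeyError(f"residue {self.name} {self.seq_id} missing backbone atom {n}")
            coords.append(a.pos)
        return np.array(coords)


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)

    def atoms(self):
        for r in self.residues:
            yield from r.atoms

    def coords(self, atom_name: str | None = None) -> np.ndarray:
        pts = [a.pos for a in self.atoms() if atom_name is None or a.name == atom_name]
        return np.array(pts).reshape(-1, 3)


@dataclass
class Structure:
    chains: list[Chain] = field(default_factory=list)
    label: str = ""

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r} in structure {self.label!r}")

    def atoms(self):
        for c in self.chains:
            yield from c.atoms()

    def coords(self) -> np.ndarray:
        return np.array([a.pos for a in self.atoms()]).reshape(-1, 3)

    def n_atoms(self) -> int:
        return sum(1 for _ in self.atoms())

    def copy(self) -> "Structure":
        return Structure(
            chains=[
                Chain(
                    id=c.id,
                    residues=[
                        Residue(
                            name=r.name,
                            seq_id=r.seq_id,
                            insertion_code=r.insertion_code,
                            atoms=[
                                Atom(a.name, a.element, a.pos.copy(), a.residue_index, a.alt_loc)
                                for a in r.atoms
                            ],
                        )
                        for r in c.residues
                    ],
                )
                for c in self.chains
            ],
            label=self.label,
        )


def _guess_element(atom_name: str) -> str:
    stripped = atom_name.strip()
    if not stripped:
        return ""
    # two-letter elements in proteins are rare; digits lead for some H names
    head = stripped.lstrip("0123456789")
    if head[:2] in ("SE", "FE", "ZN", "MG", "CL", "BR", "NA", "CA") and len(stripped) > 3:
        return head[:2]
    return head[:1]


def read_pdb(text: str, label: str = "") -> Structure:
    """Parse PDB-format text into a :class:`Structure`.

    First alternate location kept per atom; hydrogens, waters and non-peptide
    HETATM records dropped (MSE read as MET); first MODEL only.
    """
    chains: list[Chain] = []
    chain_by_id: dict[str, Chain] = {}
    current_res_key = None
    current_res: Residue | None = None
    seen_any = False
    in_first_model = True

    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6]
        if rec.startswith("ENDMDL"):
            in_first_model = False
            continue
        if not in_first_model:
            continue
        if not (rec.startswith("ATOM") or rec.startswith("HETATM")):
            continue
        if len(line) < 54:
            raise PDBParseError(f"line {lineno}: truncated coordinate record")
        res_name = line[17:20].strip()
        is_het = rec.startswith("HETATM")
        if res_name in _WATER_NAMES:
            continue
        if is_het and res_name != "MSE":
            continue
        atom_name = line[12:16].strip()
        alt_loc = line[16].strip()
        chain_id = line[21]
        try:
            seq_id = int(line[22:26])
        except ValueError as exc:
            raise PDBParseError(f"line {lineno}: bad residue number {line[22:26]!r}") from exc
        icode = line[26].strip()
        try:
            pos = np.array([float(line[30:38]), float(line[38:46]), float(line[46:54])])
        except ValueError as exc:
            raise PDBParseError(f"line {lineno}: malformed coordinates") from exc
        element = line[76:78].strip() if len(line) >= 78 else ""
        if not element:
            element = _guess_element(atom_name)
        if element in ("H", "D"):
            continue
        if res_name == "MSE":
            res_name = "MET"
            if atom_name == "SE":
                atom_name, element = "SD", "S"

        if chain_id not in chain_by_id:
            chain_by_id[chain_id] = Chain(id=chain_id)
            chains.append(chain_by_id[chain_id])
        chain = chain_by_id[chain_id]

        res_key = (chain_id, seq_id, icode)
        if res_key != current_res_key:
            current_res = None
            for r in chain.residues:
                if r.seq_id == seq_id and r.insertion_code == icode:
                    current_res = r
                    break
            if current_res is None:
                current_res = Residue(name=res_name, seq_id=seq_id, insertion_code=icode)
                chain.residues.append(current_res)
            current_res_key = res_key

        assert current_res is not None
        if current_res.atom(atom_name) is not None:
            continue  # first alt-loc (or duplicate) wins
        current_res.atoms.append(
            Atom(name=atom_name, element=element, pos=pos, alt_loc=alt_loc)
        )
        seen_any = True

    if not seen_any:
        raise EmptyStructureError("no ATOM/HETATM records found")

    for chain in chains:
        for i, res in enumerate(chain.residues, start=1):
            for a in res.atoms:
                a.residue_index = i
    return Structure(chains=chains, label=label)


def _format_atom_name(name: str, element: str) -> str:
    # PDB column rule: single-letter elements start in column 14
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1:
        return f" {name:<3s}"
    return f"{name:<4s}"


def write_pdb(s: Structure) -> str:
    """Serialize to fixed-column PDB text (ATOM/TER/END)."""
    lines: list[str] = []
    serial = 0
    for chain in s.chains:
        for res in chain.residues:
            for a in res.atoms:
                if np.max(np.abs(a.pos)) >= 10000.0:
                    raise PDBFormatError(
                        f"coordinate magnitude >= 10000 A for atom {a.name} "
                        f"in {res.name} {res.seq_id}"
                    )
                serial += 1
                lines.append(
                    "ATOM  {serial:>5d} {name} {res:<3s} {chain}{seq:>4d}{icode}"
                    "   {x:>8.3f}{y:>8.3f}{z:>8.3f}{occ:>6.2f}{b:>6.2f}"
                    "          {elem:>2s}".format(
                        serial=min(serial, 99999),
                        name=_format_atom_name(a.name, a.element),
                        res=res.name,
                        chain=chain.id,
                        seq=res.seq_id,
                        icode=res.insertion_code or " ",
                        x=a.pos[0], y=a.pos[1], z=a.pos[2],
                        occ=1.00, b=0.00,
                        elem=a.element[:2],
                    )
                )
        if chain.residues:
            last = chain.residues[-1]
            serial += 1
            lines.append(
                "TER   {serial:>5d}      {res:<3s} {chain}{seq:>4d}".format(
                    serial=min(serial, 99999), res=last.name, chain=chain.id, seq=last.seq_id
                )
            )
    lines.append("END")
    return "\n".join(lines) + "\n"


def chain_sequence(chain: Chain) -> str:
    """One-letter sequence of a chain of standard amino acids."""
    out = []
    for res in chain.residues:
        try:
            out.append(THREE_TO_ONE[res.name])
        except KeyError:
            raise UnknownResidueError(
                f"non-standard residue {res.name!r} at position {res.seq_id}"
            ) from None
    return "".join(out)
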