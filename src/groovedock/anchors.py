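"""Template selection, groove superposition and anchor transfer.

A bound peptide's terminal residues sit in conserved pockets of the MHC
class I groove, so their backbone coordinates can be borrowed from a solved
complex with a peptide of the same length: the template receptor is
superposed onto the input receptor over the groove (heavy-chain alpha1/alpha2
region), and the backbone atoms (N, CA, C, O) of the template peptide's first
two and last two residues are carried through that transform. Poses whose
anchors have left the pockets after unconstrained minimization are rejected
by a CA-deviation filter.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .geometry import Transform, superpose
from .structure import Chain, Structure, read_pdb

__all__ = [
    "ANCHOR_ATOMS",
    "DEFAULT_TEMPLATE_CODES",
    "TemplateEntry",
    "AnchorSpec",
    "TemplateRegistry",
    "TemplateConfigurationError",
    "TemplateIntegrityError",
    "InsufficientOverlapError",
    "default_template_registry",
    "load_template_manifest",
    "groove_superpose",
    "extract_anchor_spec",
    "anchor_spec_from_peptide",
    "anchor_deviation",
    "passes_anchor_filter",
]

ANCHOR_ATOMS = ("N", "CA", "C", "O")

#: Curated default templates per peptide length (solved pMHC structures).
DEFAULT_TEMPLATE_CODES = {8: "2VAA", 9: "1DUZ", 10: "1I4F", 11: "2NW3"}

#: Heavy-chain residue ordinals forming the peptide-binding groove
#: (alpha1 + alpha2 domains).
GROOVE_ORDINAL_RANGE = (1, 180)

DEFAULT_ANCHOR_FILTER_THRESHOLD = 2.0  # Angstrom, max CA deviation over slots


class TemplateConfigurationError(RuntimeError):
    """A requested template is not available."""


class TemplateIntegrityError(ValueError):
    """A template structure is missing required atoms."""


class InsufficientOverlapError(ValueError):
    """Too few matched groove CA pairs for a superposition."""


@dataclass
class TemplateEntry:
    """A solved receptor + bound peptide used for anchor placement."""

    peptide_length: int
    structure: Structure
    peptide_chain_id: str
    source_id: str

    def __post_init__(self) -> None:
        pep = self.structure.chain(self.peptide_chain_id)
        if len(pep) != self.peptide_length:
            raise TemplateIntegrityError(
                f"template {self.source_id}: peptide chain {self.peptide_chain_id!r} "
                f"has {len(pep)} residues, expected {self.peptide_length}"
            )
        if len(self.receptor_chain()) < 150:
            raise TemplateIntegrityError(
                f"template {self.source_id}: receptor chain has fewer than 150 residues"
            )

    def peptide_chain(self) -> Chain:
        return self.structure.chain(self.peptide_chain_id)

    def receptor_chain(self) -> Chain:
        for c in self.structure.chains:
            if c.id != self.peptide_chain_id:
                return c
        raise TemplateIntegrityError(f"template {self.source_id}: no receptor chain")


@dataclass
class AnchorSpec:
    """Target backbone positions for the peptide's terminal residues.

    positions maps (slot, atom name) -> 3-vector in the receptor frame, where
    slot is the 1-based peptide residue ordinal in {1, 2, n-1, n}.
    """

    n: int
    positions: dict[tuple[int, str], np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        expected = {(s, a) for s in self.slots() for a in ANCHOR_ATOMS}
        if set(self.positions) != expected:
            raise ValueError(
                f"anchor spec must hold exactly the 16 backbone positions of "
                f"residues {sorted(self.slots())}"
            )
        self.positions = {k: np.asarray(v, dtype=float) for k, v in self.positions.items()}
        for pair in ((1, 2), (self.n - 1, self.n)):
            d = float(np.linalg.norm(self.positions[(pair[0], "CA")] - self.positions[(pair[1], "CA")]))
            if not (2.8 <= d <= 4.3):
                raise ValueError(
                    f"consecutive anchor CA-CA distance {d:.2f} A for residues "
                    f"{pair} outside [2.8, 4.3]"
                )

    def slots(self) -> tuple[int, int, int, int]:
        return (1, 2, self.n - 1, self.n)

    def slot_coords(self, slot: int, atoms: tuple[str, ...] = ANCHOR_ATOMS) -> np.ndarray:
        return np.array([self.positions[(slot, a)] for a in atoms])

    def transformed(self, t: Transform) -> "AnchorSpec":
        return AnchorSpec(self.n, {k: t.apply(v) for k, v in self.positions.items()})


class TemplateRegistry:
    """Maps peptide length to a template, loading structures lazily.

    Entries may be concrete :class:`TemplateEntry` objects (fixture mode) or
    (source_id, path, peptide_chain_id) descriptors resolved on first access.
    """

    def __init__(self) -> None:
        self._entries: dict[int, TemplateEntry] = {}
        self._pending: dict[int, tuple[str, str, str]] = {}

    def add_entry(self, entry: TemplateEntry) -> None:
        self._entries[entry.peptide_length] = entry

    def add_file(self, length: int, source_id: str, path: str, peptide_chain_id: str) -> None:
        self._pending[length] = (source_id, path, peptide_chain_id)

    def __contains__(self, length: int) -> bool:
        return length in self._entries or length in self._pending

    def lengths(self) -> list[int]:
        return sorted(set(self._entries) | set(self._pending))

    def source_id(self, length: int) -> str:
        if length in self._entries:
            return self._entries[length].source_id
        if length in self._pending:
            return self._pending[length][0]
        raise TemplateConfigurationError(
            f"no template registered for {length}-mers; supply a custom template"
        )

    def __getitem__(self, length: int) -> TemplateEntry:
        if length in self._entries:
            return self._entries[length]
        if length in self._pending:
            source_id, path, chain_id = self._pending[length]
            if not os.path.exists(path):
                raise TemplateConfigurationError(
                    f"template file for {length}-mers not found: expected "
                    f"{source_id} at {path}"
                )
            with open(path) as fh:
                structure = read_pdb(fh.read(), label=source_id)
            entry = TemplateEntry(length, structure, chain_id, source_id)
            self._entries[length] = entry
            return entry
        raise TemplateConfigurationError(
            f"no template registered for {length}-mers; supply a custom template"
        )


def default_template_registry(template_dir: str | None = None,
                              peptide_chain_id: str = "C") -> TemplateRegistry:
    """Registry of the curated default templates for 8- to 11-mers.

    Structures are loaded from ``template_dir/<CODE>.pdb`` on first access;
    lengths 12-15 have no default and require a user template.
    """
    reg = TemplateRegistry()
    base = template_dir or os.environ.get("GROOVEDOCK_TEMPLATE_DIR", "templates")
    for length, code in DEFAULT_TEMPLATE_CODES.items():
        reg.add_file(length, code, os.path.join(base, f"{code}.pdb"), peptide_chain_id)
    return reg


def load_template_manifest(path: str) -> TemplateRegistry:
    """Build a registry from a plain-text manifest: ``length  path  chain_id`` per line."""
    reg = TemplateRegistry()
    base = os.path.dirname(os.path.abspath(path))
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise TemplateConfigurationError(
                    f"{path}:{lineno}: expected 'length path chain_id', got {line!r}"
                )
            length = int(parts[0])
            tpl_path = parts[1]
            if not os.path.isabs(tpl_path):
                tpl_path = os.path.join(base, tpl_path)
            reg.add_file(length, os.path.splitext(os.path.basename(tpl_path))[0],
                         tpl_path, parts[2])
    return reg


def _groove_ca_coords(chain: Chain, n_residues: int) -> list[np.ndarray | None]:
    out: list[np.ndarray | None] = []
    for res in chain.residues[:n_residues]:
        a = res.atom("CA")
        out.append(None if a is None else a.pos)
    return out


def groove_superpose(receptor: Structure, template: TemplateEntry) -> Transform:
    """Transform mapping the template into the receptor frame.

    CA atoms of the groove region (heavy-chain residue ordinals 1-180) are
    paired by ordinal position after trimming to the shorter chain.
    """
    rec_chain = receptor.chains[0]
    tpl_chain = template.receptor_chain()
    lo, hi = GROOVE_ORDINAL_RANGE
    n = min(len(rec_chain), len(tpl_chain), hi)
    rec_cas = _groove_ca_coords(rec_chain, n)
    tpl_cas = _groove_ca_coords(tpl_chain, n)
    fixed, mobile = [], []
    for r, t in zip(rec_cas, tpl_cas):
        if r is not None and t is not None:
            fixed.append(r)
            mobile.append(t)
    if len(fixed) < 50:
        raise InsufficientOverlapError(
            f"only {len(fixed)} matched groove CA pairs (need >= 50)"
        )
    transform, _ = superpose(np.array(fixed), np.array(mobile))
    return transform


def extract_anchor_spec(template: TemplateEntry, t: Transform, n: int) -> AnchorSpec:
    """Anchor positions: template peptide terminal backbone atoms mapped through t."""
    if n != template.peptide_length:
        raise ValueError(
            f"peptide length {n} does not match template peptide length "
            f"{template.peptide_length}"
        )
    pep = template.peptide_chain()
    positions: dict[tuple[int, str], np.ndarray] = {}
    for slot in (1, 2, n - 1, n):
        res = pep.residues[slot - 1]
        for atom_name in ANCHOR_ATOMS:
            a = res.atom(atom_name)
            if a is None:
                raise TemplateIntegrityError(
                    f"template {template.source_id}: peptide residue {slot} "
                    f"missing backbone atom {atom_name}"
                )
            positions[(slot, atom_name)] = t.apply(a.pos)
    return AnchorSpec(n, positions)


def anchor_spec_from_peptide(peptide: Structure | Chain) -> AnchorSpec:
    """Anchor spec implied by a peptide's own terminal backbone atoms."""
    chain = peptide.chains[0] if isinstance(peptide, Structure) else peptide
    n = len(chain)
    positions: dict[tuple[int, str], np.ndarray] = {}
    for slot in (1, 2, n - 1, n):
        res = chain.residues[slot - 1]
        for atom_name in ANCHOR_ATOMS:
            a = res.atom(atom_name)
            if a is None:
                raise TemplateIntegrityError(
                    f"peptide residue {slot} missing backbone atom {atom_name}"
                )
            positions[(slot, atom_name)] = a.pos.copy()
    return AnchorSpec(n, positions)


def anchor_deviation(pose_peptide: Structure | Chain, spec: AnchorSpec) -> dict[int, float]:
    """Euclidean CA deviation from the spec for slots 1, 2, n-1, n."""
    chain = pose_peptide.chains[0] if isinstance(pose_peptide, Structure) else pose_peptide
    if len(chain) != spec.n:
        raise ValueError(
            f"pose peptide has {len(chain)} residues, spec expects {spec.n}"
        )
    out: dict[int, float] = {}
    for slot in spec.slots():
        ca = chain.residues[slot - 1].atom("CA")
        if ca is None:
            raise ValueError(f"pose peptide residue {slot} has no CA atom")
        out[slot] = float(np.linalg.norm(ca.pos - spec.positions[(slot, "CA")]))
    return out


def passes_anchor_filter(pose_peptide: Structure | Chain, spec: AnchorSpec,
                         threshold: float = DEFAULT_ANCHOR_FILTER_THRESHOLD) -> bool:
    """True iff the largest slot CA deviation does not exceed threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return max(anchor_deviation(pose_peptide, spec).values()) <= threshold
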