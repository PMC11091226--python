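"""MFCC fragmentation: capped tripeptides, caps-only systems, link hydrogens.

The protein is conceptually split at the backbone amide C(=O)-N bonds.  For
each residue R_i the scheme builds four systems:

* ``BID_CRC`` — ligand + caps + residue (C_{i-1} R_i C_{i+1} plus binder)
* ``CRC``     — caps + residue alone
* ``BID_CC``  — ligand + caps with R_i removed
* ``CC``      — caps alone

Every cut bond is saturated by a link hydrogen placed on the original bond
vector (1.09 Å from carbon, 1.01 Å from nitrogen).  Original atoms are never
moved: fragments share coordinates bitwise, so the interaction energy
IE = E(BID+CRC) - E(CRC) - E(BID+CC) + E(CC) cancels the cap contribution
exactly under a strictly pairwise-additive energy model.

Chain termini (and sequence gaps, treated like termini) simply omit the
missing cap and retain the native terminal group.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .structures import Atom, ComplexStructure, Residue, StructureError

__all__ = [
    "LINK_BOND_LENGTHS",
    "LinkAtom",
    "Fragment",
    "FragmentQuartet",
    "CapError",
    "place_link_hydrogen",
    "excise_capped_tripeptide",
    "excise_caps_only",
    "build_quartet",
]

#: link hydrogen bond lengths by parent element, Å
LINK_BOND_LENGTHS = {"C": 1.09, "N": 1.01}

ROLES = ("BID_CRC", "CRC", "BID_CC", "CC")


class CapError(StructureError):
    pass


@dataclass(frozen=True)
class LinkAtom:
    """A cap hydrogen saturating one cut covalent bond."""

    atom: Atom
    parent: Atom
    removed_neighbor_position: np.ndarray
    bond_length: float


@dataclass
class Fragment:
    """One of the four MFCC systems for a residue."""

    role: str
    atoms: list[Atom]
    residues_included: list[tuple[str, int, str]]
    includes_ligand: bool
    net_charge: int
    multiplicity: int = 1
    link_atoms: list[LinkAtom] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown fragment role {self.role!r}")
        if self.includes_ligand != (self.role in ("BID_CRC", "BID_CC")):
            raise ValueError(f"role {self.role} inconsistent with includes_ligand")

    @property
    def n_link_atoms(self) -> int:
        return sum(1 for a in self.atoms if a.is_link)

    def content_hash(self) -> str:
        """Stable key over role, geometry (µÅ precision), charge and spin."""
        h = hashlib.sha256()
        h.update(self.role.encode())
        h.update(f"{self.net_charge} {self.multiplicity}".encode())
        for a in self.atoms:
            x, y, z = np.round(a.position, 6)
            h.update(f"{a.element} {x:.6f} {y:.6f} {z:.6f}".encode())
        return h.hexdigest()[:16]


@dataclass
class FragmentQuartet:
    """The four capped systems entering the MFCC interaction energy."""

    residue_id: tuple[str, int, str, str]
    fragments: dict[str, Fragment]

    def __post_init__(self) -> None:
        if set(self.fragments) != set(ROLES):
            raise ValueError(f"quartet must hold roles {ROLES}")

    def __getitem__(self, role: str) -> Fragment:
        return self.fragments[role]


def place_link_hydrogen(parent: Atom, removed_neighbor_position) -> LinkAtom:
    """Place a link hydrogen on the parent→removed-neighbor bond vector.

    The hydrogen sits at 1.09 Å from a carbon parent and 1.01 Å from a
    nitrogen parent, exactly collinear with the cut bond.
    """
    neighbor = np.asarray(removed_neighbor_position, dtype=float)
    vec = neighbor - parent.position
    norm = float(np.linalg.norm(vec))
    if norm < 1e-8:
        raise StructureError("zero-length bond vector for link hydrogen")
    try:
        length = LINK_BOND_LENGTHS[parent.element.upper()]
    except KeyError:
        raise CapError(f"no link bond length for parent element {parent.element}")
    pos = parent.position + vec / norm * length
    atom = Atom(serial=-1, name="HL", element="H", position=pos, is_link=True)
    return LinkAtom(atom=atom, parent=parent, removed_neighbor_position=neighbor,
                    bond_length=length)


def _neighbors(complex_: ComplexStructure, residue: Residue):
    """Sequence-adjacent residues in the same chain (None at termini/gaps).

    A numbering gap is treated like a chain terminus: a residue whose
    neighbor is not at number ± 1 has no cap on that side.
    """
    chain = complex_.chain_residues(residue.chain)
    idx = next(i for i, r in enumerate(chain) if r.id == residue.id)
    prev_res = chain[idx - 1] if idx > 0 else None
    next_res = chain[idx + 1] if idx < len(chain) - 1 else None
    if prev_res is not None and not residue.icode and not prev_res.icode \
            and prev_res.number != residue.number - 1:
        prev_res = None
    if next_res is not None and not residue.icode and not next_res.icode \
            and next_res.number != residue.number + 1:
        next_res = None
    return prev_res, next_res


def _require_backbone(res: Residue) -> None:
    names = {a.name for a in res.atoms}
    if not {"N", "CA", "C"} <= names:
        raise CapError(f"cannot cap: residue {res.label} lacks backbone N/CA/C")


def _outer_links(prev_res, next_res, complex_: ComplexStructure):
    """Link hydrogens for the two outward cuts of a capped fragment."""
    links = []
    if prev_res is not None:
        before, _ = _neighbors(complex_, prev_res)
        if before is not None:
            # cut (i-2).C — (i-1).N: saturate the cap's backbone N
            links.append(place_link_hydrogen(prev_res.atom("N"), before.atom("C").position))
    if next_res is not None:
        _, after = _neighbors(complex_, next_res)
        if after is not None:
            # cut (i+1).C — (i+2).N: saturate the cap's carbonyl C
            links.append(place_link_hydrogen(next_res.atom("C"), after.atom("N").position))
    return links


def _assemble(role: str, residues: list[Residue], links: list[LinkAtom],
              ligand_atoms: list[Atom] | None, charges: int) -> Fragment:
    atoms: list[Atom] = []
    if ligand_atoms is not None:
        atoms.extend(ligand_atoms)
    for r in residues:
        atoms.extend(r.atoms)
    serial = max((a.serial for a in atoms), default=0)
    link_atoms = []
    for i, link in enumerate(links, start=1):
        renumbered = Atom(serial=serial + i, name="HL", element="H",
                          position=link.atom.position, is_link=True)
        atoms.append(renumbered)
        link_atoms.append(LinkAtom(renumbered, link.parent,
                                   link.removed_neighbor_position, link.bond_length))
    return Fragment(
        role=role,
        atoms=atoms,
        residues_included=[r.id for r in residues],
        includes_ligand=ligand_atoms is not None,
        net_charge=charges,
        link_atoms=link_atoms,
    )


def excise_capped_tripeptide(
    complex_: ComplexStructure, residue_id: tuple[str, int, str]
) -> Fragment:
    """The CRC system: residue i with its two neighboring-residue caps.

    Interior residues gain exactly two link hydrogens (one per outward amide
    cut); at a terminus the missing cap is omitted and no link is added on
    that side.
    """
    residue = complex_.residue(residue_id)
    _require_backbone(residue)
    prev_res, next_res = _neighbors(complex_, residue)
    for cap in (prev_res, next_res):
        if cap is not None:
            _require_backbone(cap)
    members = [r for r in (prev_res, residue, next_res) if r is not None]
    links = _outer_links(prev_res, next_res, complex_)
    charge = sum(r.formal_charge for r in members)
    return _assemble("CRC", members, links, None, charge)


def excise_caps_only(
    complex_: ComplexStructure, residue_id: tuple[str, int, str]
) -> Fragment:
    """The CC system: the caps with residue i removed.

    Carries the same outward link hydrogens as the CRC system plus one link
    per inward cut to the removed residue (two for an interior residue).
    Cap coordinates are identical to those in the CRC fragment.
    """
    residue = complex_.residue(residue_id)
    _require_backbone(residue)
    prev_res, next_res = _neighbors(complex_, residue)
    for cap in (prev_res, next_res):
        if cap is not None:
            _require_backbone(cap)
    members = [r for r in (prev_res, next_res) if r is not None]
    if not members:
        raise CapError(f"cannot cap: residue {residue.label} has no neighbors")
    links = _outer_links(prev_res, next_res, complex_)
    if prev_res is not None:
        # inward cut (i-1).C — i.N: saturate the cap's carbonyl C
        links.append(place_link_hydrogen(prev_res.atom("C"), residue.atom("N").position))
    if next_res is not None:
        # inward cut i.C — (i+1).N: saturate the cap's backbone N
        links.append(place_link_hydrogen(next_res.atom("N"), residue.atom("C").position))
    charge = sum(r.formal_charge for r in members)
    return _assemble("CC", members, links, None, charge)


def build_quartet(
    complex_: ComplexStructure, residue_id: tuple[str, int, str]
) -> FragmentQuartet:
    """Assemble the four MFCC systems for one residue.

    Ligand coordinates are identical (bitwise) in BID_CRC and BID_CC, and
    cap coordinates identical across all four roles.
    """
    residue = complex_.residue(residue_id)
    crc = excise_capped_tripeptide(complex_, residue_id)
    cc = excise_caps_only(complex_, residue_id)
    lig = complex_.ligand

    def with_ligand(frag: Fragment, role: str) -> Fragment:
        return _assemble(
            role,
            [complex_.residue(rid) for rid in frag.residues_included],
            frag.link_atoms,
            list(lig.atoms),
            frag.net_charge + lig.formal_charge,
        )

    return FragmentQuartet(
        residue_id=(*residue.id, residue.name),
        fragments={
            "BID_CRC": with_ligand(crc, "BID_CRC"),
            "CRC": crc,
            "BID_CC": with_ligand(cc, "BID_CC"),
            "CC": cc,
        },
    )
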