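"""Normalized protein-ligand complex model, PDB I/O and pocket selection.

A complex is one receptor (ordered residues with author numbering and
integer formal charges) plus exactly one ligand.  Binding-pocket membership
is decided by the minimum heavy-atom distance between a residue and the
ligand, which is robust to hydrogen placement and matches common pocket
practice; the convention is exposed so callers can include hydrogens.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "Atom",
    "Residue",
    "Ligand",
    "ComplexStructure",
    "StructureError",
    "LigandNotFoundError",
    "AmbiguousLigandError",
    "PDBParseError",
    "read_complex",
    "write_complex_pdb",
    "write_xyz",
    "min_distance",
    "select_pocket",
]

#: default formal charges of titratable residues at neutral pH, in e
RESIDUE_FORMAL_CHARGES = {"ASP": -1, "GLU": -1, "LYS": 1, "ARG": 1}

STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

_ELEMENTS = {
    "H", "D", "HE", "LI", "BE", "B", "C", "N", "O", "F", "NE", "NA", "MG",
    "AL", "SI", "P", "S", "CL", "AR", "K", "CA", "MN", "FE", "CO", "NI",
    "CU", "ZN", "SE", "BR", "I",
}


class StructureError(ValueError):
    """Base error for structural model violations."""


class LigandNotFoundError(StructureError):
    pass


class AmbiguousLigandError(StructureError):
    pass


class PDBParseError(StructureError):
    pass


@dataclass(frozen=True)
class Atom:
    """One atom: serial id, PDB atom name, element symbol and position in Å.

    ``is_link`` is True only for cap hydrogens added during fragmentation.
    """

    serial: int
    name: str
    element: str
    position: np.ndarray
    is_link: bool = False

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise StructureError(f"atom {self.name}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)
        if self.element.upper() not in _ELEMENTS:
            raise StructureError(f"atom {self.name}: unknown element {self.element!r}")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


@dataclass
class Residue:
    """One amino-acid residue with author numbering preserved."""

    chain: str
    number: int
    icode: str
    name: str
    atoms: list[Atom]
    formal_charge: int = 0
    n_terminal: bool = False
    c_terminal: bool = False
    nonstandard: bool = False

    def __post_init__(self) -> None:
        if not self.atoms:
            raise StructureError(f"residue {self.label}: no atoms")
        names = {a.name for a in self.atoms}
        if self.name in STANDARD_AA and not {"N", "CA", "C"} <= names:
            self.nonstandard = True

    @property
    def id(self) -> tuple[str, int, str]:
        return (self.chain, self.number, self.icode)

    @property
    def label(self) -> str:
        return f"{self.name}{self.number}{self.icode}".strip()

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"residue {self.label}: no atom {name!r}")

    def coords(self, heavy_only: bool = False) -> np.ndarray:
        sel = [a for a in self.atoms if not (heavy_only and a.is_hydrogen)]
        return np.array([a.position for a in sel]) if sel else np.empty((0, 3))


@dataclass
class Ligand:
    """The binder molecule, optionally carrying a published atom-label scheme.

    ``label_map`` maps atom names to ``{"label": ..., "region": ..., "ring": ...}``
    entries so reports can name the ligand region/atom each residue contacts.
    """

    name: str
    atoms: list[Atom]
    formal_charge: int = 0
    label_map: dict[str, dict] | None = None

    def __post_init__(self) -> None:
        if not self.atoms:
            raise StructureError("ligand has no atoms")
        if self.label_map:
            names = {a.name for a in self.atoms}
            bad = set(self.label_map) - names
            if bad:
                raise StructureError(f"label_map names absent from ligand: {sorted(bad)}")

    def coords(self, heavy_only: bool = False) -> np.ndarray:
        sel = [a for a in self.atoms if not (heavy_only and a.is_hydrogen)]
        return np.array([a.position for a in sel]) if sel else np.empty((0, 3))


@dataclass
class ComplexStructure:
    """Receptor residues (chain order) plus one ligand."""

    residues: list[Residue]
    ligand: Ligand
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        prev: dict[str, tuple[int, str]] = {}
        for r in self.residues:
            key = (r.number, r.icode)
            if r.chain in prev and key <= prev[r.chain]:
                raise StructureError(
                    f"residues out of order in chain {r.chain} at {r.label}"
                )
            prev[r.chain] = key
        lig_serials = {a.serial for a in self.ligand.atoms}
        for r in self.residues:
            for a in r.atoms:
                if a.serial in lig_serials:
                    raise StructureError(f"atom serial {a.serial} shared by ligand and {r.label}")

    def residue(self, residue_id: tuple[str, int, str]) -> Residue:
        for r in self.residues:
            if r.id == residue_id:
                return r
        raise KeyError(f"residue {residue_id} not in complex")

    def index_of(self, residue_id: tuple[str, int, str]) -> int:
        for i, r in enumerate(self.residues):
            if r.id == residue_id:
                return i
        raise KeyError(f"residue {residue_id} not in complex")

    def chain_residues(self, chain: str) -> list[Residue]:
        return [r for r in self.residues if r.chain == chain]


# ---------------------------------------------------------------------------
# reading


def _element_of(bio_atom) -> str:
    el = (bio_atom.element or "").strip()
    if el.upper() in _ELEMENTS:
        return el.capitalize() if len(el) > 1 else el.upper()
    # fall back to the first letter of the atom name
    stripped = bio_atom.get_name().strip().lstrip("0123456789")
    return stripped[0].upper()


def _pick_altloc(bio_atom):
    """Resolve a possibly-disordered atom to one conformer.

    Highest occupancy wins; ties resolve to the lowest altloc id ('A').
    """
    if not bio_atom.is_disordered():
        return bio_atom
    children = bio_atom.disordered_get_list()
    return sorted(children, key=lambda a: (-(a.get_occupancy() or 0.0), a.get_altloc()))[0]


def read_complex(
    pdb_source,
    ligand_resname: str,
    keep_het: Sequence[str] = (),
    ligand_chain: str | None = None,
    ligand_charge: int = 0,
    label_map: dict | None = None,
) -> ComplexStructure:
    """Read a protein-ligand complex from PDB text.

    Exactly one HETATM residue must match ``ligand_resname`` (narrow with
    ``ligand_chain`` when the lattice holds several copies).  Waters and any
    het group not listed in ``keep_het`` are dropped.  Only the first MODEL
    is used; alternate locations resolve to the highest-occupancy conformer.

    Raises
    ------
    LigandNotFoundError, AmbiguousLigandError, PDBParseError
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionException

    if hasattr(pdb_source, "read"):
        handle, source_id = pdb_source, "<stream>"
    else:
        handle, source_id = open(pdb_source), Path(pdb_source).stem

    parser = PDBParser(PERMISSIVE=0, QUIET=True)
    try:
        structure = parser.get_structure(source_id, handle)
    except PDBConstructionException as exc:  # message carries the line number
        raise PDBParseError(f"malformed PDB record: {exc}") from exc
    finally:
        if handle is not pdb_source:
            handle.close()

    model = next(iter(structure))
    keep = {n.upper() for n in keep_het}
    residues: list[Residue] = []
    ligand_candidates = []

    for chain in model:
        for res in chain:
            hetflag, number, icode = res.get_id()
            resname = res.get_resname().strip().upper()
            atoms = []
            seen = set()
            for bio_atom in res:
                bio_atom = _pick_altloc(bio_atom)
                if bio_atom.get_name() in seen:
                    continue
                seen.add(bio_atom.get_name())
                atoms.append(
                    Atom(
                        serial=bio_atom.get_serial_number(),
                        name=bio_atom.get_name(),
                        element=_element_of(bio_atom),
                        position=np.asarray(bio_atom.get_coord(), dtype=float),
                    )
                )
            if not atoms:
                continue
            if resname == ligand_resname.upper():
                ligand_candidates.append((chain.id, resname, atoms))
                continue
            if hetflag.strip() and hetflag != " ":
                if resname in ("HOH", "WAT", "DOD") or resname not in keep:
                    continue
            residues.append(
                Residue(
                    chain=chain.id,
                    number=number,
                    icode=icode.strip(),
                    name=resname,
                    atoms=atoms,
                    formal_charge=RESIDUE_FORMAL_CHARGES.get(resname, 0),
                )
            )

    if ligand_chain is not None:
        ligand_candidates = [c for c in ligand_candidates if c[0] == ligand_chain]
    if not ligand_candidates:
        raise LigandNotFoundError(f"ligand not found: no residue named {ligand_resname!r}")
    if len(ligand_candidates) > 1:
        chains = sorted(c[0] for c in ligand_candidates)
        raise AmbiguousLigandError(
            f"ambiguous ligand: {ligand_resname!r} present in chains {chains}; "
            "pass ligand_chain to select one"
        )

    _, resname, lig_atoms = ligand_candidates[0]
    for chain_id in {r.chain for r in residues}:
        chain_res = [r for r in residues if r.chain == chain_id]
        chain_res[0].n_terminal = True
        chain_res[-1].c_terminal = True

    return ComplexStructure(
        residues=residues,
        ligand=Ligand(resname, lig_atoms, formal_charge=ligand_charge, label_map=label_map),
        metadata={"source": source_id},
    )


# ---------------------------------------------------------------------------
# writing


def _pdb_atom_line(record: str, atom: Atom, resname: str, chain: str,
                   resnum: int, icode: str) -> str:
    name = atom.name
    # PDB columns 13-16: element right-justified in 13-14 for 1-letter names
    field = f" {name:<3s}" if len(name) < 4 and len(atom.element) == 1 else f"{name:<4s}"
    x, y, z = atom.position
    return (
        f"{record:<6s}{atom.serial:>5d} {field:<4s}{'':1s}{resname:>3s} {chain:1s}"
        f"{resnum:>4d}{icode or ' ':1s}   {x:8.3f}{y:8.3f}{z:8.3f}"
        f"{1.00:6.2f}{0.00:6.2f}          {atom.element.upper():>2s}"
    )


def write_complex_pdb(complex_: ComplexStructure, destination) -> None:
    """Write the normalized complex back out as PDB text (Å, 3 decimals)."""
    lines = []
    last_chain = None
    last = None
    for res in complex_.residues:
        if last_chain is not None and res.chain != last_chain:
            lines.append(_ter_line(last))
        for atom in res.atoms:
            lines.append(_pdb_atom_line("ATOM", atom, res.name, res.chain,
                                        res.number, res.icode))
        last_chain, last = res.chain, res
    if last is not None:
        lines.append(_ter_line(last))
    lig = complex_.ligand
    for atom in lig.atoms:
        lines.append(_pdb_atom_line("HETATM", atom, lig.name, "L", 1, ""))
    lines.append("END")
    text = "\n".join(lines) + "\n"
    if hasattr(destination, "write"):
        destination.write(text)
    else:
        Path(destination).write_text(text)


def _ter_line(res: Residue) -> str:
    return (f"TER   {res.atoms[-1].serial + 1:>5d}      {res.name:>3s} "
            f"{res.chain:1s}{res.number:>4d}{res.icode or ' ':1s}")


def write_xyz(atoms: Iterable[Atom], destination, comment: str = "") -> None:
    """Write atoms in XYZ format (element, Å coordinates to 6 decimals)."""
    atoms = list(atoms)
    buf = io.StringIO()
    buf.write(f"{len(atoms)}\n{comment}\n")
    for a in atoms:
        x, y, z = a.position
        buf.write(f"{a.element:<2s} {x:14.6f} {y:14.6f} {z:14.6f}\n")
    text = buf.getvalue()
    if hasattr(destination, "write"):
        destination.write(text)
    else:
        Path(destination).write_text(text)


# ---------------------------------------------------------------------------
# pocket geometry


def min_distance(residue: Residue, ligand: Ligand, heavy_only: bool = True) -> float:
    """Minimum atom-pair Euclidean distance between a residue and the ligand."""
    a = residue.coords(heavy_only=heavy_only)
    b = ligand.coords(heavy_only=heavy_only)
    if a.size == 0 or b.size == 0:
        raise StructureError("min_distance: empty atom selection")
    return float(cdist(a, b).min())


def select_pocket(
    complex_: ComplexStructure, r: float, heavy_only: bool = True
) -> list[Residue]:
    """Residues whose minimum distance to the ligand is ≤ r Å, in chain order.

    Monotone in r: smaller spheres select subsets of larger ones.
    """
    if r < 0:
        raise ValueError("pocket radius must be non-negative")
    return [
        res
        for res in complex_.residues
        if min_distance(res, complex_.ligand, heavy_only=heavy_only) <= r
    ]
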