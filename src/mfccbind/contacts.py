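"""Geometric contact annotation of pocket residues against the ligand.

Each residue in the energy report is annotated with its nearest ligand atom
(translated through the ligand's published label/region scheme when one is
attached) and a simplified five-class geometric interaction type:

* ``hydrogen_bond`` — N/O donor-H ... N/O acceptor, donor-acceptor ≤ 3.5 Å
  and donor-H-acceptor angle ≥ 120°
* ``nonconventional_hbond`` — same geometry with a C-H donor
* ``aromatic`` — residue ring centroid within 5.5 Å of a ligand ring centroid
* ``hydrophobic`` — apolar carbon pair within 4.5 Å
* ``polar_contact`` — fallback when nothing above fires

This is a reduced scheme: richer typings (pi-alkyl, pi-sulfur, pi-sigma,
dipole-dipole) produced by visualization suites are out of scope, and all
thresholds are configurable rather than tuned to any particular software.
Annotation never alters energies; joins are by residue id only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .decomposition import ResidueIE
from .structures import Atom, ComplexStructure, Ligand, Residue

__all__ = ["HBondParams", "ContactAnnotation", "annotate_contacts"]

#: ring atom names for aromatic residue side chains
_RESIDUE_RINGS = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
}

_COVALENT_H_MAX = 1.25  # Å, X-H bond detection
_COVALENT_HEAVY_MAX = 1.75  # Å, C-N/C-O bond detection


@dataclass(frozen=True)
class HBondParams:
    """Geometric thresholds for the contact classifier."""

    donor_acceptor_max: float = 3.5  # Å
    angle_min_deg: float = 120.0
    aromatic_centroid_max: float = 5.5  # Å
    hydrophobic_max: float = 4.5  # Å


@dataclass(frozen=True)
class ContactAnnotation:
    residue_id: tuple[str, int, str, str]
    nearest_ligand_atom: str  # published label when available, else atom name
    region: str | None
    distance: float
    contact_class: str


def _bonded(center: Atom, atoms: list[Atom], cutoff: float):
    return [
        a for a in atoms
        if a is not center
        and float(np.linalg.norm(a.position - center.position)) <= cutoff
    ]


def _donors(atoms: list[Atom]):
    """(heavy, H) pairs where a hydrogen is covalently bound to the heavy atom."""
    hydrogens = [a for a in atoms if a.is_hydrogen]
    out = []
    for h in hydrogens:
        for heavy in atoms:
            if heavy.is_hydrogen:
                continue
            if float(np.linalg.norm(h.position - heavy.position)) <= _COVALENT_H_MAX:
                out.append((heavy, h))
                break
    return out


def _acceptors(atoms: list[Atom]):
    return [a for a in atoms if a.element.upper() in ("N", "O")]


def _apolar_carbons(atoms: list[Atom]):
    """Carbons with no N/O within covalent range (a crude polarity proxy)."""
    heteros = [a for a in atoms if a.element.upper() in ("N", "O")]
    out = []
    for c in atoms:
        if c.element.upper() != "C":
            continue
        if not _bonded(c, heteros, _COVALENT_HEAVY_MAX):
            out.append(c)
    return out


def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    v1, v2 = a - b, c - b
    cosang = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def _hbond_class(residue: Residue, ligand: Ligand, p: HBondParams) -> str | None:
    best = None
    # donor on either side, acceptor on the other
    for donors, acceptors in (
        (_donors(residue.atoms), _acceptors(ligand.atoms)),
        (_donors(ligand.atoms), _acceptors(residue.atoms)),
    ):
        for heavy, h in donors:
            for acc in acceptors:
                d_da = float(np.linalg.norm(heavy.position - acc.position))
                if d_da > p.donor_acceptor_max:
                    continue
                if _angle_deg(heavy.position, h.position, acc.position) < p.angle_min_deg:
                    continue
                kind = (
                    "hydrogen_bond"
                    if heavy.element.upper() in ("N", "O")
                    else "nonconventional_hbond"
                )
                if kind == "hydrogen_bond":
                    return kind
                best = best or kind
    return best


def _ligand_ring_centroids(ligand: Ligand) -> list[np.ndarray]:
    if not ligand.label_map:
        return []
    rings: dict[str, list[np.ndarray]] = {}
    for atom in ligand.atoms:
        entry = ligand.label_map.get(atom.name)
        if entry and entry.get("ring") not in (None, "none", ""):
            rings.setdefault(entry["ring"], []).append(atom.position)
    return [np.mean(ps, axis=0) for ps in rings.values() if len(ps) >= 3]


def _classify(residue: Residue, ligand: Ligand, p: HBondParams) -> str:
    hb = _hbond_class(residue, ligand, p)
    if hb == "hydrogen_bond":
        return hb
    ring_names = _RESIDUE_RINGS.get(residue.name, ())
    res_ring = [a.position for a in residue.atoms if a.name in ring_names]
    if len(res_ring) >= 3:
        centroid = np.mean(res_ring, axis=0)
        for lig_centroid in _ligand_ring_centroids(ligand):
            if float(np.linalg.norm(centroid - lig_centroid)) <= p.aromatic_centroid_max:
                return "aromatic"
    if hb == "nonconventional_hbond":
        return hb
    res_c = _apolar_carbons(residue.atoms)
    lig_c = _apolar_carbons(ligand.atoms)
    for a in res_c:
        for b in lig_c:
            if float(np.linalg.norm(a.position - b.position)) <= p.hydrophobic_max:
                return "hydrophobic"
    return "polar_contact"


def annotate_contacts(
    complex_: ComplexStructure,
    residue_ies: list[ResidueIE],
    hbond_params: HBondParams | None = None,
) -> list[ContactAnnotation]:
    """Annotate every residue in the energy report with its ligand contact.

    The nearest ligand heavy atom is named through the label map when the
    ligand carries one (falling back to the raw atom name), and the residue
    receives one of the five geometric contact classes.
    """
    p = hbond_params or HBondParams()
    ligand = complex_.ligand
    lig_heavy = [a for a in ligand.atoms if not a.is_hydrogen]
    annotations = []
    for ie in residue_ies:
        residue = complex_.residue(ie.residue_id[:3])
        res_heavy = residue.coords(heavy_only=True)
        d = np.linalg.norm(
            res_heavy[:, None, :] - np.array([a.position for a in lig_heavy])[None, :, :],
            axis=-1,
        )
        j = int(np.argmin(d.min(axis=0)))
        nearest = lig_heavy[j]
        entry = (ligand.label_map or {}).get(nearest.name)
        annotations.append(
            ContactAnnotation(
                residue_id=ie.residue_id,
                nearest_ligand_atom=(entry or {}).get("label", nearest.name),
                region=(entry or {}).get("region"),
                distance=float(d.min()),
                contact_class=_classify(residue, ligand, p),
            )
        )
    return annotations
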