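"""Deterministic toy peptide-ligand complexes with known additive energetics.

These fixtures exist so every pipeline stage — pocket selection, capping,
the four-fragment energy algebra, the radius scan — can be verified on a
desk without downloading structures.  A short peptide is built from internal
coordinates (standard backbone bond lengths, extended conformation by
default) from a five-residue library {GLY, ALA, SER, ASP(-1), LYS(+1)}, and
a small probe ligand is placed at a controlled offset from a chosen anchor
residue.  Charges and Lennard-Jones parameters are assigned from a fixed
table (or seeded uniform draws with per-residue net-charge enforcement), so
the exact per-residue ligand cross energy is computable by brute force —
the independent oracle the fragmentation pipeline is checked against.

The fixtures test algebra and geometry, not pharmacology: they do not mimic
any real ligand chemistry or receptor fold.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .energies import COULOMB_CONSTANT, AtomParameters, ParameterSet
from .structures import Atom, ComplexStructure, Ligand, Residue, StructureError, write_complex_pdb

__all__ = [
    "ToySpec",
    "build_toy_complex",
    "assign_toy_parameters",
    "ground_truth_decomposition",
    "emit_fixture",
]

# backbone internal coordinates, Å / degrees
_B_N_CA, _B_CA_C, _B_C_N = 1.458, 1.525, 1.329
_B_C_O, _B_N_H = 1.229, 1.010
_A_C_N_CA, _A_N_CA_C, _A_CA_C_N = 121.7, 111.2, 116.2
_A_CA_C_O = 120.8

#: per-atom partial charges, e; each residue sums exactly to its formal charge
_CHARGE_TABLE = {
    "GLY": {"N": -0.40, "H": 0.30, "CA": 0.00, "C": 0.50, "O": -0.40},
    "ALA": {"N": -0.40, "H": 0.30, "CA": 0.10, "CB": -0.10, "C": 0.50, "O": -0.40},
    "SER": {"N": -0.40, "H": 0.30, "CA": 0.05, "CB": 0.10, "OG": -0.60,
            "HG": 0.40, "C": 0.55, "O": -0.40},
    "ASP": {"N": -0.40, "H": 0.30, "CA": 0.00, "CB": -0.10, "CG": 0.60,
            "OD1": -0.70, "OD2": -0.70, "C": 0.50, "O": -0.50},
    "LYS": {"N": -0.40, "H": 0.30, "CA": 0.00, "CB": 0.00, "CG": 0.00,
            "CD": 0.00, "CE": 0.20, "NZ": -0.10, "HZ1": 0.90, "C": 0.50, "O": -0.40},
}
_FORMAL_CHARGES = {"GLY": 0, "ALA": 0, "SER": 0, "ASP": -1, "LYS": 1}

#: Lennard-Jones by element: sigma Å, epsilon kcal/mol
_LJ_TABLE = {
    "H": (2.50, 0.0157),
    "C": (3.40, 0.0860),
    "N": (3.25, 0.1700),
    "O": (2.96, 0.2100),
    "S": (3.56, 0.2500),
    "AR": (3.40, 0.2380),
}

_PROBE_CHARGES = {
    "lj_sphere": {"X1": 0.0},
    "diatomic_dipole": {"O1": -0.40, "H1": 0.40},
    "tripeptide_mimic": {
        "C1": 0.00, "C2": 0.55, "O1": -0.55, "N1": -0.40, "HN": 0.40,
        "CR1": 0.00, "CR2": 0.00, "CR3": 0.00, "CR4": 0.00, "CR5": 0.00, "CR6": 0.00,
    },
}

#: label/region scheme for the amide+ring probe (regions i/ii, ring A)
_MIMIC_LABEL_MAP = {
    "C1": {"label": "i(C1)", "region": "i", "ring": "none"},
    "C2": {"label": "i(C2)", "region": "i", "ring": "none"},
    "O1": {"label": "i(O1)", "region": "i", "ring": "none"},
    "N1": {"label": "i(N1)", "region": "i", "ring": "none"},
    "HN": {"label": "i(N1)H", "region": "i", "ring": "none"},
    **{f"CR{k}": {"label": f"ii(C{k + 2})", "region": "ii", "ring": "A"} for k in range(1, 7)},
}


@dataclass(frozen=True)
class ToySpec:
    """Recipe for one deterministic toy complex."""

    sequence: tuple[str, ...]
    probe: str = "diatomic_dipole"
    anchor_index: int = 1  # 1-based residue index the probe sits above
    offset: float = 3.5  # Å along +z from the anchor CA
    phi: float = -139.0
    psi: float = 135.0
    omega: float = 180.0
    charge_scheme: str = "table"  # "table" | "seeded_random"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.sequence) < 2:
            raise ValueError("toy peptide needs at least 2 residues")
        bad = set(self.sequence) - set(_CHARGE_TABLE)
        if bad:
            raise ValueError(f"residues outside the toy library: {sorted(bad)}")
        if self.probe not in _PROBE_CHARGES:
            raise ValueError(f"unknown probe {self.probe!r}")
        if not 1 <= self.anchor_index <= len(self.sequence):
            raise ValueError("anchor_index outside sequence")
        if self.charge_scheme not in ("table", "seeded_random"):
            raise ValueError(f"unknown charge_scheme {self.charge_scheme!r}")


def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
          bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom d from internal coordinates relative to chain a-b-c."""
    angle = math.radians(angle_deg)
    torsion = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * math.cos(angle),
            bond * math.sin(angle) * math.cos(torsion),
            bond * math.sin(angle) * math.sin(torsion),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _sidechain(resname: str, n: np.ndarray, ca: np.ndarray, c: np.ndarray):
    """Side-chain positions keyed by atom name, grown from the backbone."""
    out: dict[str, np.ndarray] = {}
    if resname == "GLY":
        return out
    cb = _nerf(c, n, ca, 1.53, 110.5, -122.0)
    out["CB"] = cb
    if resname == "ALA":
        return out
    if resname == "SER":
        og = _nerf(n, ca, cb, 1.41, 109.5, 180.0)
        out["OG"] = og
        out["HG"] = _nerf(ca, cb, og, 0.96, 109.5, 180.0)
    elif resname == "ASP":
        cg = _nerf(n, ca, cb, 1.52, 112.0, 180.0)
        out["CG"] = cg
        out["OD1"] = _nerf(ca, cb, cg, 1.25, 118.0, 0.0)
        out["OD2"] = _nerf(ca, cb, cg, 1.25, 118.0, 180.0)
    elif resname == "LYS":
        cg = _nerf(n, ca, cb, 1.52, 112.0, 180.0)
        cd = _nerf(ca, cb, cg, 1.52, 112.0, 180.0)
        ce = _nerf(cb, cg, cd, 1.52, 112.0, 180.0)
        nz = _nerf(cg, cd, ce, 1.47, 112.0, 180.0)
        out.update(CG=cg, CD=cd, CE=ce, NZ=nz)
        out["HZ1"] = _nerf(cd, ce, nz, 1.01, 109.5, 180.0)
    return out


def _probe_atoms(spec: ToySpec, base: np.ndarray, serial0: int):
    def mk(serial, name, element, pos):
        return Atom(serial=serial, name=name, element=element, position=np.asarray(pos, float))

    s = serial0
    if spec.probe == "lj_sphere":
        return [mk(s, "X1", "Ar", base)], None
    if spec.probe == "diatomic_dipole":
        return [
            mk(s, "O1", "O", base),
            mk(s + 1, "H1", "H", base + np.array([0.0, 0.0, 1.2])),
        ], None
    # tripeptide_mimic: an N-acetyl amide head plus a six-carbon ring proxy
    atoms = [
        mk(s, "C1", "C", base + np.array([-1.50, 0.0, 0.0])),
        mk(s + 1, "C2", "C", base),
        mk(s + 2, "O1", "O", base + np.array([0.55, 0.0, -1.10])),
        mk(s + 3, "N1", "N", base + np.array([0.70, 1.10, 0.0])),
        mk(s + 4, "HN", "H", base + np.array([0.35, 2.02, 0.0])),
    ]
    ring_center = base + np.array([3.2, 1.1, 0.0])
    for k in range(6):
        ang = math.radians(60.0 * k)
        pos = ring_center + 1.39 * np.array([math.cos(ang), math.sin(ang), 0.0])
        atoms.append(mk(s + 5 + k, f"CR{k + 1}", "C", pos))
    return atoms, dict(_MIMIC_LABEL_MAP)


def build_toy_complex(spec: ToySpec) -> ComplexStructure:
    """Build the peptide and place the probe; bit-for-bit deterministic.

    Raises a geometry error when any interatomic distance falls below
    0.8 Å (a clash that would make the pair potential blow up).
    """
    placed = []  # (resname, number, atom positions, C, N, CA) per residue
    serial = 0
    prev = None  # (N, CA, C) of the previous residue
    for i, resname in enumerate(spec.sequence, start=1):
        if prev is None:
            n = np.zeros(3)
            ca = np.array([_B_N_CA, 0.0, 0.0])
            ang = math.radians(180.0 - _A_N_CA_C)
            c = ca + _B_CA_C * np.array([math.cos(ang), math.sin(ang), 0.0])
            h = _nerf(c, ca, n, _B_N_H, 118.0, 180.0)
        else:
            pn, pca, pc = prev
            n = _nerf(pn, pca, pc, _B_C_N, _A_CA_C_N, spec.psi)
            ca = _nerf(pca, pc, n, _B_N_CA, _A_C_N_CA, spec.omega)
            c = _nerf(pc, n, ca, _B_CA_C, _A_N_CA_C, spec.phi)
            h = _nerf(pca, pc, n, _B_N_H, 119.0, spec.psi - 180.0)
        atoms_pos: dict[str, np.ndarray] = {"N": n, "H": h, "CA": ca, "C": c}
        atoms_pos.update(_sidechain(resname, n, ca, c))
        placed.append((resname, i, atoms_pos, c, n, ca))
        prev = (n, ca, c)

    # carbonyl oxygens need the next residue's N (anti to it); the last
    # residue's O is placed anti to its own N instead
    built: list[Residue] = []
    for idx, (resname, i, atoms_pos, c, n, ca) in enumerate(placed):
        if idx < len(placed) - 1:
            next_n = placed[idx + 1][4]
            o = _nerf(next_n, ca, c, _B_C_O, _A_CA_C_O, 180.0)
        else:
            o = _nerf(n, ca, c, _B_C_O, _A_CA_C_O, 180.0)
        atoms_pos["O"] = o
        order = ["N", "H", "CA", "C", "O"] + [
            k for k in atoms_pos if k not in ("N", "H", "CA", "C", "O")
        ]
        atom_list = []
        for name in order:
            serial += 1
            atom_list.append(
                Atom(serial=serial, name=name, element=name[0], position=atoms_pos[name])
            )
        built.append(
            Residue(
                chain="A",
                number=i,
                icode="",
                name=resname,
                atoms=atom_list,
                formal_charge=_FORMAL_CHARGES[resname],
                n_terminal=(i == 1),
                c_terminal=(i == len(placed)),
            )
        )

    anchor_ca = built[spec.anchor_index - 1].atom("CA").position
    base = anchor_ca + np.array([0.0, 0.0, spec.offset])
    probe_atoms, label_map = _probe_atoms(spec, base, serial + 1)
    ligand = Ligand(name="PRB", atoms=probe_atoms, formal_charge=0, label_map=label_map)

    complex_ = ComplexStructure(
        residues=built,
        ligand=ligand,
        metadata={"source": "toy", "spec": repr(spec)},
    )
    all_pos = np.array(
        [a.position for r in built for a in r.atoms] + [a.position for a in probe_atoms]
    )
    diff = all_pos[:, None, :] - all_pos[None, :, :]
    d = np.sqrt((diff ** 2).sum(-1)) + np.eye(len(all_pos)) * 10.0
    if d.min() < 0.8:
        raise StructureError(f"steric clash in toy complex: min distance {d.min():.3f} Å")
    return complex_


def assign_toy_parameters(complex_: ComplexStructure, spec: ToySpec) -> ParameterSet:
    """Charges from the embedded table or seeded draws; LJ by element.

    The seeded scheme draws uniform charges then shifts each residue's atoms
    so the residue sums exactly to its formal charge (probe atoms always use
    the table, keeping the ligand's net charge fixed at the spec value).
    """
    by_serial: dict[int, AtomParameters] = {}
    rng = np.random.default_rng(spec.seed)
    for res in complex_.residues:
        table = _CHARGE_TABLE[res.name]
        if spec.charge_scheme == "table":
            charges = [table[a.name] for a in res.atoms]
        else:
            draws = rng.uniform(-0.4, 0.4, size=len(res.atoms))
            draws += (res.formal_charge - draws.sum()) / len(res.atoms)
            charges = list(draws)
        for atom, q in zip(res.atoms, charges):
            sigma, eps = _LJ_TABLE[atom.element.upper()]
            by_serial[atom.serial] = AtomParameters(q=float(q), sigma=sigma, epsilon_lj=eps)
    probe_table = _PROBE_CHARGES[spec.probe]
    for atom in complex_.ligand.atoms:
        sigma, eps = _LJ_TABLE[atom.element.upper()]
        by_serial[atom.serial] = AtomParameters(
            q=probe_table[atom.name], sigma=sigma, epsilon_lj=eps
        )
    return ParameterSet(by_serial=by_serial)


def ground_truth_decomposition(
    complex_: ComplexStructure, params: ParameterSet, epsilon: float
) -> dict[tuple[str, int, str], float]:
    """Exact per-residue ligand cross energies with no fragmentation.

    A deliberately plain double loop over ligand × residue atom pairs,
    independent of the vectorized backend, so it can serve as the oracle
    the MFCC pipeline is compared against.
    """
    out: dict[tuple[str, int, str], float] = {}
    lig = [(a, params.params_for(a)) for a in complex_.ligand.atoms]
    for res in complex_.residues:
        e = 0.0
        for atom in res.atoms:
            pa = params.params_for(atom)
            for latom, pl in lig:
                r = math.dist(atom.position, latom.position)
                e += COULOMB_CONSTANT * pa.q * pl.q / (epsilon * r)
                sig = 0.5 * (pa.sigma + pl.sigma)
                eps_ij = math.sqrt(pa.epsilon_lj * pl.epsilon_lj)
                sr6 = (sig / r) ** 6
                e += 4.0 * eps_ij * (sr6 * sr6 - sr6)
        out[res.id] = e
    return out


def emit_fixture(spec: ToySpec, directory, epsilon: float = 10.0) -> dict:
    """Write a regression fixture: PDB + parameter and expected-value sidecars."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    complex_ = build_toy_complex(spec)
    params = assign_toy_parameters(complex_, spec)
    truth = ground_truth_decomposition(complex_, params, epsilon)
    write_complex_pdb(complex_, directory / "complex.pdb")
    (directory / "parameters.json").write_text(
        json.dumps(
            {
                str(serial): {"q": p.q, "sigma": p.sigma, "epsilon_lj": p.epsilon_lj}
                for serial, p in sorted(params.by_serial.items())
            },
            indent=1,
        )
    )
    expected = {
        "epsilon": epsilon,
        "per_residue_cross_energy": {
            f"{c}/{n}{i}": e for (c, n, i), e in truth.items()
        },
    }
    (directory / "expected.json").write_text(json.dumps(expected, indent=1))
    return expected
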