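"""Energy evaluators: classical pairwise backend and quantum-chemistry I/O.

The built-in classical backend is a strictly pairwise-additive
Coulomb + Lennard-Jones model.  It is a desk-scale stand-in, not a claim of
physical fidelity: because it is exactly additive, the MFCC cap terms cancel
algebraically, so per-residue interaction energies can be verified against a
brute-force ligand-residue cross sum to floating-point precision.  The
medium enters only through the dielectric constant ε dividing the Coulomb
term, mirroring how a continuum solvent model screens electrostatics.

Production energies come from an external quantum-chemistry engine instead:
``write_qm_input`` emits a deterministic Gaussian-style deck per fragment
(default B97D/6-311+G(d,p), CPCM with ε 10 or 40) and ``parse_qm_output``
harvests the final energy (hartree → kcal/mol) and convergence flag from the
engine's text output.  No electronic-structure computation happens here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Protocol, Sequence
import re

import numpy as np
from scipy.spatial.distance import cdist

from .fragments import Fragment
from .structures import Atom

__all__ = [
    "COULOMB_CONSTANT",
    "HARTREE_TO_KCALMOL",
    "AtomParameters",
    "ParameterSet",
    "QMJobSpec",
    "EnergyResult",
    "EnergyError",
    "MissingParameterError",
    "SingularGeometryError",
    "NoEnergyError",
    "EnergyModel",
    "ClassicalBackend",
    "QMHarvestBackend",
    "classical_energy",
    "classical_energy_components",
    "pair_cross_energy",
    "write_qm_input",
    "parse_qm_output",
]

#: Coulomb constant, kcal·Å/(mol·e²)
COULOMB_CONSTANT = 332.0636
#: hartree → kcal/mol
HARTREE_TO_KCALMOL = 627.509474


class EnergyError(ValueError):
    pass


class MissingParameterError(EnergyError):
    pass


class SingularGeometryError(EnergyError):
    pass


class NoEnergyError(EnergyError):
    pass


@dataclass(frozen=True)
class AtomParameters:
    """Partial charge (e) and Lennard-Jones sigma (Å) / epsilon (kcal/mol)."""

    q: float
    sigma: float
    epsilon_lj: float


@dataclass
class ParameterSet:
    """Per-atom parameters keyed by atom serial, plus the link-atom policy.

    ``link_atom_policy`` is ``"ghost"`` (link hydrogens carry zero charge
    and zero LJ well depth, making the MFCC algebra exact) or
    ``"parameterized"`` (link hydrogens use ``link_atom_params``).
    """

    by_serial: dict[int, AtomParameters] = field(default_factory=dict)
    link_atom_policy: str = "ghost"
    link_atom_params: AtomParameters = AtomParameters(q=0.06, sigma=2.50, epsilon_lj=0.0157)

    def __post_init__(self) -> None:
        if self.link_atom_policy not in ("ghost", "parameterized"):
            raise ValueError(f"unknown link_atom_policy {self.link_atom_policy!r}")

    def params_for(self, atom: Atom) -> AtomParameters:
        if atom.is_link:
            if self.link_atom_policy == "ghost":
                return AtomParameters(q=0.0, sigma=2.50, epsilon_lj=0.0)
            return self.link_atom_params
        try:
            return self.by_serial[atom.serial]
        except KeyError:
            raise MissingParameterError(
                f"no parameters for atom serial={atom.serial} name={atom.name}"
            )


def _arrays(atoms: Sequence[Atom], params: ParameterSet):
    pos = np.array([a.position for a in atoms], dtype=float).reshape(len(atoms), 3)
    p = [params.params_for(a) for a in atoms]
    q = np.array([x.q for x in p])
    sig = np.array([x.sigma for x in p])
    eps = np.array([x.epsilon_lj for x in p])
    return pos, q, sig, eps


def _pair_terms(r, qq, sig, eps, dielectric):
    """Coulomb and LJ matrices for a distance matrix r (Lorentz-Berthelot)."""
    if np.any(r < 1e-10):
        raise SingularGeometryError("coincident atoms (r = 0) in energy evaluation")
    coul = COULOMB_CONSTANT * qq / (dielectric * r)
    sr6 = (sig / r) ** 6
    lj = 4.0 * eps * (sr6 * sr6 - sr6)
    return coul, lj


def classical_energy_components(
    fragment: Fragment | Sequence[Atom], params: ParameterSet, epsilon: float
) -> tuple[float, float]:
    """(Coulomb, Lennard-Jones) internal energy of a fragment, kcal/mol.

    Sums over unordered atom pairs within the fragment; the Coulomb part
    scales exactly as 1/ε, the LJ part is ε-independent.
    """
    atoms = fragment.atoms if isinstance(fragment, Fragment) else list(fragment)
    if len(atoms) < 2:
        return 0.0, 0.0
    pos, q, sig, eps = _arrays(atoms, params)
    iu = np.triu_indices(len(atoms), k=1)
    r = cdist(pos, pos)[iu]
    qq = np.outer(q, q)[iu]
    sig_ij = (0.5 * (sig[:, None] + sig[None, :]))[iu]
    eps_ij = np.sqrt(np.outer(eps, eps))[iu]
    coul, lj = _pair_terms(r, qq, sig_ij, eps_ij, epsilon)
    return float(coul.sum()), float(lj.sum())


def classical_energy(
    fragment: Fragment | Sequence[Atom], params: ParameterSet, epsilon: float
) -> float:
    """Total classical internal energy of a fragment, kcal/mol."""
    coul, lj = classical_energy_components(fragment, params, epsilon)
    return coul + lj


def pair_cross_energy(
    atoms_a: Iterable[Atom], atoms_b: Iterable[Atom],
    params: ParameterSet, epsilon: float,
) -> float:
    """Cross-interaction energy between two disjoint atom sets, kcal/mol.

    Same pair potential as :func:`classical_energy`, summed over A×B pairs
    only, so E(A∪B) = E(A) + E(B) + cross(A, B) holds exactly.
    """
    atoms_a, atoms_b = list(atoms_a), list(atoms_b)
    if not atoms_a or not atoms_b:
        return 0.0
    pa, qa, sa, ea = _arrays(atoms_a, params)
    pb, qb, sb, eb = _arrays(atoms_b, params)
    r = cdist(pa, pb)
    qq = np.outer(qa, qb)
    sig_ij = 0.5 * (sa[:, None] + sb[None, :])
    eps_ij = np.sqrt(np.outer(ea, eb))
    coul, lj = _pair_terms(r, qq, sig_ij, eps_ij, epsilon)
    return float(coul.sum() + lj.sum())


# ---------------------------------------------------------------------------
# energy-evaluator contract


@dataclass(frozen=True)
class EnergyResult:
    """One fragment energy as delivered by a backend."""

    fragment_key: str
    energy: float
    source: str  # "classical" | "qm_parsed"
    converged: bool = True

    def __post_init__(self) -> None:
        if not np.isfinite(self.energy):
            raise EnergyError("non-finite fragment energy")


class EnergyModel(Protocol):
    """Deterministic fragment → energy evaluator at a given dielectric."""

    def evaluate(self, fragment: Fragment, epsilon: float) -> EnergyResult: ...


class ClassicalBackend:
    """Pairwise-additive backend with a content-hash energy cache."""

    def __init__(self, params: ParameterSet):
        self.params = params
        self._cache: dict[tuple[str, float], EnergyResult] = {}
        self.n_evaluations = 0

    def evaluate(self, fragment: Fragment, epsilon: float) -> EnergyResult:
        key = (fragment.content_hash(), float(epsilon))
        if key not in self._cache:
            self.n_evaluations += 1
            e = classical_energy(fragment, self.params, epsilon)
            self._cache[key] = EnergyResult(key[0], e, "classical")
        return self._cache[key]


class QMHarvestBackend:
    """Serve energies harvested from parsed quantum-chemistry outputs.

    ``table`` maps (fragment content hash, ε) → :class:`EnergyResult`.
    Unconverged or missing fragments raise, so the caller can mark the
    residue failed and continue.
    """

    def __init__(self, table: dict[tuple[str, float], EnergyResult]):
        self.table = table

    def evaluate(self, fragment: Fragment, epsilon: float) -> EnergyResult:
        key = (fragment.content_hash(), float(epsilon))
        try:
            result = self.table[key]
        except KeyError:
            raise NoEnergyError(f"no harvested energy for fragment {key[0]} at eps={epsilon}")
        if not result.converged:
            raise EnergyError(f"fragment {key[0]} did not converge")
        return result


# ---------------------------------------------------------------------------
# external quantum-chemistry interface


@dataclass(frozen=True)
class QMJobSpec:
    """Settings for one external DFT single-point job."""

    atoms: tuple[tuple[str, float, float, float], ...]
    charge: int
    multiplicity: int = 1
    method: str = "B97D"
    basis: str = "6-311+G(d,p)"
    solvent_model: str = "CPCM"
    epsilon: float = 40.0
    title: str = "fragment"

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("dielectric constant must be positive")
        if self.multiplicity < 1:
            raise ValueError("multiplicity must be >= 1")

    @classmethod
    def from_fragment(cls, fragment: Fragment, epsilon: float, **kw) -> "QMJobSpec":
        atoms = tuple(
            (a.element, float(a.position[0]), float(a.position[1]), float(a.position[2]))
            for a in fragment.atoms
        )
        title = f"{fragment.role} {fragment.content_hash()} q={fragment.net_charge}"
        return cls(atoms=atoms, charge=fragment.net_charge,
                   multiplicity=fragment.multiplicity, epsilon=epsilon,
                   title=title, **kw)


def write_qm_input(spec: QMJobSpec, destination=None) -> str:
    """Render a Gaussian-dialect input deck; byte-identical for equal specs."""
    lines = [
        f"# {spec.method}/{spec.basis} SCRF=({spec.solvent_model},Eps={spec.epsilon:g})",
        "",
        spec.title,
        "",
        f"{spec.charge} {spec.multiplicity}",
    ]
    for el, x, y, z in spec.atoms:
        lines.append(f"{el:<2s} {x:14.6f} {y:14.6f} {z:14.6f}")
    lines.append("")
    text = "\n".join(lines) + "\n"
    if destination is not None:
        if hasattr(destination, "write"):
            destination.write(text)
        else:
            Path(destination).write_text(text)
    return text


_ENERGY_PATTERNS = (
    re.compile(r"SCF Done:\s+E\([^)]*\)\s*=\s*([-+]?\d+\.\d+(?:[DdEe][-+]?\d+)?)"),
    re.compile(r"FINAL ENERGY\s*=\s*([-+]?\d+\.\d+(?:[DdEe][-+]?\d+)?)"),
)
_TERMINATION_MARKERS = ("Normal termination", "NORMAL TERMINATION")


def parse_qm_output(source, fragment_key: str = "") -> EnergyResult:
    """Harvest the final energy from quantum-chemistry text output.

    The last matching energy line wins (engines print one per SCF cycle or
    geometry step); the value is read as hartree and converted to kcal/mol.
    ``converged`` is False when the normal-termination marker is absent.
    """
    if hasattr(source, "read"):
        text = source.read()
    elif isinstance(source, str) and "\n" in source:
        text = source
    else:
        text = Path(source).read_text()
    matches = []
    for pattern in _ENERGY_PATTERNS:
        matches.extend((m.start(), m.group(1)) for m in pattern.finditer(text))
    if not matches:
        raise NoEnergyError("no energy found in quantum-chemistry output")
    matches.sort(key=lambda t: t[0])
    hartree = float(matches[-1][1].replace("D", "E").replace("d", "e"))
    converged = any(marker in text for marker in _TERMINATION_MARKERS)
    return EnergyResult(
        fragment_key=fragment_key,
        energy=hartree * HARTREE_TO_KCALMOL,
        source="qm_parsed",
        converged=converged,
    )
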