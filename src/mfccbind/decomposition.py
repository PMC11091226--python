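"""Per-residue interaction energies, radius scan and convergence analysis.

The per-residue interaction energy between binder and residue R_i is

    IE(BID/R_i) = E(BID + C R_i C) - E(C R_i C) - E(BID + C C) + E(C C)

where C C are the neighboring-residue caps.  Negative IE means attraction,
positive repulsion.  The binding pocket is scanned on the half-Ångström
radius grid r = R/2 (R = 1, 2, ...); the cumulative energy at each radius
is the sum of IE over the residues inside that sphere, and the scan is
declared converged at the smallest radius where the cumulative energy stops
changing by more than a relative threshold (default 10%) — and keeps
satisfying that criterion at every later computed radius.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .energies import EnergyError, EnergyModel
from .fragments import build_quartet
from .structures import ComplexStructure, min_distance, select_pocket

__all__ = [
    "NEUTRAL_BAND",
    "ResidueIE",
    "FailedResidue",
    "RadiusScan",
    "residue_interaction_energy",
    "classify",
    "decompose",
    "radius_scan",
    "find_convergence",
    "rank_and_classify",
]

#: |IE| below this is classified neutral, kcal/mol
NEUTRAL_BAND = 1e-6


@dataclass(frozen=True)
class ResidueIE:
    """One residue's four MFCC term energies and combined interaction energy."""

    residue_id: tuple[str, int, str, str]  # chain, number, icode, name
    epsilon: float
    e_bid_crc: float
    e_crc: float
    e_bid_cc: float
    e_cc: float
    ie: float
    classification: str
    min_distance: float = math.nan

    @property
    def label(self) -> str:
        chain, number, icode, name = self.residue_id
        return f"{name.capitalize()}{number}{icode}".strip()


@dataclass(frozen=True)
class FailedResidue:
    residue_id: tuple[str, int, str, str]
    epsilon: float
    reason: str


@dataclass
class RadiusScan:
    """Nested pocket sets over the r = R/2 grid with cumulative energies."""

    epsilon: float
    radii: list[float]
    residue_sets: list[list[tuple[str, int, str]]]
    cumulative_energy: list[float]
    threshold: float = 0.10
    converged_radius: float | None = None

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "radius": self.radii,
                "n_residues": [len(s) for s in self.residue_sets],
                "cumulative_energy": self.cumulative_energy,
                "converged": [
                    self.converged_radius is not None and r >= self.converged_radius
                    for r in self.radii
                ],
            }
        )


def residue_interaction_energy(e1: float, e2: float, e3: float, e4: float) -> float:
    """Combine the four MFCC term energies (BID_CRC, CRC, BID_CC, CC order).

    Returns e1 - e2 - e3 + e4: the caps' self-energy and their interaction
    with the binder cancel, isolating the binder-residue contribution.
    """
    terms = (e1, e2, e3, e4)
    if not all(math.isfinite(t) for t in terms):
        raise EnergyError(f"non-finite MFCC term energies: {terms}")
    return e1 - e2 - e3 + e4


def classify(ie: float, neutral_band: float = NEUTRAL_BAND) -> str:
    if abs(ie) < neutral_band:
        return "neutral"
    return "attractive" if ie < 0 else "repulsive"


def decompose(
    complex_: ComplexStructure,
    backend: EnergyModel,
    r_max: float,
    epsilon: float,
    heavy_only: bool = True,
) -> tuple[list[ResidueIE], list[FailedResidue]]:
    """Per-residue MFCC interaction energies for the r_max pocket.

    A residue whose fragment energies are missing or unconverged is reported
    in the failure list and the run continues.  Deterministic for a
    deterministic backend.
    """
    results: list[ResidueIE] = []
    failures: list[FailedResidue] = []
    for residue in select_pocket(complex_, r_max, heavy_only=heavy_only):
        dist = min_distance(residue, complex_.ligand, heavy_only=heavy_only)
        try:
            quartet = build_quartet(complex_, residue.id)
            e = {
                role: backend.evaluate(quartet[role], epsilon).energy
                for role in ("BID_CRC", "CRC", "BID_CC", "CC")
            }
        except (EnergyError, KeyError) as exc:
            failures.append(
                FailedResidue((*residue.id, residue.name), epsilon, str(exc))
            )
            continue
        ie = residue_interaction_energy(e["BID_CRC"], e["CRC"], e["BID_CC"], e["CC"])
        results.append(
            ResidueIE(
                residue_id=(*residue.id, residue.name),
                epsilon=epsilon,
                e_bid_crc=e["BID_CRC"],
                e_crc=e["CRC"],
                e_bid_cc=e["BID_CC"],
                e_cc=e["CC"],
                ie=ie,
                classification=classify(ie),
                min_distance=dist,
            )
        )
    return results, failures


def radius_scan(
    complex_: ComplexStructure,
    residue_ies: list[ResidueIE],
    r_max: float,
    step: float = 0.5,
    threshold: float = 0.10,
    heavy_only: bool = True,
) -> RadiusScan:
    """Cumulative interaction energy over nested pocket spheres.

    Each residue's IE is computed once (at the r_max pocket) and reused at
    every radius containing it; nothing is re-evaluated per sphere.
    """
    by_id = {ie.residue_id[:3]: ie for ie in residue_ies}
    dist = {
        res.id: min_distance(res, complex_.ligand, heavy_only=heavy_only)
        for res in complex_.residues
        if res.id in by_id
    }
    n_steps = int(round(r_max / step))
    radii = [step * k for k in range(1, n_steps + 1)]
    sets, cumulative = [], []
    for r in radii:
        inside = [rid for rid in by_id if dist[rid] <= r + 1e-9]
        inside.sort(key=lambda rid: ([res.id for res in complex_.residues].index(rid)))
        sets.append(inside)
        cumulative.append(sum(by_id[rid].ie for rid in inside))
    epsilon = residue_ies[0].epsilon if residue_ies else float("nan")
    scan = RadiusScan(
        epsilon=epsilon,
        radii=radii,
        residue_sets=sets,
        cumulative_energy=cumulative,
        threshold=threshold,
    )
    scan.converged_radius = find_convergence(scan, threshold)
    return scan


def find_convergence(
    scan: RadiusScan,
    threshold: float = 0.10,
    floor: float = 1e-6,
    require_hold: bool = True,
) -> float | None:
    """Smallest radius at which the cumulative energy has converged.

    Convergence at radius r_k means the cumulative energy changed by no more
    than ``threshold`` relative to the previous radius,
    |E(r_k) − E(r_{k−1})| / max(|E(r_k)|, floor) ≤ threshold, and (when
    ``require_hold``) the same criterion holds at every later computed
    radius.  Returns None when the criterion is never met or the series is
    identically zero.
    """
    energies = scan.cumulative_energy
    radii = scan.radii
    if len(energies) < 2:
        return None
    if all(abs(e) < floor for e in energies):
        import warnings

        warnings.warn("all-zero cumulative energy series; convergence undefined")
        return None
    ok = [
        abs(energies[k] - energies[k - 1]) / max(abs(energies[k]), floor) <= threshold
        for k in range(1, len(energies))
    ]
    for k in range(1, len(energies)):
        if ok[k - 1] and (not require_hold or all(ok[k - 1:])):
            return radii[k]
    return None


def rank_and_classify(residue_ies: list[ResidueIE]) -> pd.DataFrame:
    """Rank residues by affinity: most negative IE first.

    Ties break by (chain, residue number, insertion code).  Returns a table
    with one row per residue carrying the four term energies, the combined
    interaction energy, its attractive/repulsive class and the rank.
    """
    rows = sorted(
        residue_ies,
        key=lambda x: (x.ie, x.residue_id[0], x.residue_id[1], x.residue_id[2]),
    )
    frame = pd.DataFrame(
        {
            "rank": range(1, len(rows) + 1),
            "chain": [r.residue_id[0] for r in rows],
            "number": [r.residue_id[1] for r in rows],
            "icode": [r.residue_id[2] for r in rows],
            "name": [r.residue_id[3] for r in rows],
            "label": [r.label for r in rows],
            "min_distance": [r.min_distance for r in rows],
            "e_bid_crc": [r.e_bid_crc for r in rows],
            "e_crc": [r.e_crc for r in rows],
            "e_bid_cc": [r.e_bid_cc for r in rows],
            "e_cc": [r.e_cc for r in rows],
            "ie": [r.ie for r in rows],
            "classification": [r.classification for r in rows],
            "epsilon": [r.epsilon for r in rows],
        }
    )
    return frame
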