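"""End-to-end runs: configuration, report assembly and the run manifest.

The workflow is read → pocket → quartets → energies → decomposition →
radius scan → convergence → contact annotation → reports.  Energies come
from the built-in classical backend (desk scale, needs a parameter sidecar),
or the run is split for an external quantum-chemistry engine: ``qm_decks``
writes one input deck per unique fragment and dielectric (deduplicated by
content hash — neighbouring residues share cap fragments), and
``qm_harvest`` folds the engine's outputs back in and finishes the
decomposition.

Report values are printed to 2 decimals (kcal/mol); internal precision is
full.  Identical config and inputs give byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .contacts import annotate_contacts
from .decomposition import RadiusScan, ResidueIE, decompose, radius_scan, rank_and_classify
from .energies import (
    AtomParameters,
    ClassicalBackend,
    EnergyResult,
    ParameterSet,
    QMHarvestBackend,
    QMJobSpec,
    parse_qm_output,
    write_qm_input,
)
from .fragments import build_quartet
from .structures import ComplexStructure, read_complex, select_pocket

__all__ = [
    "RunConfig",
    "run_pipeline",
    "write_reports",
    "write_decks",
    "harvest_outputs",
    "load_parameter_set",
]


@dataclass
class RunConfig:
    """One pipeline run; defaults follow the study workflow (r_max 10 Å,
    half-Ångström radius grid, dielectrics 10 and 40, 10% convergence)."""

    input: str
    ligand_resname: str
    r_max: float = 10.0
    radius_step: float = 0.5
    epsilons: tuple[float, ...] = (10.0, 40.0)
    backend: str = "classical"  # classical | qm_decks | qm_harvest
    link_atom_policy: str = "ghost"
    convergence_threshold: float = 0.10
    output_dir: str = "mfcc_out"
    seed: int = 0
    params_path: str | None = None  # classical backend parameter sidecar
    harvest_manifest: str | None = None  # qm_harvest energy table

    def __post_init__(self) -> None:
        if self.r_max <= 0:
            raise ValueError("r_max must be positive")
        if not self.epsilons:
            raise ValueError("at least one dielectric constant required")
        if not 0.0 < self.convergence_threshold < 1.0:
            raise ValueError("convergence threshold must lie in (0, 1)")
        if self.backend not in ("classical", "qm_decks", "qm_harvest"):
            raise ValueError(f"unknown backend {self.backend!r}")


def load_parameter_set(path, link_atom_policy: str = "ghost") -> ParameterSet:
    """Read the JSON parameter sidecar (serial → q/sigma/epsilon_lj)."""
    data = json.loads(Path(path).read_text())
    return ParameterSet(
        by_serial={
            int(serial): AtomParameters(p["q"], p["sigma"], p["epsilon_lj"])
            for serial, p in data.items()
        },
        link_atom_policy=link_atom_policy,
    )


def write_decks(
    complex_: ComplexStructure,
    r_max: float,
    epsilons,
    destination,
    method: str = "B97D",
    basis: str = "6-311+G(d,p)",
) -> dict:
    """One deck per unique (fragment, ε); shared cap fragments deduplicate."""
    destination = Path(destination)
    destination.mkdir(parents=True, exist_ok=True)
    jobs: dict[str, dict] = {}
    for residue in select_pocket(complex_, r_max):
        quartet = build_quartet(complex_, residue.id)
        for role in ("BID_CRC", "CRC", "BID_CC", "CC"):
            fragment = quartet[role]
            key = fragment.content_hash()
            for eps in epsilons:
                job_id = f"{key}_eps{eps:g}"
                if job_id in jobs:
                    continue
                spec = QMJobSpec.from_fragment(fragment, eps, method=method, basis=basis)
                deck_path = destination / f"{job_id}.gjf"
                write_qm_input(spec, deck_path)
                jobs[job_id] = {
                    "fragment_key": key,
                    "epsilon": eps,
                    "role": role,
                    "residue": list(residue.id),
                    "deck": deck_path.name,
                    "n_atoms": len(fragment.atoms),
                    "charge": fragment.net_charge,
                }
    manifest = {"jobs": jobs}
    (destination / "deck_manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def harvest_outputs(deck_manifest_path, outputs_dir) -> dict[tuple[str, float], EnergyResult]:
    """Parse engine outputs named after their deck ids (<job_id>.log|.out)."""
    manifest = json.loads(Path(deck_manifest_path).read_text())
    outputs_dir = Path(outputs_dir)
    table: dict[tuple[str, float], EnergyResult] = {}
    for job_id, job in manifest["jobs"].items():
        for suffix in (".log", ".out"):
            path = outputs_dir / (job_id + suffix)
            if path.exists():
                result = parse_qm_output(path, fragment_key=job["fragment_key"])
                table[(job["fragment_key"], float(job["epsilon"]))] = result
                break
    return table


def run_pipeline(config: RunConfig, annotate: bool = True) -> dict:
    """Execute the full workflow and write reports; returns the manifest.

    Nonzero fragment failures are reported in the manifest (and surface as
    a nonzero exit status in the command-line layer); the run continues
    past them.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    complex_ = read_complex(config.input, config.ligand_resname)
    pocket = select_pocket(complex_, config.r_max)

    manifest: dict = {
        "version": __version__,
        "config": asdict(config),
        "n_residues": len(complex_.residues),
        "pocket_size": len(pocket),
    }

    if config.backend == "qm_decks":
        deck_manifest = write_decks(
            complex_, config.r_max, config.epsilons, outdir / "decks"
        )
        manifest["n_decks"] = len(deck_manifest["jobs"])
        manifest["failures"] = []
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        return manifest

    if config.backend == "classical":
        if config.params_path is None:
            raise ValueError("classical backend requires params_path")
        params = load_parameter_set(config.params_path, config.link_atom_policy)
        backend = ClassicalBackend(params)
    else:  # qm_harvest
        if config.harvest_manifest is None:
            raise ValueError("qm_harvest backend requires harvest_manifest")
        table = harvest_outputs(config.harvest_manifest, Path(config.harvest_manifest).parent)
        backend = QMHarvestBackend(table)

    results: dict[float, list[ResidueIE]] = {}
    scans: dict[float, RadiusScan] = {}
    failures = []
    for eps in config.epsilons:
        ies, failed = decompose(complex_, backend, config.r_max, eps)
        results[eps] = ies
        failures.extend(
            {"residue": list(f.residue_id), "epsilon": f.epsilon, "reason": f.reason}
            for f in failed
        )
        scans[eps] = radius_scan(
            complex_, ies, config.r_max, config.radius_step, config.convergence_threshold
        )

    annotations = (
        annotate_contacts(complex_, results[config.epsilons[0]]) if annotate else []
    )
    manifest["failures"] = failures
    manifest["n_energy_evaluations"] = getattr(backend, "n_evaluations", None)
    manifest.update(
        write_reports(results, annotations, scans, outdir)
    )
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def write_reports(
    results: dict[float, list[ResidueIE]],
    annotations,
    scans: dict[float, RadiusScan],
    destination,
) -> dict:
    """Write residues.csv and scan.csv with stable column order.

    The residue table carries one row per pocket residue: identity, minimum
    ligand distance, the four term energies and combined interaction energy
    per dielectric, the attractive/repulsive class, the rank (by the first
    dielectric), and the ligand contact columns (empty when no annotations
    were computed).
    """
    destination = Path(destination)
    destination.mkdir(parents=True, exist_ok=True)
    epsilons = sorted(results)
    primary = list(results)[0]

    base = rank_and_classify(results[primary])
    frame = base[["rank", "chain", "number", "icode", "name", "label", "min_distance"]].copy()
    for eps in epsilons:
        table = rank_and_classify(results[eps]).set_index(["chain", "number", "icode"])
        table = table.reindex(
            pd.MultiIndex.from_frame(frame[["chain", "number", "icode"]])
        )
        tag = f"eps{eps:g}"
        for col in ("e_bid_crc", "e_crc", "e_bid_cc", "e_cc", "ie"):
            frame[f"{col}_{tag}"] = table[col].to_numpy()
        frame[f"classification_{tag}"] = table["classification"].to_numpy()

    ann_by_id = {a.residue_id[:3]: a for a in annotations}
    keys = list(zip(frame["chain"], frame["number"], frame["icode"]))
    if annotations:
        missing = [k for k in keys if k not in ann_by_id]
        if missing:
            raise ValueError(f"annotation join failed for residues {missing}")
    frame["nearest_ligand_atom"] = [
        ann_by_id[k].nearest_ligand_atom if k in ann_by_id else "" for k in keys
    ]
    frame["ligand_region"] = [
        (ann_by_id[k].region or "") if k in ann_by_id else "" for k in keys
    ]
    frame["contact_distance"] = [
        ann_by_id[k].distance if k in ann_by_id else float("nan") for k in keys
    ]
    frame["contact_class"] = [
        ann_by_id[k].contact_class if k in ann_by_id else "" for k in keys
    ]
    frame.to_csv(destination / "residues.csv", index=False, float_format="%.2f")

    scan_frame = None
    for eps in epsilons:
        tag = f"eps{eps:g}"
        sf = scans[eps].as_frame().rename(
            columns={
                "cumulative_energy": f"cumulative_energy_{tag}",
                "converged": f"converged_{tag}",
                "n_residues": f"n_residues_{tag}",
            }
        )
        scan_frame = sf if scan_frame is None else scan_frame.merge(sf, on="radius")
    scan_frame.to_csv(destination / "scan.csv", index=False, float_format="%.2f")

    return {
        "residues_csv": str(destination / "residues.csv"),
        "scan_csv": str(destination / "scan.csv"),
        "converged_radius": {
            f"eps{eps:g}": scans[eps].converged_radius for eps in epsilons
        },
        "total_energy": {
            f"eps{eps:g}": round(sum(ie.ie for ie in results[eps]), 6) for eps in epsilons
        },
    }
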