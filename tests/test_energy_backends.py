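"""Classical pair potential, additivity, dielectric scaling, QM deck I/O."""

import io

import numpy as np
import pytest

from mfccbind.energies import (
    AtomParameters,
    ClassicalBackend,
    MissingParameterError,
    NoEnergyError,
    ParameterSet,
    QMJobSpec,
    SingularGeometryError,
    classical_energy,
    classical_energy_components,
    pair_cross_energy,
    parse_qm_output,
    write_qm_input,
)
from mfccbind.structures import Atom


def make_atoms(positions):
    return [
        Atom(serial=i + 1, name=f"C{i + 1}", element="C", position=np.array(p, float))
        for i, p in enumerate(positions)
    ]


def charge_only_params(charges):
    return ParameterSet(
        by_serial={
            i + 1: AtomParameters(q=q, sigma=3.0, epsilon_lj=0.0)
            for i, q in enumerate(charges)
        }
    )


class TestClassicalEnergy:
    def test_unit_charges_at_calibrated_distance(self):
        atoms = make_atoms([(0, 0, 0), (3.320636, 0, 0)])
        e = classical_energy(atoms, charge_only_params([1.0, -1.0]), epsilon=1.0)
        assert e == pytest.approx(-100.0, abs=1e-9)

    def test_dielectric_screens_coulomb(self):
        atoms = make_atoms([(0, 0, 0), (3.320636, 0, 0)])
        e = classical_energy(atoms, charge_only_params([1.0, -1.0]), epsilon=40.0)
        assert e == pytest.approx(-2.5, abs=1e-9)

    def test_single_atom_fragment_is_zero(self):
        assert classical_energy(make_atoms([(0, 0, 0)]), charge_only_params([1.0]), 1.0) == 0.0

    def test_coincident_atoms_rejected(self):
        atoms = make_atoms([(0, 0, 0), (0, 0, 0)])
        with pytest.raises(SingularGeometryError):
            classical_energy(atoms, charge_only_params([1.0, 1.0]), 1.0)

    def test_missing_parameters_name_the_atom(self):
        atoms = make_atoms([(0, 0, 0), (3, 0, 0)])
        with pytest.raises(MissingParameterError, match="serial=2"):
            classical_energy(atoms, charge_only_params([1.0]), 1.0)

    def test_coulomb_part_scales_exactly_with_inverse_epsilon(self, toy_complex, toy_params):
        atoms = [a for r in toy_complex.residues for a in r.atoms]
        c10, lj10 = classical_energy_components(atoms, toy_params, 10.0)
        c40, lj40 = classical_energy_components(atoms, toy_params, 40.0)
        assert c10 == pytest.approx(4.0 * c40, rel=1e-12)
        assert lj10 == lj40


class TestCrossEnergy:
    def test_empty_set_gives_zero(self):
        atoms = make_atoms([(0, 0, 0)])
        assert pair_cross_energy(atoms, [], charge_only_params([1.0]), 1.0) == 0.0

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_additivity_identity(self, seed):
        """E(A∪B) − E(A) − E(B) equals the cross term exactly."""
        rng = np.random.default_rng(seed)
        pos = rng.uniform(0, 12, size=(14, 3))
        atoms = make_atoms(pos)
        params = ParameterSet(
            by_serial={
                i + 1: AtomParameters(
                    q=float(rng.uniform(-0.5, 0.5)),
                    sigma=float(rng.uniform(2.5, 3.5)),
                    epsilon_lj=float(rng.uniform(0.0, 0.3)),
                )
                for i in range(14)
            }
        )
        a, b = atoms[:6], atoms[6:]
        whole = classical_energy(atoms, params, 4.0)
        parts = classical_energy(a, params, 4.0) + classical_energy(b, params, 4.0)
        cross = pair_cross_energy(a, b, params, 4.0)
        assert whole - parts == pytest.approx(cross, abs=1e-9)

    def test_partition_over_residues(self, toy_complex, toy_params):
        lig = toy_complex.ligand.atoms
        protein = [a for r in toy_complex.residues for a in r.atoms]
        total = pair_cross_energy(lig, protein, toy_params, 10.0)
        per_res = sum(
            pair_cross_energy(lig, r.atoms, toy_params, 10.0) for r in toy_complex.residues
        )
        assert per_res == pytest.approx(total, abs=1e-9)


class TestEnergyCache:
    def test_identical_fragment_evaluated_once(self, toy_complex, toy_params):
        from mfccbind.fragments import build_quartet

        backend = ClassicalBackend(toy_params)
        quartet = build_quartet(toy_complex, ("A", 3, ""))
        first = backend.evaluate(quartet["CRC"], 10.0)
        count = backend.n_evaluations
        again = backend.evaluate(build_quartet(toy_complex, ("A", 3, ""))["CRC"], 10.0)
        assert backend.n_evaluations == count
        assert again.energy == first.energy


class TestQMDecks:
    def spec(self, n_atoms=1, charge=0):
        atoms = tuple(("C", float(i), 0.0, 0.0) for i in range(n_atoms))
        return QMJobSpec(atoms=atoms, charge=charge, epsilon=40.0)

    def test_charge_multiplicity_line_and_coordinates(self):
        deck = write_qm_input(self.spec())
        lines = deck.splitlines()
        assert "0 1" in lines
        coord_rows = [l for l in lines if l.startswith("C ")]
        assert len(coord_rows) == 1

    def test_route_line_carries_method_basis_solvent(self):
        deck = write_qm_input(self.spec())
        assert deck.startswith("# B97D/6-311+G(d,p) SCRF=(CPCM,Eps=40)")

    def test_byte_identical_for_identical_specs(self, tmp_path):
        a, b = tmp_path / "a.gjf", tmp_path / "b.gjf"
        write_qm_input(self.spec(n_atoms=3), a)
        write_qm_input(self.spec(n_atoms=3), b)
        assert a.read_bytes() == b.read_bytes()

    def test_atom_count_conserved(self):
        deck = write_qm_input(self.spec(n_atoms=7))
        body = deck.split("0 1\n", 1)[1]
        assert len([l for l in body.splitlines() if l.strip()]) == 7

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            QMJobSpec(atoms=(("C", 0.0, 0.0, 0.0),), charge=0, epsilon=-1.0)
        with pytest.raises(ValueError):
            QMJobSpec(atoms=(("C", 0.0, 0.0, 0.0),), charge=0, multiplicity=0)


class TestQMOutputParsing:
    def test_hartree_converted_to_kcalmol(self):
        text = "SCF Done:  E(RB97D) =  -1.000000000     A.U. after 9 cycles\nNormal termination\n"
        result = parse_qm_output(io.StringIO(text))
        assert result.energy == pytest.approx(-627.509474)
        assert result.converged

    def test_last_energy_line_wins(self):
        text = (
            "SCF Done:  E(RB97D) =  -2.000000000 A.U.\n"
            "SCF Done:  E(RB97D) =  -1.500000000 A.U.\n"
            "Normal termination of Gaussian\n"
        )
        result = parse_qm_output(io.StringIO(text))
        assert result.energy == pytest.approx(-1.5 * 627.509474)

    def test_generic_final_energy_dialect(self):
        result = parse_qm_output(io.StringIO("FINAL ENERGY = -0.500000\nNormal termination\n"))
        assert result.energy == pytest.approx(-0.5 * 627.509474)

    def test_truncated_output_flagged_unconverged(self):
        result = parse_qm_output(io.StringIO("SCF Done:  E(RB97D) =  -1.000000000 A.U.\n"))
        assert not result.converged

    def test_no_energy_line_raises(self):
        with pytest.raises(NoEnergyError, match="no energy found"):
            parse_qm_output(io.StringIO("nothing to see\n"))
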