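"""MFCC energy combination, radius scan, convergence and ranking."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mfccbind.decomposition import (
    RadiusScan,
    ResidueIE,
    classify,
    decompose,
    find_convergence,
    radius_scan,
    rank_and_classify,
    residue_interaction_energy,
)
from mfccbind.energies import ClassicalBackend, EnergyError, pair_cross_energy
from mfccbind.structures import min_distance
from mfccbind.toys import ToySpec, assign_toy_parameters, build_toy_complex


class TestInteractionEnergy:
    def test_sign_bookkeeping(self):
        assert residue_interaction_energy(-100, -40, -70, -15) == pytest.approx(-5.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(a=st.floats(-1e6, 1e6), b=st.floats(-1e6, 1e6))
    def test_cap_terms_cancel(self, a, b):
        assert residue_interaction_energy(a, a, b, b) == 0.0

    def test_non_finite_rejected(self):
        with pytest.raises(EnergyError):
            residue_interaction_energy(math.nan, 0, 0, 0)

    def test_classification_bands(self):
        assert classify(-2.0) == "attractive"
        assert classify(2.0) == "repulsive"
        assert classify(1e-9) == "neutral"


class TestDecompose:
    def test_one_entry_per_pocket_residue(self, toy_complex, toy_backend):
        ies, failures = decompose(toy_complex, toy_backend, r_max=50.0, epsilon=10.0)
        assert not failures
        assert len(ies) == len(toy_complex.residues)

    def test_mfcc_equals_bruteforce_cross_energy(self, toy_complex, toy_params, toy_backend):
        """Ghost link atoms make the cap terms cancel exactly."""
        ies, _ = decompose(toy_complex, toy_backend, r_max=50.0, epsilon=10.0)
        for ie in ies:
            res = toy_complex.residue(ie.residue_id[:3])
            direct = pair_cross_energy(toy_complex.ligand.atoms, res.atoms, toy_params, 10.0)
            assert ie.ie == pytest.approx(direct, abs=1e-9)

    def test_sum_conserves_total_cross_energy(self, toy_complex, toy_params, toy_backend):
        ies, _ = decompose(toy_complex, toy_backend, r_max=50.0, epsilon=10.0)
        protein = [a for r in toy_complex.residues for a in r.atoms]
        total = pair_cross_energy(toy_complex.ligand.atoms, protein, toy_params, 10.0)
        assert sum(ie.ie for ie in ies) == pytest.approx(total, abs=1e-9)

    def test_parameterized_links_shift_by_inner_link_cross_term(self, toy_complex, toy_spec):
        """The only MFCC error with real link hydrogens is the ligand's
        interaction with the two inner link atoms of the caps-only system."""
        from dataclasses import replace

        from mfccbind.fragments import build_quartet

        params = assign_toy_parameters(toy_complex, toy_spec)
        params_real = replace(params, link_atom_policy="parameterized")
        backend = ClassicalBackend(params_real)
        quartet = build_quartet(toy_complex, ("A", 3, ""))
        e = {r: backend.evaluate(quartet[r], 10.0).energy for r in quartet.fragments}
        ie = residue_interaction_energy(e["BID_CRC"], e["CRC"], e["BID_CC"], e["CC"])
        res = toy_complex.residue(("A", 3, ""))
        direct = pair_cross_energy(toy_complex.ligand.atoms, res.atoms, params_real, 10.0)
        inner_links = [a for a in quartet["CC"].atoms if a.is_link][2:]
        link_cross = pair_cross_energy(
            toy_complex.ligand.atoms, inner_links, params_real, 10.0
        )
        assert ie - direct == pytest.approx(-link_cross, abs=1e-9)

    def test_far_field_residue_contributes_nothing(self):
        spec = ToySpec(sequence=("GLY", "ALA", "GLY"), anchor_index=2, offset=500.0)
        cx = build_toy_complex(spec)
        backend = ClassicalBackend(assign_toy_parameters(cx, spec))
        ies, _ = decompose(cx, backend, r_max=1000.0, epsilon=10.0)
        assert all(abs(ie.ie) < 1e-6 for ie in ies)

    def test_dielectric_ordering_on_coulomb_dominated_fixture(self, toy_complex, toy_backend):
        """Weaker screening (ε = 10) gives larger cumulative magnitude."""
        ies10, _ = decompose(toy_complex, toy_backend, 50.0, 10.0)
        ies40, _ = decompose(toy_complex, toy_backend, 50.0, 40.0)
        assert abs(sum(i.ie for i in ies10)) >= abs(sum(i.ie for i in ies40))


class TestRadiusScan:
    def test_grid_is_half_angstrom(self, toy_complex, toy_backend):
        ies, _ = decompose(toy_complex, toy_backend, 10.0, 10.0)
        scan = radius_scan(toy_complex, ies, r_max=10.0)
        assert scan.radii == [0.5 * k for k in range(1, 21)]

    def test_cumulative_matches_membership(self, toy_complex, toy_params, toy_backend):
        ies, _ = decompose(toy_complex, toy_backend, 10.0, 10.0)
        scan = radius_scan(toy_complex, ies, r_max=10.0)
        by_id = {ie.residue_id[:3]: ie for ie in ies}
        for r, members, cum in zip(scan.radii, scan.residue_sets, scan.cumulative_energy):
            for rid in by_id:
                res = toy_complex.residue(rid)
                inside = min_distance(res, toy_complex.ligand) <= r + 1e-9
                assert (rid in members) == inside
            assert cum == pytest.approx(sum(by_id[rid].ie for rid in members), abs=1e-12)

    def test_sets_nested_and_total_reached(self, toy_complex, toy_backend):
        ies, _ = decompose(toy_complex, toy_backend, 10.0, 10.0)
        scan = radius_scan(toy_complex, ies, r_max=10.0)
        for smaller, larger in zip(scan.residue_sets, scan.residue_sets[1:]):
            assert set(smaller) <= set(larger)
        assert scan.cumulative_energy[-1] == pytest.approx(sum(ie.ie for ie in ies))

    def test_single_residue_energy_appears_at_covering_radius(self, toy_complex, toy_backend):
        """Cumulative energy jumps from zero exactly when the sphere first
        reaches the nearest residue."""
        ies, _ = decompose(toy_complex, toy_backend, 10.0, 10.0)
        scan = radius_scan(toy_complex, ies, r_max=10.0)
        d_min = min(
            min_distance(r, toy_complex.ligand) for r in toy_complex.residues
        )
        first_radius = 0.5 * math.ceil(d_min / 0.5)
        for r, cum in zip(scan.radii, scan.cumulative_energy):
            if r < first_radius:
                assert cum == 0.0
        k = scan.radii.index(first_radius)
        assert scan.cumulative_energy[k] != 0.0


def _scan(radii, energies):
    return RadiusScan(
        epsilon=40.0,
        radii=list(radii),
        residue_sets=[[] for _ in radii],
        cumulative_energy=list(energies),
    )


class TestConvergence:
    def test_reference_series_converges_at_third_radius(self):
        # relative changes: 50%, 6.98%, 1.8%
        scan = _scan([1, 2, 3, 4], [-10.0, -20.0, -21.5, -21.9])
        assert find_convergence(scan, threshold=0.10) == 3

    def test_constant_series_converges_immediately(self):
        scan = _scan([1, 2, 3], [-5.0, -5.0, -5.0])
        assert find_convergence(scan) == 2

    def test_alternating_series_never_converges(self):
        energies = [-8.0, -12.0, -8.0, -12.0, -8.0, -12.0]  # ±50% swings
        scan = _scan(range(1, 7), energies)
        assert find_convergence(scan) is None

    def test_transient_dip_does_not_count_when_hold_required(self):
        scan = _scan([1, 2, 3, 4], [-10.0, -10.1, -20.0, -20.1])
        assert find_convergence(scan, require_hold=True) == 4
        assert find_convergence(scan, require_hold=False) == 2

    def test_all_zero_series_warns_and_returns_none(self):
        scan = _scan([1, 2, 3], [0.0, 0.0, 0.0])
        with pytest.warns(UserWarning):
            assert find_convergence(scan) is None


def _ie(number, value, chain="A", name="GLY"):
    return ResidueIE(
        residue_id=(chain, number, "", name),
        epsilon=40.0,
        e_bid_crc=value, e_crc=0.0, e_bid_cc=0.0, e_cc=0.0,
        ie=value,
        classification=classify(value),
    )


class TestRanking:
    def test_most_attractive_first_and_repulsive_flagged(self):
        frame = rank_and_classify([_ie(1, -3.83), _ie(2, 1.26), _ie(3, -7.93)])
        assert list(frame["number"]) == [3, 1, 2]
        assert list(frame["rank"]) == [1, 2, 3]
        assert frame.iloc[-1]["classification"] == "repulsive"

    def test_ties_break_by_residue_number(self):
        frame = rank_and_classify([_ie(7, -2.0), _ie(4, -2.0)])
        assert list(frame["number"]) == [4, 7]

    def test_empty_input(self):
        assert rank_and_classify([]).empty
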