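"""Gō potential: pair terms, bonded terms, analytic forces, invariances."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar
from scipy.spatial.transform import Rotation

from gofold import (
    GoParameters,
    GoSystem,
    bonded_energy,
    native_pair_energy,
    nonnative_pair_energy,
    total_energy_forces,
)
from gofold.contacts import ContactMap, ContactPair, build_native_contacts

from conftest import toy_structure


class TestNativePair:
    def test_zero_at_sigma(self):
        assert native_pair_energy(3.5, 3.5, 0.14) == 0.0

    def test_minimum_location_and_depth_vs_numeric_oracle(self):
        # independent 1-D minimisation of the printed 12-10 form
        res = minimize_scalar(lambda r: native_pair_energy(r, 1.0, 0.14),
                              bounds=(0.9, 2.0), method="bounded",
                              options={"xatol": 1e-10})
        assert res.x == pytest.approx(np.sqrt(6.0 / 5.0), abs=1e-6)
        assert res.fun == pytest.approx(-0.2679184 * 0.14, abs=1e-6)

    def test_decays_to_zero(self):
        assert abs(native_pair_energy(1e3, 3.5, 0.14)) < 1e-20

    def test_rejects_nonpositive_r(self):
        with pytest.raises(ValueError):
            native_pair_energy(0.0, 3.5, 0.14)


class TestNonNativePair:
    def test_value_at_sigma_rep(self):
        assert nonnative_pair_energy(2.5, 2.5, 0.01) == pytest.approx(0.04)

    def test_value_at_twice_sigma_rep(self):
        assert nonnative_pair_energy(5.0, 2.5, 0.01) \
            == pytest.approx(4 * 0.01 / 4096)

    def test_strictly_decreasing(self):
        r = np.linspace(1.0, 10.0, 50)
        v = [nonnative_pair_energy(x, 2.5, 0.01) for x in r]
        assert all(a > b for a, b in zip(v, v[1:]))
        assert min(v) > 0

    def test_rejects_nonpositive_r(self):
        with pytest.raises(ValueError):
            nonnative_pair_energy(-1.0, 2.5, 0.01)


class TestBonded:
    def test_zero_at_native(self, hairpin):
        structure, _, _ = hairpin
        comps = bonded_energy(structure.coordinates(), structure)
        for v in comps.values():
            assert abs(v) < 1e-9

    def test_stretched_bond(self):
        s = toy_structure([[0, 0, 0], [1.5, 0, 0]], [1, 1], bonds=[(1, 2)])
        pos = np.array([[0, 0, 0], [1.6, 0, 0]], dtype=float)
        comps = bonded_energy(pos, s, GoParameters(k_bond=100.0))
        assert comps["bond"] == pytest.approx(1.0, rel=1e-9)

    def test_dihedral_rotated_by_pi(self):
        # butane-like chain with a +60° native dihedral
        s = toy_structure(
            [[0, 1, 1], [0, 0, 0], [1.5, 0, 0],
             [1.5 + np.cos(np.pi / 3), np.sin(np.pi / 3), 0]],
            [1, 1, 1, 1], bonds=[(1, 2), (2, 3), (3, 4)],
        )
        pos = s.coordinates()
        # rotate the last atom by pi about the central bond (x axis)
        pos[3, 1:] = -pos[3, 1:]
        comps = bonded_energy(pos, s, GoParameters(k_dihedral=1.0))
        assert comps["dihedral"] == pytest.approx(2.0, abs=1e-9)
        assert comps["bond"] == pytest.approx(0.0, abs=1e-9)
        assert comps["angle"] == pytest.approx(0.0, abs=1e-9)

    def test_colinear_triple_guarded(self):
        s = toy_structure([[0, 0, 0], [1.5, 0, 0], [2.5, 1, 0]],
                          [1, 1, 1], bonds=[(1, 2), (2, 3)])
        pos = np.array([[0, 0, 0], [1.5, 0, 0], [3.0, 0, 0]], dtype=float)
        comps = bonded_energy(pos, s)
        assert np.isfinite(comps["angle"])


class TestTotalEnergyForces:
    def test_native_term_vanishes_at_native(self, hairpin):
        # every r_ij equals sigma_ij, where the printed form crosses zero
        structure, _, cmap = hairpin
        rep = total_energy_forces(structure.coordinates(), structure, cmap)
        assert abs(rep.native_term) < 1e-12

    def test_isolated_pair_force_at_sigma(self):
        # two atoms, one native contact, no bonds: |F| = 8 eps / sigma,
        # pointing outward (the printed form still climbs toward its minimum
        # at 1.0954 sigma)
        s = toy_structure([[0, 0, 0], [3.5, 0, 0]], [1, 2])
        cmap = ContactMap(
            contacts=[ContactPair(1, 2, 3.5, (1, 2))],
            exclusions=set(), cutoff=4.0,
        )
        params = GoParameters(eps_native=0.14)
        rep = total_energy_forces(s.coordinates(), s, cmap, params)
        f = rep.forces
        assert np.linalg.norm(f[0]) == pytest.approx(8 * 0.14 / 3.5, rel=1e-6)
        assert f[0][0] < 0 and f[1][0] > 0  # lengthening the pair
        # the conventional SBM form has its minimum exactly at sigma
        rep_sbm = total_energy_forces(
            s.coordinates(), s, cmap, GoParameters(form="sbm"))
        assert np.linalg.norm(rep_sbm.forces) < 1e-12

    def test_forces_match_central_differences(self, hairpin_system):
        gs = hairpin_system
        rng = np.random.default_rng(11)
        x0 = gs.native_coords
        h = 1e-5
        for _ in range(3):
            x = x0 + rng.normal(0, 0.25, x0.shape)
            rep = gs.energy_forces(x)
            num = np.zeros_like(x)
            for a in range(x.shape[0]):
                for d in range(3):
                    xp, xm = x.copy(), x.copy()
                    xp[a, d] += h
                    xm[a, d] -= h
                    num[a, d] = -(gs.energy_forces(xp).total
                                  - gs.energy_forces(xm).total) / (2 * h)
            rel = np.linalg.norm(rep.forces - num) / np.linalg.norm(rep.forces)
            assert rel < 1e-5

    def test_rigid_body_invariance(self, hairpin_system):
        gs = hairpin_system
        x = gs.native_coords + 0.1
        rot = Rotation.from_euler("xyz", [0.3, -1.1, 2.0]).as_matrix()
        moved = x @ rot.T + np.array([5.0, -3.0, 12.0])
        e0 = gs.energy_forces(x)
        e1 = gs.energy_forces(moved)
        assert e1.total == pytest.approx(e0.total, rel=1e-9)
        # net force and net torque vanish
        assert np.abs(e0.forces.sum(axis=0)).max() < 1e-9
        torque = np.cross(x - x.mean(axis=0), e0.forces).sum(axis=0)
        assert np.abs(torque).max() < 1e-8

    def test_decomposition_sums_to_total(self, mini_system):
        gs = mini_system
        rng = np.random.default_rng(5)
        x = gs.native_coords + rng.normal(0, 0.3, gs.native_coords.shape)
        rep = gs.energy_forces(x)
        parts = (rep.native_term + rep.nonnative_term + rep.bond_term
                 + rep.angle_term + rep.dihedral_term)
        assert rep.total == pytest.approx(parts, rel=1e-12)

    def test_overlapping_nonnative_pair_rejected(self):
        s = toy_structure([[0, 0, 0], [4.5, 0, 0]], [1, 2])
        cmap = ContactMap(contacts=[], exclusions=set(), cutoff=4.0)
        pos = np.array([[0, 0, 0], [1e-9, 0, 0]])
        with pytest.raises(FloatingPointError, match="overlap"):
            total_energy_forces(pos, s, cmap)


class TestParameters:
    def test_well_ordering_enforced(self):
        with pytest.raises(ValueError):
            GoParameters(eps_native=0.01, eps_nonnative=0.14)

    def test_lambda_and_form_validated(self):
        with pytest.raises(ValueError):
            GoParameters(lambda_formed=0.9)
        with pytest.raises(ValueError):
            GoParameters(form="weird")

    def test_hash_stable_and_sensitive(self):
        assert GoParameters().hash() == GoParameters().hash()
        assert GoParameters().hash() != GoParameters(eps_native=0.2).hash()
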