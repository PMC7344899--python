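"""Gaussian well energies, analytic forces and restraint-set construction."""

import math

import numpy as np
import pytest

from cgmelt.restraints import (
    EXTENDED_BEND_CENTER,
    EXTENDED_DIHEDRAL_CENTER,
    HELICAL_BEND_CENTER,
    HELICAL_DIHEDRAL_CENTER,
    RestraintSpec,
    build_conformation_restraints,
    cartesian_forces,
    export_tabulated_potentials,
    parse_tabulated_potential,
    restraint_energy,
    restraint_internal_gradient,
    serialize_restraints,
)
from conftest import finite_difference_forces, random_chain


@pytest.fixture
def bend_spec():
    return RestraintSpec.bend((0, 1, 2), HELICAL_BEND_CENTER, depth_k=50.0)


@pytest.fixture
def dihedral_spec():
    return RestraintSpec.dihedral((0, 1, 2, 3), HELICAL_DIHEDRAL_CENTER, depth_k=50.0)


class TestEnergy:
    def test_minimum_is_minus_depth_at_center(self, bend_spec, dihedral_spec):
        assert restraint_energy(96.0, bend_spec) == pytest.approx(-50.0)
        assert restraint_energy(60.0, dihedral_spec) == pytest.approx(-50.0, rel=1e-12)

    def test_energy_above_minimum_away_from_center(self, bend_spec, rng):
        for x in rng.uniform(0, 180, size=50):
            if abs(x - 96.0) > 1e-6:
                assert restraint_energy(x, bend_spec) > -50.0

    def test_distant_evaluation_is_negligible(self, bend_spec):
        # the extended-basin center evaluated in the helical well
        v = restraint_energy(EXTENDED_BEND_CENTER, bend_spec)
        assert v == pytest.approx(-50.0 * math.exp(-(124.0 - 96.0) ** 2 / 14.0), rel=1e-12)
        assert abs(v) < 1e-20

    def test_periodic_image_consistency(self, dihedral_spec):
        assert restraint_energy(-179.0, dihedral_spec) == pytest.approx(
            restraint_energy(181.0 - 360.0, dihedral_spec), rel=1e-12
        )

    def test_dihedral_energy_continuous_across_branch_cut(self, dihedral_spec):
        jump = abs(
            restraint_energy(179.9995, dihedral_spec)
            - restraint_energy(-179.9995, dihedral_spec)
        )
        assert jump < 1e-8


class TestInternalGradient:
    def test_zero_at_center(self, bend_spec, dihedral_spec):
        assert restraint_internal_gradient(96.0, bend_spec) == 0.0
        assert restraint_internal_gradient(60.0, dihedral_spec) == 0.0

    def test_odd_around_center(self, bend_spec):
        g_plus = restraint_internal_gradient(101.0, bend_spec)
        g_minus = restraint_internal_gradient(91.0, bend_spec)
        assert g_plus == pytest.approx(-g_minus, rel=1e-12)

    @pytest.mark.parametrize("x", [50.0, 90.0, 96.0, 99.5, 130.0])
    def test_matches_finite_difference_of_energy(self, bend_spec, x):
        h = 1e-4
        num = (restraint_energy(x + h, bend_spec) - restraint_energy(x - h, bend_spec)) / (2 * h)
        ana = restraint_internal_gradient(x, bend_spec)
        assert ana == pytest.approx(num, rel=1e-6, abs=1e-18)


class TestCartesianForces:
    def test_zero_forces_at_center_pose(self):
        th = math.radians(96.0)
        pos = np.array([[0.35, 0, 0], [0, 0, 0], [0.35 * math.cos(th), 0.35 * math.sin(th), 0]])
        from cgmelt.geometry import BeadChain

        chain = BeadChain([1, 2, 3], list("AAA"), pos)
        spec = RestraintSpec.bend((0, 1, 2), 96.0)
        res = cartesian_forces(chain, spec)
        assert res.energy == pytest.approx(-50.0)
        assert np.abs(res.cartesian_forces).max() < 1e-10

    @pytest.mark.parametrize("kind", ["bend", "dihedral"])
    def test_forces_match_finite_differences(self, rng, kind):
        # wide well so random poses carry non-negligible force
        for _ in range(25):
            chain = random_chain(rng, 5)
            if kind == "bend":
                spec = RestraintSpec.bend((1, 2, 3), 96.0, width_sigma=400.0)
            else:
                spec = RestraintSpec.dihedral((0, 1, 2, 3), 60.0, width_sigma=400.0)
            ana = cartesian_forces(chain, spec).cartesian_forces
            num = finite_difference_forces(chain, spec)
            scale = max(1.0, np.abs(num).max())
            assert np.abs(ana - num).max() / scale < 1e-5

    def test_newtons_third_law_and_zero_torque(self, rng):
        for _ in range(25):
            chain = random_chain(rng, 6)
            for spec in (
                RestraintSpec.bend((0, 1, 2), 124.0, width_sigma=400.0),
                RestraintSpec.dihedral((2, 3, 4, 5), 100.0, width_sigma=400.0),
            ):
                f = cartesian_forces(chain, spec).cartesian_forces
                assert np.abs(f.sum(axis=0)).max() < 1e-10
                torque = np.cross(chain.backbone_positions, f).sum(axis=0)
                assert np.abs(torque).max() < 1e-10

    def test_uninvolved_beads_carry_zero_force(self, rng):
        chain = random_chain(rng, 8)
        spec = RestraintSpec.bend((2, 3, 4), 96.0, width_sigma=400.0)
        f = cartesian_forces(chain, spec).cartesian_forces
        assert np.all(f[[0, 1, 5, 6, 7]] == 0.0)

    def test_degenerate_geometry_raises(self):
        from cgmelt.geometry import BeadChain, DegenerateGeometryError

        pos = np.array([[0, 0, 0], [0.35, 0, 0], [0.7, 0, 0], [1.05, 1, 0]])
        chain = BeadChain([1, 2, 3, 4], list("AAAA"), pos)
        with pytest.raises(DegenerateGeometryError):
            cartesian_forces(chain, RestraintSpec.dihedral((0, 1, 2, 3), 60.0))


class TestRestraintSets:
    def test_helical_set_counts_and_centers(self):
        specs = build_conformation_restraints(30, "helical")
        bends = [s for s in specs if s.kind == "bend"]
        dihedrals = [s for s in specs if s.kind == "dihedral"]
        assert len(bends) == 28 and len(dihedrals) == 27
        assert all(s.center_deg == HELICAL_BEND_CENTER for s in bends)
        assert all(s.center_deg == HELICAL_DIHEDRAL_CENTER for s in dihedrals)
        assert all(s.periodic_images == (-300.0, 420.0) for s in dihedrals)

    def test_minimal_chain(self):
        specs = build_conformation_restraints(3, "extended")
        assert len(specs) == 1
        assert specs[0].kind == "bend" and specs[0].center_deg == EXTENDED_BEND_CENTER

    def test_too_short_chain_raises(self):
        with pytest.raises(ValueError):
            build_conformation_restraints(2, "helical")

    def test_modes_differ_only_in_centers(self):
        hel = build_conformation_restraints(10, "helical")
        ext = build_conformation_restraints(10, "extended")
        for h, e in zip(hel, ext):
            assert h.kind == e.kind
            assert h.bead_indices == e.bead_indices
            assert (h.width_sigma, h.depth_k) == (e.width_sigma, e.depth_k)
            expected = {
                ("bend"): (HELICAL_BEND_CENTER, EXTENDED_BEND_CENTER),
                ("dihedral"): (HELICAL_DIHEDRAL_CENTER, EXTENDED_DIHEDRAL_CENTER),
            }[h.kind]
            assert (h.center_deg, e.center_deg) == expected

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            RestraintSpec.bend((0, 1, 2), 200.0)
        with pytest.raises(ValueError):
            RestraintSpec.bend((0, 1, 2), 96.0, width_sigma=-1.0)
        with pytest.raises(ValueError):
            RestraintSpec.dihedral((0, 1, 2, 3), 300.0)


class TestTabulatedExport:
    def test_bend_table_layout(self, bend_spec):
        table = parse_tabulated_potential(export_tabulated_potentials(bend_spec, 1.0))
        assert table.shape == (181, 3)
        assert table[np.argmin(table[:, 1]), 0] == 96.0

    def test_dihedral_table_is_periodic(self, dihedral_spec):
        table = parse_tabulated_potential(export_tabulated_potentials(dihedral_spec, 1.0))
        assert table.shape == (361, 3)
        assert table[0, 1] == pytest.approx(table[-1, 1], abs=1e-10)

    # The 1e-3 agreement bands below are finite-difference truncation-error
    # budgets at 0.1 deg spacing; they scale linearly with K, so the checks
    # use a 5 kJ/mol well (K itself is a free parameter of the restraints).
    def test_force_column_is_negative_derivative(self):
        spec = RestraintSpec.bend((0, 1, 2), HELICAL_BEND_CENTER, depth_k=5.0)
        table = parse_tabulated_potential(export_tabulated_potentials(spec, 0.1))
        x, v, f = table.T
        num = -np.gradient(v, x)
        assert np.abs(f[1:-1] - num[1:-1]).max() < 1e-3

    def test_roundtrip_interpolation(self):
        spec = RestraintSpec.bend((0, 1, 2), HELICAL_BEND_CENTER, depth_k=5.0)
        table = parse_tabulated_potential(export_tabulated_potentials(spec, 0.1))
        for x in (95.55, 96.05, 100.333):
            v = np.interp(x, table[:, 0], table[:, 1])
            assert v == pytest.approx(restraint_energy(x, spec), abs=1e-3)

    def test_non_dividing_spacing_raises(self, bend_spec):
        with pytest.raises(ValueError):
            export_tabulated_potentials(bend_spec, 0.7)

    def test_serialization_lists_every_restraint(self):
        specs = build_conformation_restraints(5, "helical")
        text = serialize_restraints(specs, "helical")
        assert "mode: helical" in text
        assert text.count("restraint_") == len(specs)
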