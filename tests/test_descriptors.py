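import math

import numpy as np
import pytest

from stericscreen import (
    ActiveSiteSpec,
    Atom,
    BuriedVolumeParams,
    Conformer,
    EnsembleAggregation,
    RadiiTable,
    ValidationError,
    aggregate_ensemble,
    compute_angle,
    compute_bond_length,
    compute_buried_volume,
    compute_sterimol,
    mc_buried_volume_oracle,
)
from stericscreen.io import GAS_CONSTANT_KCAL

from conftest import random_cluster_conformer

CARBON_SCALED = 1.70 * 1.17  # Bondi carbon x conventional 1.17 scale


def sphere_overlap_volume(R, r, d):
    """Closed-form volume of the intersection of spheres with radii R, r at
    center distance d (spherical-cap formula)."""
    if d >= R + r:
        return 0.0
    if d <= abs(R - r):
        rr = min(R, r)
        return 4.0 / 3.0 * math.pi * rr**3
    return (
        math.pi
        * (R + r - d) ** 2
        * (d**2 + 2 * d * r - 3 * r**2 + 2 * d * R + 6 * r * R - 3 * R**2)
        / (12 * d)
    )


class TestBuriedVolume:
    def test_empty_site_is_zero_with_warning(self, caplog):
        conf = Conformer("c", [Atom("C", (0, 0, 0))])
        res = compute_buried_volume(conf, ActiveSiteSpec(0))
        assert all(v == 0.0 for v in res.percent_buried.values())

    def test_full_occlusion(self):
        # single included atom at the center with scaled radius >= R
        conf = Conformer("c", [Atom("C", (0, 0, 0)), Atom("Si", (0, 0, 0))])
        radii = RadiiTable({"C": 1.70, "Si": 2.5}, provenance="test")
        params = BuriedVolumeParams(sphere_radii=(2.5,), grid_spacing=0.1,
                                    radii_scale=1.17)
        res = compute_buried_volume(conf, ActiveSiteSpec(0), radii, params)
        assert res[2.5] == pytest.approx(100.0)

    def test_centered_carbon_ratio_of_cubes(self, centered_carbon):
        conf, site = centered_carbon
        params = BuriedVolumeParams(sphere_radii=(3.5,), grid_spacing=0.05)
        res = compute_buried_volume(conf, site, params=params)
        analytic = 100.0 * (CARBON_SCALED / 3.5) ** 3
        assert res[3.5] == pytest.approx(analytic, abs=0.3)

    def test_off_center_atom_spherical_cap(self):
        # atom partially protruding from the probe sphere
        d = 2.8
        conf = Conformer("c", [Atom("C", (0, 0, 0)), Atom("C", (0, 0, d))])
        params = BuriedVolumeParams(sphere_radii=(3.5,), grid_spacing=0.05)
        res = compute_buried_volume(conf, ActiveSiteSpec(0), params=params)
        R = 3.5
        expected = 100.0 * sphere_overlap_volume(R, CARBON_SCALED, d) / (
            4.0 / 3.0 * math.pi * R**3
        )
        assert res[3.5] == pytest.approx(expected, abs=0.3)

    def test_grid_matches_mc_oracle_on_random_fixtures(self, rng):
        params = BuriedVolumeParams(sphere_radii=(3.5,), grid_spacing=0.05)
        for k in range(20):
            conf, site = random_cluster_conformer(rng)
            grid = compute_buried_volume(conf, site, params=params)
            mc = mc_buried_volume_oracle(conf, site, params=params,
                                         n_samples=200_000, seed=k)
            tol = max(0.5, 3.0 * mc.standard_error[3.5])
            assert grid[3.5] == pytest.approx(mc[3.5], abs=tol)

    def test_bounds_and_monotone_in_scale_and_atoms(self, rng):
        conf, site = random_cluster_conformer(rng)
        vals = []
        for scale in (0.9, 1.0, 1.17, 1.3):
            params = BuriedVolumeParams(sphere_radii=(3.5,), grid_spacing=0.1,
                                        radii_scale=scale)
            v = compute_buried_volume(conf, site, params=params)[3.5]
            assert 0.0 <= v <= 100.0
            vals.append(v)
        assert vals == sorted(vals)
        # adding an atom never decreases occupancy
        bigger = Conformer("b", conf.atoms + [Atom("C", (1.0, 1.0, 1.0))])
        params = BuriedVolumeParams(sphere_radii=(3.5,), grid_spacing=0.1)
        assert (
            compute_buried_volume(bigger, site, params=params)[3.5]
            >= compute_buried_volume(conf, site, params=params)[3.5]
        )

    def test_rigid_motion_invariance(self, rng):
        conf, site = random_cluster_conformer(rng)
        params = BuriedVolumeParams(sphere_radii=(3.5,), grid_spacing=0.1)
        ref = compute_buried_volume(conf, site, params=params)[3.5]
        # random rotation + translation applied jointly to all atoms
        q = np.linalg.qr(rng.normal(size=(3, 3)))[0]
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        shift = rng.uniform(-3, 3, 3)
        moved = Conformer(
            "m",
            [Atom(a.element, tuple(q @ np.array(a.position) + shift))
             for a in conf.atoms],
        )
        got = compute_buried_volume(moved, site, params=params)[3.5]
        assert got == pytest.approx(ref, abs=0.3)

    def test_scale_invariance(self, rng):
        conf, site = random_cluster_conformer(rng, n_atoms=4)
        factor = 1.3
        scaled_conf = Conformer(
            "s",
            [Atom(a.element, tuple(np.array(a.position) * factor))
             for a in conf.atoms],
        )
        radii = RadiiTable({"C": 1.70}, provenance="test")
        radii_scaled = RadiiTable({"C": 1.70 * factor}, provenance="test-scaled")
        p1 = BuriedVolumeParams(sphere_radii=(3.5,), grid_spacing=0.05)
        p2 = BuriedVolumeParams(sphere_radii=(3.5 * factor,), grid_spacing=0.05)
        v1 = compute_buried_volume(conf, site, radii, p1)[3.5]
        v2 = compute_buried_volume(scaled_conf, site, radii_scaled, p2)[3.5 * factor]
        assert v2 == pytest.approx(v1, abs=0.3)

    def test_grid_convergence(self, rng):
        conf, site = random_cluster_conformer(rng)
        v_coarse = compute_buried_volume(
            conf, site,
            params=BuriedVolumeParams(sphere_radii=(3.5,), grid_spacing=0.1),
        )[3.5]
        v_fine = compute_buried_volume(
            conf, site,
            params=BuriedVolumeParams(sphere_radii=(3.5,), grid_spacing=0.05),
        )[3.5]
        assert abs(v_fine - v_coarse) < 0.3

    def test_hydrogen_flag_and_exclusions(self):
        atoms = [Atom("C", (0, 0, 0)), Atom("H", (0, 0, 1.0)), Atom("C", (0, 1.5, 0))]
        conf = Conformer("c", atoms)
        params = BuriedVolumeParams(sphere_radii=(3.5,), grid_spacing=0.1)
        with_h = compute_buried_volume(conf, ActiveSiteSpec(0), params=params)[3.5]
        no_h = compute_buried_volume(
            conf, ActiveSiteSpec(0),
            params=BuriedVolumeParams(sphere_radii=(3.5,), grid_spacing=0.1,
                                      include_hydrogens=False),
        )[3.5]
        proton_tagged = compute_buried_volume(
            conf, ActiveSiteSpec(0, acidic_proton_index=1), params=params
        )[3.5]
        assert no_h < with_h
        assert proton_tagged == pytest.approx(no_h)

    def test_mc_oracle_exact_extremes(self, centered_carbon):
        conf = Conformer("c", [Atom("C", (0, 0, 0))])
        res = mc_buried_volume_oracle(conf, ActiveSiteSpec(0), n_samples=100_000)
        assert all(v == 0.0 for v in res.percent_buried.values())
        full = Conformer("f", [Atom("C", (0, 0, 0)), Atom("Si", (0, 0, 0))])
        radii = RadiiTable({"C": 1.70, "Si": 2.5}, provenance="test")
        params = BuriedVolumeParams(sphere_radii=(2.5,), radii_scale=1.17)
        res = mc_buried_volume_oracle(full, ActiveSiteSpec(0), radii, params,
                                      n_samples=100_000)
        assert res[2.5] == 100.0


def brute_force_b1(perp, radii, step_deg=0.1):
    """Exhaustive rotational scan oracle for B1 in the perpendicular plane
    (perp given as 2-D coordinates)."""
    best = math.inf
    for ang in np.arange(0.0, 360.0, step_deg):
        d = np.array([math.cos(math.radians(ang)), math.sin(math.radians(ang))])
        best = min(best, max(p @ d + r for p, r in zip(perp, radii)))
    return best


class TestSterimol:
    def test_single_hydrogen(self):
        conf = Conformer("h", [Atom("C", (0, 0, 0)), Atom("H", (0, 0, 1.08))])
        res = compute_sterimol(conf, (0, 1))
        assert res.L == pytest.approx(1.08 + 1.20)
        assert res.B1 == pytest.approx(1.20)
        assert res.B5 == pytest.approx(1.20)

    def test_b1_matches_fine_scan_on_random_fixtures(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 7))
            atoms = [Atom("C", (0, 0, 0)), Atom("C", (0, 0, 1.5))]
            for _ in range(n):
                x, y = rng.uniform(-2, 2, 2)
                z = rng.uniform(0.5, 3.0)
                atoms.append(Atom("C", (x, y, z)))
            conf = Conformer("r", atoms)
            res = compute_sterimol(conf, (0, 1), angular_resolution=1.0)
            assert res.B1 <= res.B5 + 1e-9
            # independent oracle: exhaustive 0.1 degree scan in the plane
            coords = conf.coordinates[1:] - conf.coordinates[0]
            radii = [1.70] * len(coords)
            perp2d = coords[:, :2]  # axis is z here
            oracle = brute_force_b1(perp2d, radii)
            # production 1 degree scan can overshoot by one resolution step
            step_err = max(np.linalg.norm(p) for p in perp2d) * math.radians(1.0)
            assert res.B1 >= oracle - 1e-9
            assert res.B1 <= oracle + step_err + 1e-9

    def test_rotation_about_axis_invariance(self, rng):
        atoms = [Atom("C", (0, 0, 0)), Atom("C", (0, 0, 1.5)),
                 Atom("C", (1.2, 0.3, 2.0)), Atom("C", (-0.5, 1.0, 1.0))]
        conf = Conformer("p", atoms)
        ref = compute_sterimol(conf, (0, 1), angular_resolution=0.5)
        theta = rng.uniform(0, 2 * math.pi)
        c, s = math.cos(theta), math.sin(theta)
        rot = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])
        moved = Conformer(
            "q", [Atom(a.element, tuple(rot @ np.array(a.position))) for a in atoms]
        )
        got = compute_sterimol(moved, (0, 1), angular_resolution=0.5)
        assert got.L == pytest.approx(ref.L, abs=1e-9)
        assert got.B5 == pytest.approx(ref.B5, abs=1e-9)
        assert got.B1 == pytest.approx(ref.B1, abs=0.05)

    def test_no_substituent_atoms_errors(self):
        conf = Conformer("b", [Atom("C", (0, 0, 0)), Atom("C", (0, 0, 1.5))])
        with pytest.raises(ValidationError):
            compute_sterimol(conf, (0, 1), excluded_atom_indices=frozenset({1}))


class TestGeometry:
    def test_bond_length(self):
        conf = Conformer("g", [Atom("C", (0, 0, 0)), Atom("C", (1.5, 0, 0))])
        assert compute_bond_length(conf, 0, 1) == pytest.approx(1.5)

    @pytest.mark.parametrize(
        "pos_k, expected",
        [((0.0, 1.0, 0.0), 90.0), ((-1.0, 0.0, 0.0), 180.0), ((1.0, 1.0, 0.0), 45.0)],
    )
    def test_angle(self, pos_k, expected):
        conf = Conformer(
            "g", [Atom("C", (1.0, 0, 0)), Atom("C", (0, 0, 0)), Atom("C", pos_k)]
        )
        assert compute_angle(conf, 0, 1, 2) == pytest.approx(expected)

    def test_coincident_atoms_error(self):
        conf = Conformer(
            "g", [Atom("C", (0, 0, 0)), Atom("C", (0, 0, 0)), Atom("C", (1, 0, 0))]
        )
        with pytest.raises(ValidationError):
            compute_angle(conf, 0, 1, 2)


class TestEnsembleAggregation:
    @pytest.mark.parametrize("strategy", ["boltzmann", "ensemble_min", "ensemble_max"])
    def test_single_conformer(self, strategy):
        agg = EnsembleAggregation(strategy)
        assert aggregate_ensemble([42.0], [0.0], agg) == 42.0

    def test_equal_energies_boltzmann_is_mean(self):
        agg = EnsembleAggregation("boltzmann")
        assert aggregate_ensemble([10.0, 20.0], [0.3, 0.3], agg) == pytest.approx(15.0)

    def test_two_state_closed_form(self):
        # hand-evaluated two-term Boltzmann sum
        T = 298.15
        w = math.exp(-1.0 / (GAS_CONSTANT_KCAL * T))
        expected = (10.0 + 20.0 * w) / (1.0 + w)
        agg = EnsembleAggregation("boltzmann", temperature=T)
        assert aggregate_ensemble([10.0, 20.0], [0.0, 1.0], agg) == pytest.approx(
            expected, abs=1e-12
        )

    def test_extrema(self):
        vals = [3.0, 1.0, 2.0]
        assert aggregate_ensemble(vals, None, EnsembleAggregation("ensemble_min")) == 1.0
        assert aggregate_ensemble(vals, None, EnsembleAggregation("ensemble_max")) == 3.0

    def test_boltzmann_requires_energies(self):
        with pytest.raises(ValidationError, match="relative energies"):
            aggregate_ensemble([1.0, 2.0], None, EnsembleAggregation("boltzmann"))
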