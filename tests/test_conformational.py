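"""Dihedral conventions, rigid scans, torsion fits, DVR, histograms."""

import numpy as np
import pytest

import pipchain as pc
from pipchain.conformational_analysis import (backbone_dihedral_quadruples,
                                              chain_rotating_set,
                                              classify_stationary_points,
                                              cos_dihedral_histogram,
                                              dihedral, dvr_levels,
                                              end_to_end_histogram,
                                              fit_torsion,
                                              reduced_rotational_constant,
                                              scan_energies, scan_geometries)


class TestDihedral:
    def test_zigzag_backbone_is_pi(self):
        g = pc.build_alkane(4)
        th = dihedral(g, 0, 1, 2, 3)
        assert th == pytest.approx(np.pi, abs=1e-12)
        assert np.cos(th) == pytest.approx(-1.0)

    def test_planar_cis_cos_plus_one(self):
        # a "u"-shaped planar four-atom chain
        X = np.array([[0, 1, 0], [0, 0, 0], [1, 0, 0], [1, 1, 0.0]])
        th = dihedral(X, 0, 1, 2, 3)
        assert np.cos(th) == pytest.approx(1.0, abs=1e-12)

    def test_reference_quadruple_three_pi_over_two(self):
        X = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [1, 1, 1.0]])
        assert dihedral(X, 0, 1, 2, 3) == pytest.approx(3 * np.pi / 2,
                                                        abs=1e-12)

    def test_collinear_rejected(self):
        X = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0.0]])
        with pytest.raises(ValueError):
            dihedral(X, 0, 1, 2, 3)


class TestScanGeometries:
    def test_angle_zero_is_identity(self):
        g = pc.build_alkane(4)
        sc = scan_geometries(g, (1, 2), chain_rotating_set(4, (1, 2)), [0.0])
        np.testing.assert_array_equal(sc.geometries[0].coords, g.coords)

    def test_full_turn_is_identity(self):
        g = pc.build_alkane(4)
        sc = scan_geometries(g, (1, 2), chain_rotating_set(4, (1, 2)), [2 * np.pi])
        np.testing.assert_allclose(sc.geometries[0].coords, g.coords,
                                   atol=1e-12)

    def test_rigid_rotation_preserves_internal_distances(self):
        g = pc.build_alkane(4)
        rot = chain_rotating_set(4, (1, 2))
        sc = scan_geometries(g, (1, 2), rot, [1.1])
        X0, X1 = g.coords3, sc.geometries[0].coords3
        for a in rot:
            for b in rot:
                d0 = np.linalg.norm(X0[a] - X0[b])
                d1 = np.linalg.norm(X1[a] - X1[b])
                assert d1 == pytest.approx(d0, abs=1e-12)
        fixed = [a for a in range(14) if a not in rot]
        np.testing.assert_array_equal(X0[fixed], X1[fixed])

    def test_axis_atom_in_rotating_set_rejected(self):
        g = pc.build_alkane(4)
        with pytest.raises(ValueError):
            scan_geometries(g, (1, 2), [2, 3], [0.5])

    def test_scan_energy_zero_at_origin(self):
        ff = pc.ToyFF(4)
        g = pc.build_alkane(4)
        sc = scan_energies(ff, scan_geometries(g, (1, 2), chain_rotating_set(4, (1, 2)),
                                               np.linspace(0, 1, 5)))
        assert sc.energies_cm[0] == 0.0


class TestFitTorsion:
    def test_exact_threefold_recovery(self):
        phi = np.linspace(0, 2 * np.pi, 73, endpoint=False)
        e = np.sin(3 * phi - 0.2) + 5.0
        fit = fit_torsion(phi, e, "threefold")
        assert fit.params["phi0"] == pytest.approx(0.2, abs=1e-10)
        assert fit.params["offset"] == pytest.approx(5.0, abs=1e-10)
        assert fit.params["amplitude"] == pytest.approx(1.0, abs=1e-10)
        assert fit.residual_rms < 1e-10

    def test_threefold_curve_is_2pi_over_3_periodic(self):
        phi = np.linspace(0, 2 * np.pi, 73, endpoint=False)
        fit = fit_torsion(phi, np.sin(3 * phi - 1.0) + 2.0, "threefold")
        x = np.linspace(0, 2 * np.pi, 50)
        np.testing.assert_allclose(fit.predict(x),
                                   fit.predict(x + 2 * np.pi / 3),
                                   atol=1e-12)

    def test_even_poly_beats_threefold_on_double_well(self):
        """The backbone torsion of toy butane is a symmetric multi-well
        curve: the even polynomial fits far better than a threefold sine."""
        ff = pc.ToyFF(4, pc.ToyFFParams(lj_enabled=False))
        g = pc.build_alkane(4)
        angles = np.linspace(0, 2 * np.pi, 73, endpoint=False)
        sc = scan_energies(ff, scan_geometries(g, (1, 2), chain_rotating_set(4, (1, 2)),
                                               angles))
        # express against the dihedral angle (anti at pi)
        phi = np.array([dihedral(gg, 0, 1, 2, 3) for gg in sc.geometries])
        order = np.argsort(phi)
        f_even = fit_torsion(phi[order], sc.energies_cm[order], "even_poly")
        f_three = fit_torsion(phi[order], sc.energies_cm[order], "threefold")
        assert f_even.residual_rms < 0.2 * f_three.residual_rms

    def test_stationary_point_taxonomy_on_backbone_curve(self):
        """GM (anti), LM (gauche), TS1, TS2 (cis) appear in the fitted
        curve with the physical energy ordering."""
        ff = pc.ToyFF(4, pc.ToyFFParams(lj_enabled=False))
        g = pc.build_alkane(4)
        angles = np.linspace(0, 2 * np.pi, 145, endpoint=False)
        sc = scan_energies(ff, scan_geometries(g, (1, 2), chain_rotating_set(4, (1, 2)),
                                               angles))
        phi = np.array([dihedral(gg, 0, 1, 2, 3) for gg in sc.geometries])
        order = np.argsort(phi)
        fit = fit_torsion(phi[order], sc.energies_cm[order], "even_poly")
        pts = classify_stationary_points(fit)
        assert len(pts["GM"]) == 1 and len(pts["LM"]) >= 1
        assert pts["TS2"] and pts["TS1"]
        e_gm = pts["GM"][0][1]
        e_lm = min(p[1] for p in pts["LM"])
        e_ts1 = min(p[1] for p in pts["TS1"])
        e_ts2 = max(p[1] for p in pts["TS2"])
        assert e_gm < e_lm < e_ts1 < e_ts2
        assert pts["GM"][0][0] == pytest.approx(np.pi, abs=0.05)

    def test_degenerate_angles_rejected(self):
        with pytest.raises(ValueError):
            fit_torsion(np.full(10, 0.3), np.arange(10.0), "threefold")


class TestDVR:
    def test_free_rotor_spectrum(self):
        B = 7.7
        levels = dvr_levels(np.zeros(201), B)
        expect = sorted(B * m * m for m in range(-7, 8))
        np.testing.assert_allclose(levels[:15], expect, atol=1e-6 * B)

    def test_deep_harmonic_well_spacing(self):
        """For V = k phi^2 / 2 deep in a well, the lowest levels match the
        harmonic spectrum omega = sqrt(2 B k) within 0.1%."""
        B = 5.0
        k = 4.0e4
        phi = np.linspace(0, 2 * np.pi, 401, endpoint=False)
        x = np.angle(np.exp(1j * phi))      # signed displacement about 0
        V = 0.5 * k * x ** 2
        levels = dvr_levels(V, B)
        omega = np.sqrt(2.0 * B * k)
        for n in range(3):
            expect = omega * (n + 0.5)
            assert levels[n] == pytest.approx(expect, rel=1e-3)

    def test_grid_doubling_converged(self):
        phi = np.linspace(0, 2 * np.pi, 201, endpoint=False)
        V = 600.0 * 0.5 * (1 + np.cos(3 * phi))
        a = dvr_levels(V, 6.0)
        phi2 = np.linspace(0, 2 * np.pi, 403, endpoint=False)
        V2 = 600.0 * 0.5 * (1 + np.cos(3 * phi2))
        b = dvr_levels(V2, 6.0)
        np.testing.assert_allclose(a[:5], b[:5], rtol=1e-6)

    def test_even_grid_rejected(self):
        with pytest.raises(ValueError):
            dvr_levels(np.zeros(200), 1.0)

    def test_rotational_constant_positive_and_sane(self):
        g = pc.build_alkane(4)
        B = reduced_rotational_constant(g, (2, 3), [11, 12, 13])
        assert 1.0 < B < 30.0     # methyl-top torsional constants are a few cm^-1


class TestHistograms:
    def test_frozen_chain_gives_delta_distribution(self):
        g = pc.build_alkane(14)
        frames = [g.coords.copy() for _ in range(50)]
        centers, dens = end_to_end_histogram(frames, 0, 13, bins=30,
                                             range_angstrom=(10, 20))
        assert (dens > 0).sum() == 1

    def test_all_anti_chain_cos_mass_at_minus_one(self):
        g = pc.build_alkane(14)
        centers, dens = cos_dihedral_histogram([g.coords] * 10, 14, bins=40)
        assert dens.argmax() == 0          # the bin at cos = -1
        assert dens[1:].sum() == 0.0

    def test_normalization(self):
        rng = np.random.default_rng(0)
        g = pc.build_alkane(6)
        frames = [g.coords + rng.normal(scale=0.05, size=g.coords.size)
                  for _ in range(40)]
        centers, dens = end_to_end_histogram(frames, 0, 5, bins=25)
        width = centers[1] - centers[0]
        assert (dens * width).sum() == pytest.approx(1.0, abs=1e-12)

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            end_to_end_histogram([], 0, 1)

    def test_backbone_quadruples(self):
        assert backbone_dihedral_quadruples(4) == [(0, 1, 2, 3)]
        assert len(backbone_dihedral_quadruples(14)) == 11
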