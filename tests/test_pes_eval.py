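"""Gradients, Hessians, normal modes, and geometry optimization."""

import numpy as np
import pytest

import pipchain as pc
from pipchain import units
from pipchain.conformational_analysis import dihedral
from pipchain.pes_eval import (HoleDetectedError, hessian, normal_modes,
                               optimize)


class Harmonic1D:
    """Two unit-mass-scale atoms on a spring: H = k exactly along the bond."""

    def __init__(self, k=0.5, r0=2.0):
        self.k, self.r0 = k, r0

    def energy(self, g):
        r = np.linalg.norm(g.coords3[1] - g.coords3[0])
        return 0.5 * self.k * (r - self.r0) ** 2

    def gradient(self, g):
        X = g.coords3
        d = X[1] - X[0]
        r = np.linalg.norm(d)
        f = self.k * (r - self.r0) * d / r
        return np.concatenate([-f, f])


class TestHessian:
    def test_harmonic_spring_constant_recovered(self):
        model = Harmonic1D(k=0.37)
        g = pc.Geometry(["H", "H"], [0, 0, 0, 2.0, 0, 0])
        H = hessian(model, g, step=1e-4).matrix
        # along-bond diagonal block equals k to O(h^2)
        assert H[0, 0] == pytest.approx(0.37, rel=1e-6)
        assert H[3, 3] == pytest.approx(0.37, rel=1e-6)
        assert H[0, 3] == pytest.approx(-0.37, rel=1e-6)

    def test_symmetrized_and_small_asymmetry(self, butane_fragmented_model,
                                             butane_model_minimum):
        n = butane_model_minimum.coords.size
        model = butane_fragmented_model
        g = butane_model_minimum
        step = 5e-3
        raw = np.empty((n, n))
        for i in range(n):
            xp, xm = g.coords.copy(), g.coords.copy()
            xp[i] += step
            xm[i] -= step
            raw[:, i] = (model.gradient(g.with_coords(xp))
                         - model.gradient(g.with_coords(xm))) / (2 * step)
        asym = np.linalg.norm(raw - raw.T) / np.linalg.norm(raw)
        # finite-difference truncation noise at step 5e-3 keeps the raw
        # asymmetry around 1e-5 of the matrix norm on this surface
        assert asym < 1e-4
        H = hessian(model, g, step=step).matrix
        np.testing.assert_allclose(H, H.T)

    def test_nonpositive_step_rejected(self):
        with pytest.raises(ValueError):
            hessian(Harmonic1D(), pc.Geometry(["H"], [0, 0, 0]), step=0.0)


class TestNormalModes:
    def test_diatomic_closed_form(self):
        """omega = sqrt(k/mu) for a harmonic diatomic, to 1e-10."""
        k = 0.31
        model = Harmonic1D(k=k)
        g = pc.Geometry(["H", "C"], [0, 0, 0, 2.0, 0, 0])
        H = hessian(model, g, step=1e-5).matrix
        masses = [units.ATOMIC_MASS_AMU["H"], units.ATOMIC_MASS_AMU["C"]]
        freqs, _ = normal_modes(H, masses, n_remove=5)
        mu = (units.mass_au("H") * units.mass_au("C")
              / (units.mass_au("H") + units.mass_au("C")))
        expect = np.sqrt(k / mu) * units.CM_PER_HARTREE
        assert freqs[-1] == pytest.approx(expect, rel=1e-7)

    def test_translations_near_zero(self, butane_fragmented_model,
                                    butane_model_minimum):
        H = hessian(butane_fragmented_model, butane_model_minimum).matrix
        masses = [units.ATOMIC_MASS_AMU[e]
                  for e in butane_model_minimum.elements]
        all_freqs, _ = normal_modes(H, masses, n_remove=0)
        smallest = np.sort(np.abs(all_freqs))[:3]
        assert smallest.max() < 1.0   # translations within 1 cm^-1 of zero

    def test_frequencies_real_positive_at_verified_minimum(
            self, butane_fragmented_model, butane_model_minimum):
        H = hessian(butane_fragmented_model, butane_model_minimum).matrix
        masses = [units.ATOMIC_MASS_AMU[e]
                  for e in butane_model_minimum.elements]
        freqs, _ = normal_modes(H, masses)
        assert len(freqs) == 36
        assert freqs.min() > 0.0

    def test_asymmetric_input_rejected(self):
        H = np.arange(36.0).reshape(6, 6)
        with pytest.raises(ValueError):
            normal_modes(H, [1.0, 1.0])

    def test_first_order_saddle_has_one_imaginary_mode(self):
        """The eclipsed-methyl torsional saddle of toy butane shows exactly
        one negative frequency."""
        from scipy.optimize import minimize as sp_minimize
        ff = pc.ToyFF(4)
        g0 = pc.build_alkane(4)
        # rotate one methyl to eclipsed, then converge |grad|^2 -> 0
        from pipchain.conformational_analysis import scan_geometries
        rot = [11, 12, 13]                    # the C4 methyl hydrogens
        sc = scan_geometries(g0, (2, 3), rot, [np.pi / 3.0])
        start = sc.geometries[0]

        def gsq(x):
            g = start.with_coords(x)
            grad = ff.gradient(g)
            return float(grad @ grad), 2 * hessian_free_jac(ff, g, grad)

        def hessian_free_jac(model, g, grad, h=1e-6):
            out = np.empty_like(grad)
            for i in range(grad.size):
                xp = g.coords.copy()
                xp[i] += h
                out[i] = (model.gradient(g.with_coords(xp)) - grad) @ grad / h
            return out

        res = sp_minimize(gsq, start.coords.copy(), jac=True, method="L-BFGS-B",
                          options={"maxiter": 500, "gtol": 1e-12, "ftol": 0})
        sp = start.with_coords(res.x)
        assert np.abs(ff.gradient(sp)).max() < 1e-6
        H = hessian(ff, sp).matrix
        masses = [units.ATOMIC_MASS_AMU[e] for e in sp.elements]
        freqs, _ = normal_modes(H, masses)
        assert (freqs < -5.0).sum() == 1


class TestGradientInvariances:
    def test_translation_and_rotation_invariance(self, butane_fragmented_model):
        """Distance-only dependence: forces sum to zero, torque is zero, and
        the energy is invariant under rigid motion to 1e-10."""
        model = butane_fragmented_model
        rng = np.random.default_rng(11)
        g0 = pc.build_alkane(4)
        g = g0.with_coords(g0.coords + rng.normal(scale=0.1,
                                                  size=g0.coords.size))
        e0 = model.energy(g)
        G = model.gradient(g).reshape(-1, 3)
        np.testing.assert_allclose(G.sum(axis=0), 0.0, atol=1e-12)
        torque = np.cross(g.coords3, -G).sum(axis=0)
        np.testing.assert_allclose(torque, 0.0, atol=1e-10)
        # rigid translation + rotation
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th), 0],
                      [np.sin(th), np.cos(th), 0], [0, 0, 1.0]])
        Xr = g.coords3 @ R.T + np.array([3.0, -1.0, 2.0])
        assert model.energy(g.with_coords(Xr.ravel())) == pytest.approx(
            e0, abs=1e-10)


class TestOptimize:
    def test_fixed_point_at_minimum(self, butane_fragmented_model,
                                    butane_model_minimum):
        g, e = optimize(butane_fragmented_model, butane_model_minimum,
                        tol=1e-7)
        assert np.abs(butane_fragmented_model.gradient(g)).max() <= 1e-7
        assert np.abs(g.coords - butane_model_minimum.coords).max() < 1e-3

    def test_toyff_recovers_anti_dihedral_from_perturbed_start(self):
        ff = pc.ToyFF(4)
        g0 = pc.build_alkane(4)
        rng = np.random.default_rng(13)
        start = g0.with_coords(g0.coords + rng.normal(scale=0.08,
                                                      size=g0.coords.size))
        g, e = optimize(ff, start, tol=1e-8)
        phi = dihedral(g, 0, 1, 2, 3)
        assert phi == pytest.approx(np.pi, abs=1e-3)

    def test_descent_property(self):
        ff = pc.ToyFF(4)
        g0 = pc.build_alkane(4)
        rng = np.random.default_rng(14)
        start = g0.with_coords(g0.coords + rng.normal(scale=0.1,
                                                      size=g0.coords.size))
        g, e = optimize(ff, start, tol=1e-8)
        assert e <= ff.energy(start)

    def test_hole_guard_fires(self):
        class Sinkhole:
            def energy(self, g):
                return -float(g.coords @ g.coords)

            def gradient(self, g):
                return -2.0 * g.coords

        g = pc.Geometry(["C"], [1.0, 1.0, 1.0])
        with pytest.raises(HoleDetectedError):
            optimize(Sinkhole(), g, energy_floor=-100.0)
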