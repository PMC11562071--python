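"""Energy, gradient, Hessian, geometry optimization and harmonic
normal-mode analysis on any model exposing .energy / .gradient.

Hessians come from central finite differences of the analytic gradient and
are symmetrized; frequencies from the mass-weighted eigenproblem, with
imaginary modes reported as negative wavenumbers.  The optimizer is
quasi-Newton (L-BFGS-B on the analytic gradient) with a configurable energy
floor guarding against descent into unphysical holes of a fitted surface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from . import units
from .chemio import Geometry


class HoleDetectedError(RuntimeError):
    """Optimization fell below the configured energy floor."""


def gradient(model, geometry: Geometry) -> np.ndarray:
    """Analytic energy gradient of a model, hartree/bohr (3N vector)."""
    return model.gradient(geometry)


@dataclass
class HessianResult:
    matrix: np.ndarray                     # 3N x 3N, hartree/bohr^2
    frequencies: np.ndarray | None = None  # cm^-1, ascending; negative = imaginary
    modes: np.ndarray | None = None        # columns, mass-weighted


def hessian(model, geometry: Geometry, step: float = 5e-3) -> HessianResult:
    """Central differences of analytic gradients, symmetrized."""
    if step <= 0:
        raise ValueError("step must be positive")
    n = geometry.coords.size
    H = np.empty((n, n))
    for i in range(n):
        xp = geometry.coords.copy()
        xp[i] += step
        xm = geometry.coords.copy()
        xm[i] -= step
        H[:, i] = (model.gradient(geometry.with_coords(xp))
                   - model.gradient(geometry.with_coords(xm))) / (2.0 * step)
    return HessianResult(matrix=0.5 * (H + H.T))


def normal_modes(hessian_matrix: np.ndarray, masses_amu, n_remove: int = 6):
    """Harmonic wavenumbers and mass-weighted modes.

    The n_remove eigenvalues of smallest magnitude (translations/rotations;
    5 for a linear molecule) are dropped.  Returns (frequencies cm^-1
    ascending, modes as columns).
    """
    H = np.asarray(hessian_matrix, float)
    if not np.allclose(H, H.T, atol=1e-8 * max(1.0, np.abs(H).max())):
        raise ValueError("Hessian must be symmetric; symmetrize it first")
    m = np.repeat(np.asarray(masses_amu, float) * units.ME_PER_AMU, 3)
    Mw = H / np.sqrt(np.outer(m, m))
    evals, vecs = np.linalg.eigh(0.5 * (Mw + Mw.T))
    freqs = np.sign(evals) * np.sqrt(np.abs(evals)) * units.CM_PER_HARTREE
    keep = np.argsort(np.abs(freqs))[n_remove:]
    keep = keep[np.argsort(freqs[keep])]
    return freqs[keep], vecs[:, keep]


def find_minimum(model, geometry: Geometry, masses_amu, tol: float = 1e-7,
                 max_mode_follow: int = 8, displacement: float = 0.25):
    """Descend to a TRUE local minimum, following negative modes if needed.

    A fitted surface's stationary point nearest an idealized start can be a
    low-order saddle (soft torsional curvature is the hardest feature for a
    low-order basis); this helper optimizes, inspects the harmonic spectrum,
    and whenever imaginary modes remain displaces along the most negative
    mode and re-optimizes.  Returns (geometry, energy, frequencies_cm).
    """
    g, e = optimize(model, geometry, tol=tol)
    m3 = np.repeat(np.asarray(masses_amu, float) * units.ME_PER_AMU, 3)
    for _ in range(max_mode_follow):
        H = hessian(model, g)
        freqs, modes = normal_modes(H.matrix, masses_amu)
        if freqs[0] > 0.0:
            return g, e, freqs
        dx = modes[:, 0] / np.sqrt(m3)
        dx /= np.linalg.norm(dx)
        cand = []
        for sign in (+1.0, -1.0):
            gi, ei = optimize(model, g.with_coords(g.coords
                                                   + sign * displacement * dx),
                              tol=tol)
            cand.append((ei, gi))
        e, g = min(cand, key=lambda t: t[0])
    H = hessian(model, g)
    freqs, _ = normal_modes(H.matrix, masses_amu)
    return g, e, freqs


def optimize(model, geometry: Geometry, tol: float = 1e-6,
             energy_floor: float | None = None, maxiter: int = 2000):
    """Minimize the model energy; converged when max|gradient| <= tol.

    energy_floor (hartree, absolute) aborts with HoleDetectedError if the
    line search dives below it — the telltale of a hole in a fitted PES.
    Returns (optimized Geometry carrying the energy, energy).
    """
    e0 = model.energy(geometry)
    if not np.isfinite(e0):
        raise ValueError("non-finite starting energy")

    def fun(x):
        g = geometry.with_coords(x)
        e = model.energy(g)
        if energy_floor is not None and e < energy_floor:
            raise HoleDetectedError(
                f"energy {e:.6f} fell below the floor {energy_floor:.6f}")
        return e, model.gradient(g)

    res = minimize(fun, geometry.coords.copy(), jac=True, method="L-BFGS-B",
                   options={"maxiter": maxiter, "gtol": tol, "ftol": 0.0})
    out = geometry.with_coords(res.x)
    out.energy = float(res.fun)
    gmax = float(np.abs(res.jac).max())
    if gmax > tol:
        # polish with a few steepest-descent/line-search steps if needed
        res = minimize(fun, res.x, jac=True, method="L-BFGS-B",
                       options={"maxiter": maxiter, "gtol": tol * 0.1,
                                "ftol": 0.0})
        out = geometry.with_coords(res.x)
        out.energy = float(res.fun)
    return out, out.energy
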