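"""Torsional scans, dihedral fits, 1D torsional DVR, and trajectory
distribution observables for chain alkanes.

Conventions: the dihedral angle of four atoms i-j-k-l is the signed angle
between the (i,j,k) and (j,k,l) planes, mapped to [0, 2pi); the all-anti
zigzag backbone sits at theta = pi (cos theta = -1) and the planar cis
("u"-shaped) arrangement at cos theta = +1.  Scans are unrelaxed: one side
of a C-C bond is rotated rigidly about the bond axis while the other side
stays frozen, so all internal coordinates within each side are preserved
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh

from . import units
from .chemio import Geometry


def dihedral(geometry_or_coords, i: int, j: int, k: int, l: int) -> float:
    """Signed dihedral of atoms i-j-k-l mapped to [0, 2pi)."""
    X = getattr(geometry_or_coords, "coords3", None)
    if X is None:
        X = np.asarray(geometry_or_coords, float).reshape(-1, 3)
    b1 = X[j] - X[i]
    b2 = X[k] - X[j]
    b3 = X[l] - X[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise ValueError("collinear atoms: dihedral undefined")
    nb2 = np.linalg.norm(b2)
    phi = -np.arctan2(np.dot(np.cross(n1, n2), b2) / nb2, np.dot(n1, n2))
    return float(phi % (2.0 * np.pi))


@dataclass
class TorsionScan:
    axis: tuple[int, int]
    rotating_set: tuple[int, ...]
    angles: np.ndarray                   # radians
    geometries: list[Geometry]
    energies_cm: np.ndarray | None = None  # relative to the reference


def scan_geometries(geometry: Geometry, axis: tuple[int, int], rotating_set,
                    angles) -> TorsionScan:
    """Rigid (unrelaxed) rotation of one side of a bond about its axis.

    rotating_set lists the atoms rotated; it must not contain the axis
    atoms themselves.  Angle 0 reproduces the input geometry exactly.
    """
    j, k = axis
    rot = tuple(rotating_set)
    if j in rot or k in rot:
        raise ValueError("rotating_set must not contain the axis atoms")
    X0 = geometry.coords3
    a = X0[k] - X0[j]
    a = a / np.linalg.norm(a)
    geoms = []
    angles = np.asarray(angles, float)
    for ang in angles:
        if ang == 0.0:
            geoms.append(geometry.with_coords(X0.ravel().copy()))
            continue
        c, s = np.cos(ang), np.sin(ang)
        K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
        R = np.eye(3) + s * K + (1 - c) * (K @ K)     # Rodrigues
        X = X0.copy()
        X[list(rot)] = (X0[list(rot)] - X0[j]) @ R.T + X0[j]
        geoms.append(geometry.with_coords(X.ravel()))
    return TorsionScan(axis=(j, k), rotating_set=rot, angles=angles,
                       geometries=geoms)


def scan_energies(model, scan: TorsionScan) -> TorsionScan:
    """Model energies along a scan, cm^-1 relative to the angle-0 point."""
    e = np.array([model.energy(g) for g in scan.geometries])
    scan.energies_cm = (e - e[0]) * units.CM_PER_HARTREE
    return scan


@dataclass
class TorsionFit:
    """Fitted 1D torsional potential.

    form "threefold": V = amplitude * sin(3 phi - phi0) + offset (exactly
    2pi/3-periodic).  form "even_poly": V = sum of even powers of
    (theta - pi) up to 12.  residual_rms in the units of the input.
    """

    form: str
    params: dict
    residual_rms: float

    def predict(self, angles) -> np.ndarray:
        phi = np.asarray(angles, float)
        if self.form == "threefold":
            return (self.params["amplitude"]
                    * np.sin(3.0 * phi - self.params["phi0"])
                    + self.params["offset"])
        coef = self.params["coefficients"]
        x = phi - np.pi
        return sum(c * x ** (2 * n) for n, c in enumerate(coef))


def fit_torsion(angles, energies, form: str = "threefold") -> TorsionFit:
    """Least-squares fit of a scan to a threefold sine or an even polynomial.

    The threefold form A sin(3 phi - phi0) + a is linearized over
    (A cos phi0, A sin phi0, a); data generated from sin(3 phi - phi0) + a
    is recovered exactly with A = 1.
    """
    phi = np.asarray(angles, float)
    e = np.asarray(energies, float)
    if form == "threefold":
        if len(phi) < 3:
            raise ValueError("need at least 3 points")
        M = np.stack([np.sin(3 * phi), -np.cos(3 * phi), np.ones_like(phi)],
                     axis=1)
        _check_rank(M)
        (b1, b2, a), *_ = np.linalg.lstsq(M, e, rcond=None)
        A = float(np.hypot(b1, b2))
        phi0 = float(np.arctan2(b2, b1) % (2 * np.pi))
        fit = TorsionFit("threefold",
                         {"amplitude": A, "phi0": phi0, "offset": float(a)},
                         0.0)
    elif form == "even_poly":
        if len(phi) < 7:
            raise ValueError("need at least 7 points")
        x = phi - np.pi
        M = np.stack([x ** (2 * n) for n in range(7)], axis=1)
        _check_rank(M)
        coef, *_ = np.linalg.lstsq(M, e, rcond=None)
        fit = TorsionFit("even_poly", {"coefficients": list(map(float, coef))},
                         0.0)
    else:
        raise ValueError(f"unknown form {form!r}")
    fit.residual_rms = float(np.sqrt(np.mean((fit.predict(phi) - e) ** 2)))
    return fit


def _check_rank(M):
    if np.linalg.matrix_rank(M) < M.shape[1]:
        raise ValueError("rank-deficient torsion fit (degenerate angles)")


def classify_stationary_points(fit: TorsionFit, n_grid: int = 20001,
                               angle_tol: float = 1e-3) -> dict:
    """Stationary points of a FITTED curve on [0, 2pi), labeled
    GM / LM / TS1 / TS2.

    Minima and maxima come from sign changes of the numerical derivative of
    the fitted form on a dense grid, refined by bisection to angle_tol.
    The lowest minimum is GM and other minima LM; maxima below the highest
    are TS1 (saddles between GM and LM) and the highest is TS2 (the barrier
    to free rotation).  Returns {"GM": [...], "LM": [...], "TS1": [...],
    "TS2": [...]} with (angle, energy) entries.
    """
    phi = np.linspace(0.0, 2.0 * np.pi, n_grid, endpoint=False)
    h = phi[1] - phi[0]
    v = fit.predict(phi)
    dv = (np.roll(v, -1) - np.roll(v, 1)) / (2 * h)
    mins, maxs = [], []
    for i in range(n_grid):
        a, b = dv[i], dv[(i + 1) % n_grid]
        if a == 0.0 or a * b >= 0:
            continue
        lo, hi = phi[i], phi[i] + h

        def deriv(x):
            eps = angle_tol / 10
            return (fit.predict(x + eps) - fit.predict(x - eps)) / (2 * eps)

        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if deriv(lo) * deriv(mid) <= 0:
                hi = mid
            else:
                lo = mid
            if hi - lo < angle_tol / 10:
                break
        x = 0.5 * (lo + hi) % (2 * np.pi)
        curv = (fit.predict(x + angle_tol) - 2 * fit.predict(x)
                + fit.predict(x - angle_tol))
        (mins if curv > 0 else maxs).append((float(x), float(fit.predict(x))))
    mins.sort(key=lambda t: t[1])
    maxs.sort(key=lambda t: t[1])
    out = {"GM": mins[:1], "LM": mins[1:], "TS1": [], "TS2": []}
    if maxs:
        top = maxs[-1][1]
        out["TS2"] = [m for m in maxs if abs(m[1] - top) < 1e-6]
        out["TS1"] = [m for m in maxs if abs(m[1] - top) >= 1e-6]
    return out


def reduced_rotational_constant(geometry: Geometry, axis, rotating_set) -> float:
    """Effective rotational constant B (cm^-1) for torsion about a bond.

    Both sides' moments of inertia about the bond axis are combined as a
    reduced moment I = I1 I2/(I1 + I2); B = 1/(2I) in hartree, reported in
    cm^-1.
    """
    j, k = axis
    X = geometry.coords3
    a = X[k] - X[j]
    a /= np.linalg.norm(a)
    m = np.array([units.mass_au(e) for e in geometry.elements])

    def inertia(atom_set):
        tot = 0.0
        for i in atom_set:
            d = X[i] - X[j]
            perp = d - (d @ a) * a
            tot += m[i] * (perp @ perp)
        return tot

    rot = set(rotating_set)
    other = set(range(geometry.n_atoms)) - rot - {j, k}
    i1, i2 = inertia(rot), inertia(other)
    if i1 <= 0 or i2 <= 0:
        raise ValueError("degenerate top: zero moment of inertia")
    red = i1 * i2 / (i1 + i2)
    return 0.5 / red * units.CM_PER_HARTREE


def dvr_levels(potential_cm, rotational_constant_cm: float) -> np.ndarray:
    """Torsional eigenvalues of -B d^2/dphi^2 + V(phi) on a periodic grid.

    Uses the periodic (Colbert-Miller style) DVR kinetic matrix for an odd
    number of uniformly spaced points on [0, 2pi); eigenvalues return in
    cm^-1, ascending.  V = 0 gives the free-rotor spectrum B m^2 with the
    correct twofold degeneracy.
    """
    V = np.asarray(potential_cm, float)
    N = len(V)
    if N % 2 == 0:
        raise ValueError("need an odd number of grid points")
    B = rotational_constant_cm
    mhalf = (N - 1) // 2
    T = np.empty((N, N))
    idx = np.arange(N)
    for d in range(N):
        if d == 0:
            T[idx, idx] = B * mhalf * (mhalf + 1) / 3.0
        else:
            val = (B * (-1.0) ** d * np.cos(np.pi * d / N)
                   / (2.0 * np.sin(np.pi * d / N) ** 2))
            T[idx[:-d], idx[:-d] + d] = val
            T[idx[:-d] + d, idx[:-d]] = val
    return np.sort(eigh(T + np.diag(V), eigvals_only=True))


def end_to_end_histogram(frames, i: int, j: int, bins=50, range_angstrom=None):
    """Distribution of the distance between atoms i and j over pooled frames.

    Returns (bin centers in angstrom, probability density per angstrom):
    probabilities per bin divided by the bin width, summing (x width) to 1.
    """
    if not frames:
        raise ValueError("empty frame pool")
    d = np.array([np.linalg.norm(x.reshape(-1, 3)[i] - x.reshape(-1, 3)[j])
                  for x in frames]) * units.ANGSTROM_PER_BOHR
    counts, edges = np.histogram(d, bins=bins, range=range_angstrom)
    width = np.diff(edges)
    density = counts / counts.sum() / width
    return 0.5 * (edges[1:] + edges[:-1]), density


def chain_rotating_set(n_carbons: int, bond: tuple[int, int]) -> list[int]:
    """Atoms on the far side of a backbone C-C bond, for a torsional scan.

    For bond (j, k) with k = j + 1 the rotating side is k's hydrogens plus
    every higher carbon and its hydrogens: the axis carbons themselves stay
    (rotation about the axis leaves them fixed), but the substituents of k
    must rotate or the scan would distort bond angles at k.
    """
    from .synthetic_data import carbon_hydrogens
    j, k = bond
    if not (0 <= j < k < n_carbons and k == j + 1):
        raise ValueError("bond must be an adjacent backbone pair (j, j+1)")
    hyd = carbon_hydrogens(n_carbons)
    out = list(hyd[k])
    for c in range(k + 1, n_carbons):
        out.append(c)
        out.extend(hyd[c])
    return sorted(out)


def backbone_dihedral_quadruples(n_carbons: int) -> list[tuple[int, int, int, int]]:
    """(i, j, k, l) quadruples around every interior C-C bond of a chain."""
    return [(c - 1, c, c + 1, c + 2) for c in range(1, n_carbons - 2)]


def cos_dihedral_histogram(frames, n_carbons: int, bins=40):
    """Pooled distribution of cos(theta) over all backbone dihedrals.

    Returns (bin centers, probability density per unit cos theta).
    """
    if not frames:
        raise ValueError("empty frame pool")
    quads = backbone_dihedral_quadruples(n_carbons)
    if not quads:
        raise ValueError("chain too short for backbone dihedrals")
    vals = []
    for x in frames:
        for (i, j, k, l) in quads:
            vals.append(np.cos(dihedral(x, i, j, k, l)))
    counts, edges = np.histogram(vals, bins=bins, range=(-1.0, 1.0))
    width = np.diff(edges)
    density = counts / counts.sum() / width
    return 0.5 * (edges[1:] + edges[:-1]), density
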