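"""Toy analytic alkane force field and dataset generators.

This module is the desk-scale stand-in for an external sampling engine plus
an electronic-structure labeler: a smooth, size-consistent valence force
field (harmonic bonds and angles, cosine torsions, Lennard-Jones nonbonded
with 1-4 exclusion) with analytic gradients, plus samplers that produce
labeled datasets with the statistical shape PES fits assume — a
concentration of low-energy frames with a broad high-energy tail.

It makes no claim of chemical accuracy.  Parameters are chosen to give
realistic C-C/C-H length scales, a roughly 1,200 cm^-1 threefold methyl
barrier, and the anti/gauche/cis stationary-point topology of real alkane
backbones (global minimum at the anti conformation, gauche local minima, a
saddle between them, and a higher cis saddle).

Atom numbering convention (0-based): carbons 0..nc-1 along the chain, then
hydrogens in carbon order — three on the first carbon, two on each interior
carbon, three on the last.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import units
from .chemio import DatasetFile, Geometry

TETRAHEDRAL = float(np.arccos(-1.0 / 3.0))  # 109.471 deg
R0_CC = 1.54 * units.BOHR_PER_ANGSTROM
R0_CH = 1.09 * units.BOHR_PER_ANGSTROM


@dataclass(frozen=True)
class ToyFFParams:
    """Force-field parameters; energies hartree, lengths bohr, angles rad.

    torsion_v3_cm is the TOTAL threefold barrier of a C-C bond (split evenly
    over its substituent quadruples, which are in phase at tetrahedral
    geometry); torsion_v1_cm applies to the carbon-backbone quadruple only
    and breaks the anti/gauche degeneracy.  lj pairs separated by fewer than
    four bonds are excluded.
    """

    bond_k: dict = field(default_factory=lambda: {"CC": 0.30, "CH": 0.34})
    bond_r0: dict = field(default_factory=lambda: {"CC": R0_CC, "CH": R0_CH})
    angle_k: dict = field(default_factory=lambda: {
        "CCC": 0.25, "CCH": 0.20, "HCH": 0.15})
    angle_theta0: dict = field(default_factory=lambda: {
        "CCC": TETRAHEDRAL, "CCH": TETRAHEDRAL, "HCH": TETRAHEDRAL})
    torsion_v3_cm: dict = field(default_factory=lambda: {
        "backbone": 1100.0, "methyl": 1200.0})
    torsion_v1_cm: float = 500.0
    lj_epsilon: dict = field(default_factory=lambda: {
        "CC": 1.1e-4, "CH": 7.0e-5, "HH": 4.8e-5})
    lj_sigma: dict = field(default_factory=lambda: {
        "CC": 3.40 * units.BOHR_PER_ANGSTROM,
        "CH": 3.00 * units.BOHR_PER_ANGSTROM,
        "HH": 2.60 * units.BOHR_PER_ANGSTROM})
    lj_enabled: bool = True


DEFAULT_TOY_PARAMS = ToyFFParams()


@dataclass
class SamplerConfig:
    mode: str = "thermal_md"                  # | mode_displacement | head_to_tail_grid
    temperatures: tuple = (500.0, 1000.0, 2500.0)   # K, thermal ladder
    displacement_scale: float = 1.0           # multiplies thermal mode amplitudes
    displacement_temperature: float = 300.0   # K, for mode_displacement
    n_frames: int = 1000
    seed: int = 0
    ceiling_cm: float | None = 80_000.0
    dt_fs: float = 0.5
    stride: int = 20
    burn_in: int = 200
    grid_angstrom: tuple = ()                 # head-to-tail targets

    def __post_init__(self):
        if self.n_frames <= 0:
            raise ValueError("n_frames must be positive")


# -- topology and construction -------------------------------------------


def alkane_elements(n_carbons: int) -> list[str]:
    return ["C"] * n_carbons + ["H"] * (2 * n_carbons + 2)


def carbon_hydrogens(n_carbons: int) -> list[list[int]]:
    """Hydrogen indices attached to each carbon, in the numbering convention."""
    nc = n_carbons
    if nc == 1:
        return [[1, 2, 3, 4]]
    out = [list(range(nc, nc + 3))]
    pos = nc + 3
    for _ in range(1, nc - 1):
        out.append([pos, pos + 1])
        pos += 2
    out.append([pos, pos + 1, pos + 2])
    return out


def alkane_bonds(n_carbons: int) -> list[tuple[int, int]]:
    bonds = [(k, k + 1) for k in range(n_carbons - 1)]
    for c, hs in enumerate(carbon_hydrogens(n_carbons)):
        bonds.extend((c, h) for h in hs)
    return bonds


def build_alkane(n_carbons: int) -> Geometry:
    """Idealized all-anti (zigzag) alkane with tetrahedral angles.

    Backbone dihedrals are exactly pi and every methyl group is staggered,
    so the construction sits at the minimum of the bonded part of the toy
    force field.
    """
    if n_carbons < 1:
        raise ValueError("need at least one carbon")
    nc = n_carbons
    half = TETRAHEDRAL / 2.0
    u = [np.array([np.sin(half), 0.0, np.cos(half)]),
         np.array([np.sin(half), 0.0, -np.cos(half)])]
    C = [np.zeros(3)]
    for k in range(1, nc):
        C.append(C[-1] + R0_CC * u[k % 2])
    C = np.array(C)

    def methyl(ci, cj):
        a = C[ci] - C[cj]
        a /= np.linalg.norm(a)
        p = np.array([-a[2], 0.0, a[0]])
        p /= np.linalg.norm(p)
        q = np.cross(a, p)
        th = np.pi - TETRAHEDRAL
        out = []
        for i in range(3):
            phi = np.pi + 2.0 * np.pi * i / 3.0   # one H anti to the chain
            d = np.cos(th) * a + np.sin(th) * (np.cos(phi) * p + np.sin(phi) * q)
            out.append(C[ci] + R0_CH * d)
        return out

    def methylene(ci):
        e1 = C[ci - 1] - C[ci]
        e1 /= np.linalg.norm(e1)
        e2 = C[ci + 1] - C[ci]
        e2 /= np.linalg.norm(e2)
        b = -(e1 + e2)
        b /= np.linalg.norm(b)
        w = np.cross(e1, e2)
        w /= np.linalg.norm(w)
        hh = TETRAHEDRAL
        return [C[ci] + R0_CH * (np.cos(hh / 2) * b + np.sin(hh / 2) * w),
                C[ci] + R0_CH * (np.cos(hh / 2) * b - np.sin(hh / 2) * w)]

    if nc == 1:
        dirs = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]],
                        float) / np.sqrt(3.0)
        H = [C[0] + R0_CH * d for d in dirs]
    else:
        H = methyl(0, 1)
        for k in range(1, nc - 1):
            H += methylene(k)
        H += methyl(nc - 1, nc - 2)
    coords = np.vstack([C, np.array(H)])
    return Geometry(alkane_elements(nc), coords.ravel(), tag="zigzag")


# -- internal coordinate terms with analytic gradients --------------------


def _angle_terms(nc):
    """(i, j, k, type) with j the center, from the bonded topology."""
    neigh = {a: [] for a in range(3 * nc + 2)}
    for i, j in alkane_bonds(nc):
        neigh[i].append(j)
        neigh[j].append(i)
    els = alkane_elements(nc)
    terms = []
    for j, nb in neigh.items():
        for x in range(len(nb)):
            for y in range(x + 1, len(nb)):
                i, k = nb[x], nb[y]
                t = "".join(sorted((els[i], els[k])))
                terms.append((i, j, k, {"CC": "CCC", "CH": "CCH",
                                        "HH": "HCH"}[t]))
    return terms


def _torsion_terms(nc):
    """(i, j, k, l, amplitude_key, n_quadruples_of_bond, is_backbone)."""
    hyd = carbon_hydrogens(nc)
    terms = []
    for b in range(nc - 1):
        j, k = b, b + 1
        left = ([j - 1] if j > 0 else []) + hyd[j]
        right = ([k + 1] if k < nc - 1 else []) + hyd[k]
        terminal = (j == 0) or (k == nc - 1)
        key = "methyl" if terminal else "backbone"
        nquad = len(left) * len(right)
        for i in left:
            for l in right:
                backbone = i < nc and l < nc
                terms.append((i, j, k, l, key, nquad, backbone))
    return terms


def _dihedral_and_grad(p0, p1, p2, p3):
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    phi = np.arctan2(np.dot(np.cross(n1, n2), b2) / nb2, np.dot(n1, n2))
    t0 = -nb2 / np.dot(n1, n1) * n1
    t3 = nb2 / np.dot(n2, n2) * n2
    a = np.dot(b1, b2) / (nb2 * nb2)
    b = np.dot(b3, b2) / (nb2 * nb2)
    t1 = -t0 - a * t0 + b * t3
    t2 = -t3 + a * t0 - b * t3
    return phi, (t0, t1, t2, t3)


class ToyFF:
    """Callable toy force field bound to one alkane topology.

    Provides .energy(geometry) and .gradient(geometry) in hartree and
    hartree/bohr, so it can stand wherever a fitted model is expected.
    """

    kind = "toyff"

    def __init__(self, n_carbons: int, params: ToyFFParams | None = None):
        self.n_carbons = n_carbons
        self.params = params or DEFAULT_TOY_PARAMS
        self.n_atoms = 3 * n_carbons + 2
        els = alkane_elements(n_carbons)
        self._bonds = [(i, j, "CC" if els[i] == els[j] == "C" else "CH")
                       for i, j in alkane_bonds(n_carbons)]
        self._angles = _angle_terms(n_carbons)
        self._torsions = _torsion_terms(n_carbons)
        self._nb_pairs = self._nonbonded_pairs(els)

    def _nonbonded_pairs(self, els):
        n = self.n_atoms
        adj = {a: set() for a in range(n)}
        for i, j, _ in self._bonds:
            adj[i].add(j)
            adj[j].add(i)
        dist = np.full((n, n), 99, dtype=int)
        for src in range(n):  # BFS bond-path distances (graph is tiny)
            dist[src, src] = 0
            frontier = [src]
            d = 0
            while frontier:
                d += 1
                nxt = []
                for a in frontier:
                    for b in adj[a]:
                        if dist[src, b] > d:
                            dist[src, b] = d
                            nxt.append(b)
                frontier = nxt
        pairs = []
        for i in range(n):
            for j in range(i + 1, n):
                if dist[i, j] >= 4:
                    t = "".join(sorted((els[i], els[j])))
                    pairs.append((i, j, {"CC": "CC", "CH": "CH",
                                         "HH": "HH"}[t]))
        return pairs

    def _index_arrays(self):
        """Flatten the term lists into numpy index/parameter arrays once."""
        p = self.params
        cm = units.HARTREE_PER_CM
        b = self._bonds
        self._b_i = np.array([t[0] for t in b])
        self._b_j = np.array([t[1] for t in b])
        self._b_k = np.array([p.bond_k[t[2]] for t in b])
        self._b_r0 = np.array([p.bond_r0[t[2]] for t in b])
        a = self._angles
        self._a_i = np.array([t[0] for t in a])
        self._a_j = np.array([t[1] for t in a])
        self._a_k = np.array([t[2] for t in a])
        self._a_kf = np.array([p.angle_k[t[3]] for t in a])
        self._a_t0 = np.array([p.angle_theta0[t[3]] for t in a])
        t = self._torsions
        self._t_idx = np.array([[q[0], q[1], q[2], q[3]] for q in t])
        self._t_v3 = np.array([p.torsion_v3_cm[q[4]] * cm / q[5] for q in t])
        self._t_v1 = np.array([p.torsion_v1_cm * cm if q[6] else 0.0
                               for q in t])
        nb = self._nb_pairs
        self._nb_i = np.array([q[0] for q in nb], dtype=int)
        self._nb_j = np.array([q[1] for q in nb], dtype=int)
        self._nb_eps = np.array([p.lj_epsilon[q[2]] for q in nb])
        self._nb_s2 = np.array([p.lj_sigma[q[2]] ** 2 for q in nb])

    def energy_gradient(self, geometry: Geometry):
        if not hasattr(self, "_b_i"):
            self._index_arrays()
        X = geometry.coords3
        G = np.zeros_like(X)
        # bonds
        d = X[self._b_i] - X[self._b_j]
        r = np.sqrt((d * d).sum(1))
        dr = r - self._b_r0
        E = float(0.5 * (self._b_k * dr * dr).sum())
        f = (self._b_k * dr / r)[:, None] * d
        np.add.at(G, self._b_i, f)
        np.add.at(G, self._b_j, -f)
        # angles
        u = X[self._a_i] - X[self._a_j]
        v = X[self._a_k] - X[self._a_j]
        nu = np.sqrt((u * u).sum(1))
        nv = np.sqrt((v * v).sum(1))
        uh = u / nu[:, None]
        vh = v / nv[:, None]
        c = np.clip((uh * vh).sum(1), -1.0, 1.0)
        s = np.sqrt(np.maximum(1.0 - c * c, 1e-14))
        dth = np.arccos(c) - self._a_t0
        E += float(0.5 * (self._a_kf * dth * dth).sum())
        coef = (self._a_kf * dth)
        di = (c[:, None] * uh - vh) / (nu * s)[:, None]
        dk = (c[:, None] * vh - uh) / (nv * s)[:, None]
        np.add.at(G, self._a_i, coef[:, None] * di)
        np.add.at(G, self._a_k, coef[:, None] * dk)
        np.add.at(G, self._a_j, -coef[:, None] * (di + dk))
        # torsions (batched dihedral + gradient)
        P = X[self._t_idx]                      # [M, 4, 3]
        b1 = P[:, 1] - P[:, 0]
        b2 = P[:, 2] - P[:, 1]
        b3 = P[:, 3] - P[:, 2]
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        nb2 = np.sqrt((b2 * b2).sum(1))
        phi = np.arctan2((np.cross(n1, n2) * b2).sum(1) / nb2,
                         (n1 * n2).sum(1))
        E += float((0.5 * self._t_v3 * (1.0 + np.cos(3.0 * phi))).sum())
        E += float((0.5 * self._t_v1 * (1.0 + np.cos(phi))).sum())
        dV = (-1.5 * self._t_v3 * np.sin(3.0 * phi)
              - 0.5 * self._t_v1 * np.sin(phi))
        t0 = -(nb2 / (n1 * n1).sum(1))[:, None] * n1
        t3 = (nb2 / (n2 * n2).sum(1))[:, None] * n2
        aa = ((b1 * b2).sum(1) / (nb2 * nb2))[:, None]
        bb = ((b3 * b2).sum(1) / (nb2 * nb2))[:, None]
        t1 = -t0 - aa * t0 + bb * t3
        t2 = -t3 + aa * t0 - bb * t3
        dVc = dV[:, None]
        np.add.at(G, self._t_idx[:, 0], dVc * t0)
        np.add.at(G, self._t_idx[:, 1], dVc * t1)
        np.add.at(G, self._t_idx[:, 2], dVc * t2)
        np.add.at(G, self._t_idx[:, 3], dVc * t3)
        # nonbonded LJ 12-6, pairs >= 4 bonds apart
        if self.params.lj_enabled and len(self._nb_i):
            d = X[self._nb_i] - X[self._nb_j]
            r2 = (d * d).sum(1)
            s6 = (self._nb_s2 / r2) ** 3
            E += float((4.0 * self._nb_eps * (s6 * s6 - s6)).sum())
            dEdr2 = 4.0 * self._nb_eps * (3.0 * s6 - 6.0 * s6 * s6) / r2
            f = (2.0 * dEdr2)[:, None] * d
            np.add.at(G, self._nb_i, f)
            np.add.at(G, self._nb_j, -f)
        return E, G.ravel()

    def energy(self, geometry: Geometry) -> float:
        return self.energy_gradient(geometry)[0]

    def gradient(self, geometry: Geometry) -> np.ndarray:
        return self.energy_gradient(geometry)[1]


def toy_energy_gradient(params: ToyFFParams, geometry: Geometry):
    """One-shot energy and gradient of the toy FF on an alkane geometry."""
    nc = sum(1 for e in geometry.elements if e == "C")
    return ToyFF(nc, params).energy_gradient(geometry)


# -- samplers -------------------------------------------------------------


def _langevin_frames(ff: ToyFF, x0, temperature, n_collect, cfg: SamplerConfig,
                     rng) -> list[np.ndarray]:
    """BAOAB Langevin chain on the toy FF; returns collected coordinates."""
    kT = units.KB_HARTREE * temperature
    dt = cfg.dt_fs / units.FS_PER_AUT
    gamma = 2.0e-3  # 1/au; relaxation ~ 12 fs
    m = np.array([units.mass_au(e) for e in ff_elements(ff)])[:, None]
    x = x0.reshape(-1, 3).copy()
    geom = Geometry(ff_elements(ff), x.ravel())
    v = rng.normal(size=x.shape) * np.sqrt(kT / m)
    _, g = ff.energy_gradient(geom)
    f = -g.reshape(-1, 3)
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt(1.0 - c1 * c1)
    out = []
    step = 0
    while len(out) < n_collect:
        v += 0.5 * dt * f / m
        x += 0.5 * dt * v
        v = c1 * v + c2 * np.sqrt(kT / m) * rng.normal(size=x.shape)
        x += 0.5 * dt * v
        geom = geom.with_coords(x.ravel())
        _, g = ff.energy_gradient(geom)
        f = -g.reshape(-1, 3)
        step += 1
        if step > cfg.burn_in and step % cfg.stride == 0:
            out.append(x.ravel().copy())
    return out


def ff_elements(ff: ToyFF) -> list[str]:
    return alkane_elements(ff.n_carbons)


def _label(ff: ToyFF, coords, tag) -> Geometry:
    g = Geometry(ff_elements(ff), coords, tag=tag)
    e, grad = ff.energy_gradient(g)
    g.energy = e
    g.gradient = grad
    return g


def toy_normal_modes(ff: ToyFF, geometry: Geometry, step: float = 5e-3):
    """Harmonic frequencies (cm^-1) and mass-weighted modes of the toy FF."""
    from .pes_eval import hessian, normal_modes
    H = hessian(ff, geometry, step=step).matrix
    masses = [units.ATOMIC_MASS_AMU[e] for e in geometry.elements]
    return normal_modes(H, masses)


def sample_dataset(params: ToyFFParams, n_carbons: int,
                   sampler: SamplerConfig) -> DatasetFile:
    """Labeled toy-FF dataset in one of three sampling modes.

    thermal_md: Langevin chains at each ladder temperature, frames split
    evenly.  mode_displacement: seeded random displacements along the
    harmonic normal modes at the minimum, thermal amplitudes times
    displacement_scale.  head_to_tail_grid: thermal frames re-selected so
    the end-to-end C-C distance lands nearest each requested grid value.
    Frames above the energy ceiling (relative to the zigzag minimum) are
    dropped; everything is reproducible from the seed.
    """
    ff = ToyFF(n_carbons, params)
    rng = np.random.default_rng(sampler.seed)
    gm = build_alkane(n_carbons)
    e_gm = ff.energy(gm)
    frames: list[Geometry] = []

    if sampler.mode == "thermal_md":
        temps = list(sampler.temperatures)
        per = int(np.ceil(sampler.n_frames / len(temps)))
        for T in temps:
            for x in _langevin_frames(ff, gm.coords, T, per, sampler, rng):
                frames.append(_label(ff, x, f"thermal_{int(T)}K"))
        frames = frames[:sampler.n_frames]
    elif sampler.mode == "mode_displacement":
        freqs, modes = toy_normal_modes(ff, gm)
        m = np.repeat([units.mass_au(e) for e in gm.elements], 3)
        kT = units.KB_HARTREE * sampler.displacement_temperature
        omega = np.abs(freqs) * units.HARTREE_PER_CM
        amp = sampler.displacement_scale * np.sqrt(kT) / np.maximum(omega, 1e-8)
        for _ in range(sampler.n_frames):
            eta = rng.normal(size=len(freqs)) * amp
            dx = (modes @ eta) / np.sqrt(m)
            frames.append(_label(ff, gm.coords + dx, "displaced"))
    elif sampler.mode == "head_to_tail_grid":
        if not sampler.grid_angstrom:
            raise ValueError("head_to_tail_grid needs grid_angstrom targets")
        pool = []
        per = max(sampler.n_frames * 4 // len(sampler.temperatures), 50)
        for T in sampler.temperatures:
            pool += _langevin_frames(ff, gm.coords, T, per, sampler, rng)
        ends = np.array([np.linalg.norm(x.reshape(-1, 3)[0]
                                        - x.reshape(-1, 3)[n_carbons - 1])
                         for x in pool]) * units.ANGSTROM_PER_BOHR
        per_target = max(1, sampler.n_frames // len(sampler.grid_angstrom))
        for target in sampler.grid_angstrom:
            order = np.argsort(np.abs(ends - target))
            for idx in order[:per_target]:
                frames.append(_label(ff, pool[idx], f"d{target}A"))
    else:
        raise ValueError(f"unknown sampler mode {sampler.mode!r}")

    if sampler.ceiling_cm is not None:
        ceil = sampler.ceiling_cm * units.HARTREE_PER_CM
        frames = [f for f in frames if f.energy - e_gm <= ceil]
        if not frames:
            raise ValueError("energy ceiling excluded every sampled frame")
    return DatasetFile(frames)
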