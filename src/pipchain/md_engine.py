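"""Microcanonical (NVE) dynamics on a fitted model.

Initialization follows the protocol of distributing the specified total
energy uniformly over the kinetic energies of all atoms with random
directions, then projecting out center-of-mass linear momentum and total
angular momentum and rescaling speeds so KE matches the target.
Propagation is velocity Verlet.  Trajectories that wander into unphysical
regions of a fitted surface ("holes", visible as an exploding molecule) are
flagged failed and excluded from pooled statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import units
from .chemio import Geometry


@dataclass
class MDConfig:
    dt_au: float = 5.0                  # ~0.121 fs
    n_steps: int = 10_000
    record_stride: int = 10
    e_total_cm: float = 5000.0          # above the starting minimum
    seed: int = 0
    hole_floor_cm: float = 5000.0       # fail if PE < PE(start) - floor
    max_bond_stretch_angstrom: float = 6.0
    bond_detect_bohr: float = 4.0       # initial-topology bond criterion

    def __post_init__(self):
        if self.dt_au <= 0:
            raise ValueError("dt must be positive")
        if self.record_stride < 1:
            raise ValueError("record_stride must be >= 1")


@dataclass
class Trajectory:
    times_au: np.ndarray
    positions: list                     # recorded coords (3N,) arrays
    velocities: list
    potential: np.ndarray               # hartree
    kinetic: np.ndarray
    completed: bool
    failure_step: int | None = None
    elements: list = field(default_factory=list)

    @property
    def total(self) -> np.ndarray:
        return self.potential + self.kinetic


def init_conditions(geometry: Geometry, e_total_cm: float, seed: int,
                    project: bool = True):
    """Velocities for a trajectory started at a minimum.

    Every atom receives the same kinetic energy in a seeded random
    direction; COM momentum and total angular momentum are projected out and
    the speeds rescaled so the kinetic energy equals the requested total
    (the potential term is the starting-minimum energy by construction).
    Returns (coords (N,3), velocities (N,3)) in atomic units.
    """
    if e_total_cm < 0:
        raise ValueError("total energy must be nonnegative")
    X = geometry.coords3.copy()
    m = np.array([units.mass_au(e) for e in geometry.elements])
    N = len(m)
    if e_total_cm == 0.0:
        return X, np.zeros_like(X)
    rng = np.random.default_rng(seed)
    e_tot = e_total_cm * units.HARTREE_PER_CM
    ke_atom = e_tot / N
    dirs = rng.normal(size=(N, 3))
    dirs /= np.linalg.norm(dirs, axis=1)[:, None]
    v = dirs * np.sqrt(2.0 * ke_atom / m)[:, None]
    if not project:
        return X, v
    v = _project_momenta(X, v, m)
    ke = 0.5 * (m[:, None] * v * v).sum()
    if ke > 0:
        v *= np.sqrt(e_tot / ke)
    return X, v


def _project_momenta(X, v, m):
    """Remove COM linear momentum, then total angular momentum."""
    v = v - (m[:, None] * v).sum(0) / m.sum()
    com = (m[:, None] * X).sum(0) / m.sum()
    r = X - com
    L = (m[:, None] * np.cross(r, v)).sum(0)
    inertia = np.zeros((3, 3))
    for ri, mi in zip(r, m):
        inertia += mi * ((ri @ ri) * np.eye(3) - np.outer(ri, ri))
    omega = np.linalg.solve(inertia, L)
    v = v - np.cross(omega, r)
    return v - (m[:, None] * v).sum(0) / m.sum()


def angular_momentum(X, v, m):
    com = (m[:, None] * X).sum(0) / m.sum()
    return (m[:, None] * np.cross(X - com, v)).sum(0)


def run_nve(model, geometry: Geometry, velocities: np.ndarray,
            config: MDConfig) -> Trajectory:
    """Velocity-Verlet NVE propagation with explosion guards.

    Failure criteria (checked each step): potential energy below the
    starting potential minus hole_floor_cm; any initially bonded pair
    stretched beyond max_bond_stretch_angstrom; non-finite force.  On
    failure the trajectory is returned with completed=False and the step
    recorded — never raised.
    """
    m = np.array([units.mass_au(e) for e in geometry.elements])
    X = geometry.coords3.copy()
    v = np.asarray(velocities, float).reshape(X.shape).copy()
    dt = config.dt_au
    pe0 = model.energy(geometry)
    floor = pe0 - config.hole_floor_cm * units.HARTREE_PER_CM
    stretch_max = config.max_bond_stretch_angstrom * units.BOHR_PER_ANGSTROM
    # bonds from the initial topology
    d0 = np.sqrt(((X[:, None] - X[None, :]) ** 2).sum(2))
    iu, ju = np.triu_indices(len(m), 1)
    bonded = d0[iu, ju] < config.bond_detect_bohr
    bi, bj = iu[bonded], ju[bonded]

    if hasattr(model, "energy_gradient"):
        def pe_forces(x):
            e, g = model.energy_gradient(geometry.with_coords(x.ravel()))
            return e, -g.reshape(X.shape)
    else:
        def pe_forces(x):
            g = geometry.with_coords(x.ravel())
            return model.energy(g), -model.gradient(g).reshape(X.shape)

    times, pos, vel, pes, kes = [], [], [], [], []
    completed, failure_step = True, None
    pe, f = pe_forces(X)
    for step in range(config.n_steps + 1):
        ke = 0.5 * (m[:, None] * v * v).sum()
        if step % config.record_stride == 0:
            times.append(step * dt)
            pos.append(X.ravel().copy())
            vel.append(v.ravel().copy())
            pes.append(pe)
            kes.append(ke)
        bad = (not np.all(np.isfinite(f))) or pe < floor or (
            np.sqrt(((X[bi] - X[bj]) ** 2).sum(1)).max(initial=0.0)
            > stretch_max)
        if bad:
            completed, failure_step = False, step
            break
        if step == config.n_steps:
            break
        v += 0.5 * dt * f / m[:, None]
        X += dt * v
        try:
            pe, f = pe_forces(X)
        except (ValueError, FloatingPointError):
            # a collapsing geometry can make the model unevaluatable;
            # record the failure instead of letting it escape
            completed, failure_step = False, step + 1
            break
        v += 0.5 * dt * f / m[:, None]
    return Trajectory(times_au=np.array(times), positions=pos, velocities=vel,
                      potential=np.array(pes), kinetic=np.array(kes),
                      completed=completed, failure_step=failure_step,
                      elements=list(geometry.elements))


def ensemble_stats(trajectories) -> dict:
    """Completion counts and the pooled recorded frames of COMPLETED
    trajectories only (failed runs are discarded from observables)."""
    if not trajectories:
        raise ValueError("need at least one trajectory")
    completed = [t for t in trajectories if t.completed]
    pooled = [x for t in completed for x in t.positions]
    return {
        "n_total": len(trajectories),
        "n_completed": len(completed),
        "n_failed": len(trajectories) - len(completed),
        "pooled_frames": pooled,
        "elements": trajectories[0].elements,
    }
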