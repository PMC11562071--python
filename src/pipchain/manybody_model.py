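"""Unified many-body PIP expansion for two-element (C/H) molecules.

The total energy is V = V1 + V2 + V3 + V4: a single constant (the 1-body
energy of the isolated atoms), plus sums of typed 2-body (CC, CH, HH),
3-body (CCC, CCH, CHH, HHH) and 4-body (CCCC, CCCH, CCHH, CHHH, HHHH)
interactions over all atom tuples of each composition.  Each 2-body term is
a power series in the pair's Morse variable; each 3-/4-body term is a
purified PIP basis for the tuple's like-atom symmetry (CCH and CHH share
the A2B basis STRUCTURE but carry independent coefficient blocks, and so
on).  All blocks are fit together in one linear least-squares problem.

Each body order has its own Morse range parameter, polynomial order, and
distance cutoff with a C2 quintic switch on the tuple's largest internal
distance, so the expansion is size consistent: pull any group of atoms
beyond every cutoff and the energy decomposes exactly.

Because tuples are enumerated over all atoms, the model is manifestly
invariant under every permutation of like atoms (including C with C), and
it transfers between molecules: the same coefficient vector evaluates any
CnH(2n+2) geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from . import units
from .chemio import Geometry
from .pip_basis import (CompiledPolynomials, canonical_pairs, enumerate_pips,
                        purify)

PAIR_TYPES = ("CC", "CH", "HH")
TRIPLET_TYPES = ("CCC", "CCH", "CHH", "HHH")
QUAD_TYPES = ("CCCC", "CCCH", "CCHH", "CHHH", "HHHH")
BLOCK_ORDER = ("const",) + PAIR_TYPES + TRIPLET_TYPES + QUAD_TYPES

_TUPLE_CHUNK = 4096


def type_symmetry(type_str: str) -> tuple[int, ...]:
    """Like-atom class sizes for a composition label, atoms ordered C then H."""
    nc = type_str.count("C")
    nh = type_str.count("H")
    sym = tuple(s for s in (nc, nh) if s > 0)
    return sym


@dataclass(frozen=True)
class NBodyConfig:
    """Per-order hyperparameters.

    morse_a in bohr, switch_on/switch_off in angstrom; index 0 is 2-body,
    1 is 3-body, 2 is 4-body.  Defaults follow the expectation that n-body
    interactions fall off (shorter range, lower order) as n grows.
    """

    morse_a: tuple[float, float, float] = (2.5, 1.8, 1.2)
    max_order: tuple[int, int, int] = (10, 8, 7)
    switch_on: tuple[float, float, float] = (9.0, 7.0, 5.0)
    switch_off: tuple[float, float, float] = (10.0, 8.0, 6.0)

    def __post_init__(self):
        for on, off in zip(self.switch_on, self.switch_off):
            if not on < off:
                raise ValueError("switch_on must be below switch_off")

    def for_n(self, n: int):
        i = n - 2
        return (self.morse_a[i], self.max_order[i],
                self.switch_on[i] * units.BOHR_PER_ANGSTROM,
                self.switch_off[i] * units.BOHR_PER_ANGSTROM)


def switch(r, r_on, r_off):
    """C2 quintic switch: 1 for r <= r_on, 0 for r >= r_off.

    Between the ends, s = 1 - (10 t^3 - 15 t^4 + 6 t^5) with
    t = (r - r_on)/(r_off - r_on); first and second derivatives vanish at
    both ends and s(midpoint) = 1/2.
    """
    if not r_on < r_off:
        raise ValueError("r_on must be below r_off")
    t = np.clip((np.asarray(r, float) - r_on) / (r_off - r_on), 0.0, 1.0)
    return 1.0 - t * t * t * (10.0 - 15.0 * t + 6.0 * t * t)


def switch_derivative(r, r_on, r_off):
    """ds/dr; zero outside (r_on, r_off)."""
    r = np.asarray(r, float)
    t = (r - r_on) / (r_off - r_on)
    inside = (t > 0.0) & (t < 1.0)
    t = np.clip(t, 0.0, 1.0)
    return np.where(inside, -30.0 * t * t * (1.0 - t) ** 2 / (r_off - r_on), 0.0)


def _typed_index_lists(elements) -> dict[str, np.ndarray]:
    c = np.array([i for i, e in enumerate(elements) if e == "C"], dtype=np.intp)
    h = np.array([i for i, e in enumerate(elements) if e == "H"], dtype=np.intp)
    return {"C": c, "H": h}


def _tuples_for_type(elements, type_str) -> np.ndarray:
    """All atom tuples of a composition, canonical within-tuple order:
    C atoms (ascending global index) before H atoms (ascending)."""
    idx = _typed_index_lists(elements)
    nc, nh = type_str.count("C"), type_str.count("H")
    cs = list(combinations(idx["C"], nc)) if nc else [()]
    hs = list(combinations(idx["H"], nh)) if nh else [()]
    out = [c + h for c in cs for h in hs]
    return np.array(out, dtype=np.intp).reshape(len(out), nc + nh)


def enumerate_tuples(geometry: Geometry, n: int, r_off_angstrom: float):
    """Typed atom tuples of size n whose largest internal distance is within
    the cutoff.  Returns {type: (tuples [T, n], r_max [T] in bohr)}."""
    if n not in (2, 3, 4):
        raise ValueError("n must be 2, 3 or 4")
    X = geometry.coords3
    D = np.sqrt(((X[:, None] - X[None, :]) ** 2).sum(axis=2))
    r_off = r_off_angstrom * units.BOHR_PER_ANGSTROM
    types = {2: PAIR_TYPES, 3: TRIPLET_TYPES, 4: QUAD_TYPES}[n]
    out = {}
    for t in types:
        tup = _tuples_for_type(geometry.elements, t)
        if len(tup) == 0:
            out[t] = (tup, np.empty(0))
            continue
        local = canonical_pairs(n)
        dm = np.stack([D[tup[:, i], tup[:, j]] for i, j in local], axis=1)
        rmax = dm.max(axis=1)
        keep = rmax <= r_off
        out[t] = (tup[keep], rmax[keep])
    return out


@dataclass
class ManyBodyModel:
    """Typed 2-/3-/4-body PIP model; coefficient layout follows BLOCK_ORDER
    (one constant, then CC, CH, HH, CCC, ..., HHHH)."""

    config: NBodyConfig = field(default_factory=NBodyConfig)
    coefficients: np.ndarray | None = None
    _bases: dict = field(default_factory=dict, repr=False)
    _compiled: dict = field(default_factory=dict, repr=False)

    kind = "manybody"

    def basis(self, type_str: str):
        """Purified PIP basis for a 3-/4-body type (cached)."""
        if type_str not in self._bases:
            n = len(type_str)
            _, M, _, _ = self.config.for_n(n)
            sym = type_symmetry(type_str)
            self._bases[type_str] = purify(enumerate_pips(sym, n, M))
        return self._bases[type_str]

    def compiled(self, type_str: str) -> CompiledPolynomials:
        if type_str not in self._compiled:
            b = self.basis(type_str)
            self._compiled[type_str] = CompiledPolynomials.from_pips(
                b.pips, b.n_pairs)
        return self._compiled[type_str]

    def block_sizes(self) -> dict[str, int]:
        sizes = {"const": 1}
        m2 = self.config.max_order[0]
        for t in PAIR_TYPES:
            sizes[t] = m2
        for t in TRIPLET_TYPES + QUAD_TYPES:
            sizes[t] = len(self.basis(t))
        return sizes

    def block_slices(self) -> dict[str, slice]:
        sizes = self.block_sizes()
        out, pos = {}, 0
        for name in BLOCK_ORDER:
            out[name] = slice(pos, pos + sizes[name])
            pos += sizes[name]
        return out

    @property
    def n_terms(self) -> int:
        return sum(self.block_sizes().values())

    # -- evaluation -------------------------------------------------------

    def feature_row(self, geometry: Geometry) -> np.ndarray:
        return self.feature_matrix([geometry])[0]

    def feature_matrix(self, geometries) -> np.ndarray:
        slices = self.block_slices()
        F = np.zeros((len(geometries), self.n_terms))
        F[:, 0] = 1.0
        m2 = self.config.max_order[0]
        for fi, g in enumerate(geometries):
            X = g.coords3
            D = np.sqrt(((X[:, None] - X[None, :]) ** 2).sum(axis=2))
            for n in (2, 3, 4):
                a, M, r_on, r_off = self.config.for_n(n)
                for t, (tup, rmax) in self._tuples(g, D, n, r_off).items():
                    if len(tup) == 0:
                        continue
                    s = switch(rmax, r_on, r_off)
                    if n == 2:
                        y = np.exp(-rmax / a)
                        pw = y[:, None] ** np.arange(1, m2 + 1)[None, :]
                        F[fi, slices[t]] = s @ pw
                    else:
                        comp = self.compiled(t)
                        acc = np.zeros(comp.n_out)
                        for lo in range(0, len(tup), _TUPLE_CHUNK):
                            sl = slice(lo, lo + _TUPLE_CHUNK)
                            Y = self._tuple_morse(D, tup[sl], n, a)
                            acc += s[sl] @ comp.values(Y)
                        F[fi, slices[t]] = acc
        return F

    @staticmethod
    def _tuples(geometry, D, n, r_off):
        types = {2: PAIR_TYPES, 3: TRIPLET_TYPES, 4: QUAD_TYPES}[n]
        out = {}
        for t in types:
            tup = _tuples_for_type(geometry.elements, t)
            if len(tup) == 0:
                out[t] = (tup, np.empty(0))
                continue
            local = canonical_pairs(n)
            dm = np.stack([D[tup[:, i], tup[:, j]] for i, j in local], axis=1)
            rmax = dm.max(axis=1)
            keep = rmax <= r_off
            out[t] = (tup[keep], rmax[keep])
        return out

    @staticmethod
    def _tuple_morse(D, tup, n, a):
        local = canonical_pairs(n)
        dm = np.stack([D[tup[:, i], tup[:, j]] for i, j in local], axis=1)
        return np.exp(-dm / a)

    def energy(self, geometry: Geometry) -> float:
        self._require_fit()
        return float(self.feature_row(geometry) @ self.coefficients)

    def gradient(self, geometry: Geometry) -> np.ndarray:
        """Analytic dE/dx including the switch-derivative term."""
        self._require_fit()
        slices = self.block_slices()
        X = geometry.coords3
        N = len(X)
        diff = X[:, None, :] - X[None, :, :]
        D = np.sqrt((diff ** 2).sum(axis=2))
        np.fill_diagonal(D, 1.0)
        unit = diff / D[:, :, None]
        grad = np.zeros((N, 3))
        m2 = self.config.max_order[0]
        powers = np.arange(1, m2 + 1)

        def add_pair_force(i_idx, j_idx, dEdr):
            np.add.at(grad, i_idx, dEdr[:, None] * unit[i_idx, j_idx])
            np.add.at(grad, j_idx, -dEdr[:, None] * unit[i_idx, j_idx])

        for n in (2, 3, 4):
            a, M, r_on, r_off = self.config.for_n(n)
            local = canonical_pairs(n)
            for t, (tup, rmax) in self._tuples(geometry, D, n, r_off).items():
                if len(tup) == 0:
                    continue
                c = self.coefficients[slices[t]]
                s = switch(rmax, r_on, r_off)
                ds = switch_derivative(rmax, r_on, r_off)
                if n == 2:
                    y = np.exp(-rmax / a)
                    pw = y[:, None] ** powers[None, :]
                    e_pair = pw @ c
                    dedy = (pw / y[:, None] * powers[None, :]) @ c
                    dEdr = s * dedy * (-y / a) + ds * e_pair
                    add_pair_force(tup[:, 0], tup[:, 1], dEdr)
                    continue
                for lo in range(0, len(tup), _TUPLE_CHUNK):
                    sl = slice(lo, lo + _TUPLE_CHUNK)
                    tt, ss, dss = tup[sl], s[sl], ds[sl]
                    dm = np.stack([D[tt[:, i], tt[:, j]] for i, j in local],
                                  axis=1)
                    Y = np.exp(-dm / a)
                    e_t, gY = self.compiled(t).weighted_value_and_grad(Y, c)
                    dEdr_pairs = ss[:, None] * gY * (-Y / a)
                    # switch acts on the largest internal distance
                    arg = dm.argmax(axis=1)
                    rows = np.arange(len(tt))
                    dEdr_pairs[rows, arg] += dss * e_t
                    for k, (i, j) in enumerate(local):
                        add_pair_force(tt[:, i], tt[:, j], dEdr_pairs[:, k])
        return grad.ravel()

    def _require_fit(self):
        if self.coefficients is None:
            raise ValueError("model has no coefficients; fit it first")

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "config": {
                "morse_a": list(self.config.morse_a),
                "max_order": list(self.config.max_order),
                "switch_on": list(self.config.switch_on),
                "switch_off": list(self.config.switch_off),
            },
            "coefficients": (None if self.coefficients is None
                             else list(self.coefficients)),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ManyBodyModel":
        cfg = NBodyConfig(
            morse_a=tuple(d["config"]["morse_a"]),
            max_order=tuple(d["config"]["max_order"]),
            switch_on=tuple(d["config"]["switch_on"]),
            switch_off=tuple(d["config"]["switch_off"]),
        )
        coef = d["coefficients"]
        return cls(config=cfg,
                   coefficients=None if coef is None else np.array(coef, float))


def build_typed_bases(config: NBodyConfig | None = None) -> ManyBodyModel:
    """Construct (and cache) all typed basis blocks for a configuration."""
    model = ManyBodyModel(config=config or NBodyConfig())
    model.block_sizes()  # force basis construction
    return model
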