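"""Permutationally invariant polynomial (PIP) bases over Morse variables.

A molecule's internuclear distances r_ij are mapped to bounded Morse
variables y_ij = exp(-r_ij / a).  A monomial is a product of positive powers
of pair variables; the like-atom permutation group of a declared symmetry
(e.g. A3 = three interchangeable atoms) acts on atoms, hence on pairs, hence
on monomials.  A PIP is the plain (unnormalized) sum of one orbit of
monomials under that action, and a basis is one PIP per orbit with total
degree between 1 and a maximum order M.  No constant term is ever part of a
basis; models carry a single separate constant coefficient.

Purification removes PIPs that fail to vanish in some dissociation channel:
a purified polynomial goes to zero whenever the atoms are split into two
groups that are pulled infinitely far apart (all cross-group Morse variables
-> 0).  For two- and three-atom symmetries this coincides with the familiar
one-atom-limit rule; for four atoms the 2+2 channels additionally matter.

Canonical pair order is lexicographic (i, j) with i < j over 0-based atom
indices; every module in this package shares it (it is also the order of
``scipy.spatial.distance.pdist``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from itertools import combinations, combinations_with_replacement

import numpy as np
from scipy.spatial.distance import pdist

# A monomial is a tuple of (pair-variable index, power), sorted by index,
# with all powers >= 1.  An orbit is a sorted tuple of monomials.
Monomial = tuple[tuple[int, int], ...]


@dataclass(frozen=True)
class MorseSpec:
    """Morse transform y = exp(-r/a); the range parameter a is in bohr.

    Values between 2 and 3 bohr are typical for full-molecule bases; the
    many-body blocks use shorter ranges at higher body order.
    """

    a: float = 2.0

    def __post_init__(self):
        if self.a <= 0:
            raise ValueError("Morse range parameter must be positive")


@dataclass(frozen=True)
class PIP:
    """One symmetrized polynomial: an orbit of monomials sharing a degree."""

    orbit: tuple[Monomial, ...]
    degree: int


@dataclass
class PIPBasis:
    symmetry: tuple[int, ...]
    n_atoms: int
    max_order: int
    pips: list[PIP]
    purified: bool = False

    def __post_init__(self):
        if sum(self.symmetry) != self.n_atoms:
            raise ValueError("class sizes must sum to the atom count")

    @property
    def n_pairs(self) -> int:
        return self.n_atoms * (self.n_atoms - 1) // 2

    def __len__(self) -> int:
        return len(self.pips)


def canonical_pairs(n: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(n) for j in range(i + 1, n)]


def pairwise_distances(coords3: np.ndarray) -> np.ndarray:
    """Condensed distance vector in canonical pair order (bohr)."""
    return pdist(np.asarray(coords3, float))


def morse_transform(geometry_or_coords, spec: MorseSpec) -> np.ndarray:
    """Morse variables y = exp(-r/a) over all pairs in canonical order."""
    coords3 = getattr(geometry_or_coords, "coords3", None)
    if coords3 is None:
        coords3 = np.asarray(geometry_or_coords, float).reshape(-1, 3)
    r = pairwise_distances(coords3)
    if np.any(r <= 0.0):
        raise ValueError("coincident atoms: zero internuclear distance")
    return np.exp(-r / spec.a)


def symmetry_classes(symmetry, n_atoms=None) -> list[list[int]]:
    """Atom-index classes for a symmetry spec, e.g. (2, 1) -> [[0, 1], [2]]."""
    classes, pos = [], 0
    for size in symmetry:
        if size <= 0:
            raise ValueError("class size must be positive")
        classes.append(list(range(pos, pos + size)))
        pos += size
    if n_atoms is not None and pos != n_atoms:
        raise ValueError("class sizes must sum to the atom count")
    return classes


def pair_permutation(n: int, atom_perm) -> tuple[int, ...]:
    """Action of an atom permutation (image list) on canonical pair indices."""
    pairs = canonical_pairs(n)
    index = {p: k for k, p in enumerate(pairs)}
    out = []
    for (i, j) in pairs:
        mi, mj = atom_perm[i], atom_perm[j]
        out.append(index[(mi, mj) if mi < mj else (mj, mi)])
    return tuple(out)


def _class_generators(classes, n) -> list[tuple[int, ...]]:
    """Pair permutations induced by adjacent within-class transpositions."""
    gens = []
    for cls in classes:
        for a, b in zip(cls, cls[1:]):
            perm = list(range(n))
            perm[a], perm[b] = b, a
            gens.append(pair_permutation(n, perm))
    return gens


def induced_pair_group(symmetry, n_atoms) -> list[tuple[int, ...]]:
    """Full group of pair permutations generated by within-class transpositions.

    The atom group has order equal to the product of class factorials; the
    induced action on pairs can be smaller when the action is unfaithful
    (e.g. A2: swapping a diatomic's atoms fixes its single pair).  Intended
    for small symmetries (oracle checks) — basis enumeration only ever uses
    generators.
    """
    classes = symmetry_classes(symmetry, n_atoms)
    n_pairs = n_atoms * (n_atoms - 1) // 2
    identity = tuple(range(n_pairs))
    gens = _class_generators(classes, n_atoms)
    group = {identity}
    frontier = [identity]
    while frontier:
        new = []
        for g in frontier:
            for h in gens:
                comp = tuple(h[g[k]] for k in range(n_pairs))
                if comp not in group:
                    group.add(comp)
                    new.append(comp)
        frontier = new
    atom_group_order = math.prod(math.factorial(s) for s in symmetry)
    if atom_group_order % len(group) != 0:
        raise AssertionError("induced group order must divide the atom "
                             "group order")
    return sorted(group)


def _apply_pair_perm(mono: Monomial, perm) -> Monomial:
    return tuple(sorted((perm[v], p) for v, p in mono))


def _orbit(mono: Monomial, gens) -> set[Monomial]:
    orb = {mono}
    frontier = [mono]
    while frontier:
        new = []
        for m in frontier:
            for g in gens:
                im = _apply_pair_perm(m, g)
                if im not in orb:
                    orb.add(im)
                    new.append(im)
        frontier = new
    return orb


def _monomial_count(n_vars: int, max_order: int) -> int:
    return sum(math.comb(n_vars + d - 1, d) for d in range(1, max_order + 1))


def enumerate_pips(symmetry, n_atoms, max_order,
                   monomial_ceiling: int = 5_000_000) -> PIPBasis:
    """All PIPs (monomial orbits) with total degree in [1, max_order].

    Ordering is deterministic: by degree, then by the lexicographically
    smallest orbit member, so coefficient vectors are portable across runs.
    """
    if max_order < 1:
        raise ValueError("max_order must be >= 1")
    classes = symmetry_classes(symmetry, n_atoms)
    n_pairs = n_atoms * (n_atoms - 1) // 2
    total = _monomial_count(n_pairs, max_order)
    if total > monomial_ceiling:
        raise MemoryError(
            f"{total} monomials for {n_pairs} pair variables at order "
            f"{max_order} exceeds the ceiling of {monomial_ceiling}; raise "
            "monomial_ceiling explicitly if this is intended")
    gens = _class_generators(classes, n_atoms)
    seen: set[Monomial] = set()
    pips: list[PIP] = []
    for d in range(1, max_order + 1):
        for combo in combinations_with_replacement(range(n_pairs), d):
            mono = tuple((v, combo.count(v)) for v in sorted(set(combo)))
            if mono in seen:
                continue
            orb = _orbit(mono, gens)
            seen |= orb
            pips.append(PIP(orbit=tuple(sorted(orb)), degree=d))
    return PIPBasis(tuple(symmetry), n_atoms, max_order, pips, purified=False)


def _vanishes_in_all_channels(mono: Monomial, pairs, n_atoms) -> bool:
    support = [pairs[v] for v, _ in mono]
    for r in range(1, n_atoms // 2 + 1):
        for group in combinations(range(n_atoms), r):
            g = set(group)
            if not any((i in g) != (j in g) for i, j in support):
                return False
    return True


def purify(basis: PIPBasis) -> PIPBasis:
    """Keep only PIPs that vanish in every dissociation channel.

    A PIP survives iff every orbit member contains, for every bipartition of
    the atoms into two nonempty groups, at least one cross-group pair
    variable; equivalently the polynomial -> 0 whenever any group of atoms is
    taken infinitely far from the rest.
    """
    if basis.purified:
        raise ValueError("basis is already purified")
    pairs = canonical_pairs(basis.n_atoms)
    survivors = [
        p for p in basis.pips
        if all(_vanishes_in_all_channels(m, pairs, basis.n_atoms) for m in p.orbit)
    ]
    return replace(basis, pips=survivors, purified=True)


def evaluate_pips(basis: PIPBasis, morse_vector: np.ndarray) -> np.ndarray:
    """Value of every PIP at one Morse vector (unnormalized orbit sums)."""
    y = np.asarray(morse_vector, float)
    if y.shape != (basis.n_pairs,):
        raise ValueError(f"expected Morse vector of length {basis.n_pairs}, "
                         f"got {y.shape}")
    return CompiledPolynomials.from_pips(basis.pips, basis.n_pairs).values(y[None, :])[0]


class CompiledPolynomials:
    """Vectorized evaluator for a list of monomial orbits.

    Monomials are flattened into (variable, power) slot arrays grouped by
    slot count, so a batch of T variable vectors evaluates with a handful of
    numpy gathers and reductions; orbit sums come from one reduceat.
    """

    def __init__(self, orbits, n_vars: int):
        self.n_vars = n_vars
        self.n_out = len(orbits)
        monos = []
        ptr = [0]
        for orb in orbits:
            monos.extend(orb)
            ptr.append(len(monos))
        self.orbit_ptr = np.array(ptr[:-1], dtype=np.intp)
        self.n_mono = len(monos)
        self.max_pow = max((p for m in monos for _, p in m), default=1)
        groups: dict[int, list[tuple[int, Monomial]]] = {}
        for col, m in enumerate(monos):
            groups.setdefault(len(m), []).append((col, m))
        self.groups = []
        for k, items in sorted(groups.items()):
            cols = np.array([c for c, _ in items], dtype=np.intp)
            var = np.array([[v for v, _ in m] for _, m in items], dtype=np.intp)
            pw = np.array([[p for _, p in m] for _, m in items], dtype=np.intp)
            self.groups.append((k, cols, var, pw))

    @classmethod
    def from_pips(cls, pips, n_vars):
        return cls([p.orbit for p in pips], n_vars)

    def _power_table(self, Y: np.ndarray) -> np.ndarray:
        T = Y.shape[0]
        P = np.empty((T, self.n_vars, self.max_pow + 1))
        P[:, :, 0] = 1.0
        for d in range(1, self.max_pow + 1):
            P[:, :, d] = P[:, :, d - 1] * Y
        return P

    def _monomials(self, P: np.ndarray) -> np.ndarray:
        T = P.shape[0]
        M = np.empty((T, self.n_mono))
        for k, cols, var, pw in self.groups:
            S = P[:, var, pw]          # [T, m, k]
            M[:, cols] = S.prod(axis=2)
        return M

    def values(self, Y: np.ndarray) -> np.ndarray:
        """Orbit sums for a batch: Y is [T, n_vars] -> [T, n_out]."""
        M = self._monomials(self._power_table(np.atleast_2d(Y)))
        return np.add.reduceat(M, self.orbit_ptr, axis=1)

    def weighted_value_and_grad(self, Y: np.ndarray, weights: np.ndarray):
        """sum_i w_i p_i and its gradient wrt the variables, per row of Y.

        Returns (E [T], G [T, n_vars]).  Partial products are formed
        directly (never by division), so exact zeros in Y are safe.
        """
        Y = np.atleast_2d(Y)
        T = Y.shape[0]
        P = self._power_table(Y)
        w = np.asarray(weights, float)
        # per-monomial folded weight
        wm = np.empty(self.n_mono)
        bounds = list(self.orbit_ptr) + [self.n_mono]
        for i in range(self.n_out):
            wm[bounds[i]:bounds[i + 1]] = w[i]
        E = np.zeros(T)
        G = np.zeros((T, self.n_vars))
        rows = np.arange(T)[:, None]
        for k, cols, var, pw in self.groups:
            S = P[:, var, pw]                      # [T, m, k]
            E += (wm[cols] * S.prod(axis=2)).sum(axis=1)
            for j in range(k):
                partial = np.ones((T, len(cols)))
                for l in range(k):
                    if l != j:
                        partial *= S[:, :, l]
                dmono = pw[:, j] * P[:, var[:, j], pw[:, j] - 1] * partial
                np.add.at(G, (rows, var[None, :, j]), wm[cols] * dmono)
        return E, G
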