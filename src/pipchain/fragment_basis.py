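"""Overlapping fragmented PIP bases for long alkane chains.

Instead of one PIP basis over all N(N-1)/2 Morse variables of a large
molecule, the basis is the union of PIP bases built on a few overlapping
atom subsets (fragments), each with its own like-atom permutation classes.
Only the BASIS is fragmented — the model is still a single linear expansion
in the union basis, evaluated on the whole molecule's Morse variables, and
one global constant.

Fragment selection is data-driven: for every atom pair the largest Morse
variable seen anywhere in the data set is recorded, and a fragment grows
greedily from its center's permutation class by repeatedly pulling in the
atom (together with its whole class — a fragment containing a permuting atom
must contain everything that permutes with it, or the basis loses the
declared symmetry) with the strongest contact to the atoms already inside.

Duplicate polynomials arise in the overlap regions.  ``dedup="all"``
(default) removes every duplicate across the whole union, which makes the
surviving set independent of fragment order.  ``dedup="chain"`` removes a
fragment's duplicates only against the surviving entries of the immediately
preceding fragment — the behavior of sequential fragment-assembly pipelines,
kept as a documented mode because published basis sizes for tetradecane
follow it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .chemio import DatasetFile, Geometry
from .pip_basis import (CompiledPolynomials, MorseSpec, canonical_pairs,
                        enumerate_pips, morse_transform, symmetry_classes)

# global orbit: sorted tuple of monomials, each monomial a sorted tuple of
# ((i, j), power) with global 0-based atom pairs i < j
GlobalOrbit = tuple


@dataclass
class FragmentSpec:
    """Atoms of one fragment, listed in permutational order.

    symmetry gives like-atom class sizes aligned with ``atoms``: the first
    symmetry[0] entries of ``atoms`` form class 0, and so on.  ``center`` is
    the (0-based) atom the fragment was grown from.
    """

    center: int
    atoms: list[int]
    symmetry: tuple[int, ...]

    def __post_init__(self):
        if sum(self.symmetry) != len(self.atoms):
            raise ValueError("class sizes must sum to the fragment atom count")
        if self.center not in self.atoms:
            raise ValueError("center atom must belong to the fragment")
        if len(set(self.atoms)) != len(self.atoms):
            raise ValueError("duplicate atom in fragment")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def classes_global(self) -> list[list[int]]:
        """Permutation classes as global atom-index lists."""
        return [[self.atoms[i] for i in cls]
                for cls in symmetry_classes(self.symmetry)]


def pairwise_max_morse(dataset: DatasetFile, spec: MorseSpec) -> np.ndarray:
    """Per-pair maximum Morse variable over all frames of a dataset.

    Entry k is the largest y_k = exp(-r_k/a) seen for canonical pair k;
    large entries mark atoms that come close somewhere in the data.
    """
    if not len(dataset):
        raise ValueError("empty dataset")
    n = dataset.geometries[0].n_atoms
    best = None
    for g in dataset.geometries:
        if g.n_atoms != n:
            raise ValueError("inconsistent atom counts across frames")
        y = morse_transform(g, spec)
        best = y if best is None else np.maximum(best, y)
    return best


def select_fragment(center: int, max_atoms: int, perm_classes,
                    max_morse: np.ndarray, n_atoms: int) -> FragmentSpec:
    """Greedy closure fragment selection.

    Start from the center's whole permutation class; repeatedly add the
    candidate atom (plus its whole class) with the largest max-Morse value to
    any atom already included, while the total stays within ``max_atoms``;
    growth stops at the first candidate whose class would overflow the cap.
    Ties break to the lowest atom index.
    """
    pairs = canonical_pairs(n_atoms)
    pair_idx = {p: k for k, p in enumerate(pairs)}
    class_of = {}
    for cls in perm_classes:
        for a in cls:
            class_of[a] = tuple(cls)
    for a in range(n_atoms):
        class_of.setdefault(a, (a,))

    chosen_classes = [class_of[center]]
    inside = set(chosen_classes[0])
    if len(inside) > max_atoms:
        raise ValueError("the center's own class exceeds max_atoms")

    def contact(atom):
        return max(max_morse[pair_idx[(min(atom, b), max(atom, b))]]
                   for b in inside)

    while True:
        candidates = {}
        for a in range(n_atoms):
            if a in inside:
                continue
            # a class joins as a unit; its contact is its best member's
            cls = class_of[a]
            score = max(contact(m) for m in cls)
            if cls not in candidates or score > candidates[cls]:
                candidates[cls] = score
        if not candidates:
            break
        best_cls = max(candidates, key=lambda c: (candidates[c], -min(c)))
        if len(inside) + len(best_cls) > max_atoms:
            break
        chosen_classes.append(best_cls)
        inside.update(best_cls)

    atoms, symmetry = [], []
    for cls in chosen_classes:
        atoms.extend(cls)
        symmetry.append(len(cls))
    return FragmentSpec(center=center, atoms=atoms, symmetry=tuple(symmetry))


# The canonical three-fragment partition of n-tetradecane (C14H30) under the
# end-methyl permutation scheme {3,3,2,...,2,1,...,1}: fragments grown from
# C1, C7 and C13 with at most 24 atoms each.  Atom numbering: C1..C14 are
# 0..13; H15..H44 are 14..43 (three H on each terminal carbon, two on each
# interior carbon, in carbon order).  Stored 0-based, printed 1-based.
TETRADECANE_FRAGMENTS = [
    FragmentSpec(center=0,
                 atoms=[a - 1 for a in [15, 16, 17, 42, 43, 44, 18, 19, 20, 21,
                                        22, 23, 24, 25, 26, 27, 28, 29, 32, 33,
                                        1, 2, 3, 4]],
                 symmetry=(3, 3, 2, 2, 2, 2, 2, 2, 2, 1, 1, 1, 1)),
    FragmentSpec(center=6,
                 atoms=[a - 1 for a in [20, 21, 22, 23, 24, 25, 26, 27, 28, 29,
                                        30, 31, 32, 33, 34, 35, 36, 37,
                                        5, 6, 7, 8, 9]],
                 symmetry=(2, 2, 2, 2, 2, 2, 2, 2, 2, 1, 1, 1, 1, 1)),
    FragmentSpec(center=12,
                 atoms=[a - 1 for a in [15, 16, 17, 42, 43, 44, 30, 31, 32, 33,
                                        34, 35, 36, 37, 38, 39, 40, 41,
                                        10, 11, 12, 13, 14]],
                 symmetry=(3, 3, 2, 2, 2, 2, 2, 2, 1, 1, 1, 1, 1)),
]


def union_morse_variables(fragments) -> list[tuple[int, int]]:
    """Distinct global atom pairs covered by any fragment (sorted)."""
    pairs = set()
    for f in fragments:
        for i, j in combinations(sorted(f.atoms), 2):
            pairs.add((i, j))
    return sorted(pairs)


def check_permutation_consistency(fragments) -> None:
    """Shared atoms must carry the same class structure in every fragment."""
    seen: dict[int, frozenset] = {}
    for f in fragments:
        for cls in f.classes_global():
            key = frozenset(cls)
            for a in cls:
                if a in seen and seen[a] != key:
                    raise ValueError(
                        f"atom {a + 1} permutes with {sorted(x + 1 for x in seen[a])} "
                        f"in one fragment but with {sorted(x + 1 for x in key)} in "
                        "another; a fragment containing a permuting atom must "
                        "contain its whole permutation class")
            for a in cls:
                seen[a] = key


def _warn_uncoupled_methyls(fragments) -> None:
    """Warn when the two terminal-methyl H triples share no fragment.

    Without a common fragment the basis carries no Morse variable between
    the two chain ends, so the fitted surface cannot repel them and folded
    conformations can overlap unphysically.
    """
    import warnings

    triples = set()
    per_fragment = []
    for f in fragments:
        own = {frozenset(cls) for cls in f.classes_global() if len(cls) == 3}
        triples |= own
        per_fragment.append(own)
    if len(triples) >= 2 and not any(len(own) >= 2 for own in per_fragment):
        warnings.warn(
            "no fragment contains both terminal-methyl hydrogen classes; "
            "the basis has no end-to-end repulsion", stacklevel=3)


def _global_orbit(orbit, frag: FragmentSpec, local_pairs) -> GlobalOrbit:
    out = []
    for mono in orbit:
        gm = []
        for v, p in mono:
            i, j = local_pairs[v]
            gi, gj = frag.atoms[i], frag.atoms[j]
            gm.append(((gi, gj) if gi < gj else (gj, gi), p))
        out.append(tuple(sorted(gm)))
    return tuple(sorted(out))


@dataclass
class FragmentedModel:
    """Linear PIP model on the deduplicated union of fragment bases.

    ``coefficients`` has length 1 + n_pips: entry 0 is the global constant,
    the rest align with ``union_orbits``.  Until fitted it is None.
    """

    n_atoms: int
    fragments: list[FragmentSpec]
    morse: MorseSpec
    max_order: int
    union_orbits: list[GlobalOrbit]
    dedup: str = "all"
    coefficients: np.ndarray | None = None
    _compiled: CompiledPolynomials | None = field(default=None, repr=False)

    kind = "fragmented"

    @property
    def n_pips(self) -> int:
        return len(self.union_orbits)

    @property
    def n_terms(self) -> int:
        return 1 + self.n_pips

    def _pair_index(self):
        return {p: k for k, p in enumerate(canonical_pairs(self.n_atoms))}

    def compiled(self) -> CompiledPolynomials:
        if self._compiled is None:
            idx = self._pair_index()
            orbits = [tuple(tuple((idx[pair], p) for pair, p in mono)
                            for mono in orb)
                      for orb in self.union_orbits]
            n_vars = self.n_atoms * (self.n_atoms - 1) // 2
            self._compiled = CompiledPolynomials(orbits, n_vars)
        return self._compiled

    def features(self, geometry: Geometry) -> np.ndarray:
        """Feature row [1, p_1(y), ..., p_n(y)] for fitting or evaluation."""
        self._check(geometry)
        y = morse_transform(geometry, self.morse)
        return np.concatenate(([1.0], self.compiled().values(y[None, :])[0]))

    def feature_matrix(self, geometries) -> np.ndarray:
        comp = self.compiled()
        Y = np.stack([morse_transform(g, self.morse) for g in geometries])
        vals = comp.values(Y)
        return np.hstack([np.ones((len(geometries), 1)), vals])

    def energy(self, geometry: Geometry) -> float:
        self._require_fit()
        return float(self.features(geometry) @ self.coefficients)

    def gradient(self, geometry: Geometry) -> np.ndarray:
        return self.energy_gradient(geometry)[1]

    def energy_gradient(self, geometry: Geometry):
        """Analytic (E, dE/dx) in hartree(/bohr) via the Morse chain rule."""
        self._require_fit()
        self._check(geometry)
        X = geometry.coords3
        diff = X[:, None, :] - X[None, :, :]
        r = np.sqrt((diff ** 2).sum(axis=2))
        iu, ju = np.triu_indices(self.n_atoms, 1)
        rv = r[iu, ju]
        y = np.exp(-rv / self.morse.a)
        e, gy = self.compiled().weighted_value_and_grad(y[None, :],
                                                        self.coefficients[1:])
        dEdr = gy[0] * (-y / self.morse.a)
        grad = np.zeros_like(X)
        unit = diff[iu, ju] / rv[:, None]
        np.add.at(grad, iu, dEdr[:, None] * unit)
        np.add.at(grad, ju, -dEdr[:, None] * unit)
        return float(e[0] + self.coefficients[0]), grad.ravel()

    def _check(self, geometry):
        if geometry.n_atoms != self.n_atoms:
            raise ValueError(f"model expects {self.n_atoms} atoms, geometry "
                             f"has {geometry.n_atoms}")

    def _require_fit(self):
        if self.coefficients is None:
            raise ValueError("model has no coefficients; fit it first")

    def to_dict(self) -> dict:
        return {
            "n_atoms": self.n_atoms,
            "max_order": self.max_order,
            "morse_a": self.morse.a,
            "dedup": self.dedup,
            "fragments": [{"center": f.center, "atoms": list(f.atoms),
                           "symmetry": list(f.symmetry)}
                          for f in self.fragments],
            "union_orbits": [[[[list(pair), p] for pair, p in mono]
                              for mono in orb]
                             for orb in self.union_orbits],
            "coefficients": (None if self.coefficients is None
                             else list(self.coefficients)),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FragmentedModel":
        orbits = [tuple(tuple((tuple(pair), p) for pair, p in mono)
                        for mono in orb)
                  for orb in d["union_orbits"]]
        return cls(
            n_atoms=d["n_atoms"],
            fragments=[FragmentSpec(f["center"], list(f["atoms"]),
                                    tuple(f["symmetry"]))
                       for f in d["fragments"]],
            morse=MorseSpec(d["morse_a"]),
            max_order=d["max_order"],
            union_orbits=orbits,
            dedup=d.get("dedup", "all"),
            coefficients=(None if d["coefficients"] is None
                          else np.array(d["coefficients"], float)),
        )


def build_union_basis(fragments, max_order, morse: MorseSpec, n_atoms: int,
                      dedup: str = "all") -> FragmentedModel:
    """Per-fragment PIP bases mapped to global pairs, with deduplication.

    dedup="all": a polynomial is dropped if its global monomial set already
    appeared in ANY earlier fragment (first occurrence kept; the surviving
    set is order-independent).  dedup="chain": it is dropped only if it
    appeared among the SURVIVING entries of the immediately preceding
    fragment, as sequential assembly pipelines do.
    """
    if dedup not in ("all", "chain"):
        raise ValueError("dedup must be 'all' or 'chain'")
    fragments = list(fragments)
    check_permutation_consistency(fragments)
    _warn_uncoupled_methyls(fragments)
    union: list[GlobalOrbit] = []
    union_set: set[GlobalOrbit] = set()
    prev_set: set[GlobalOrbit] = set()
    for frag in fragments:
        basis = enumerate_pips(frag.symmetry, frag.n_atoms, max_order)
        local_pairs = canonical_pairs(frag.n_atoms)
        cur: set[GlobalOrbit] = set()
        for pip in basis.pips:
            gorb = _global_orbit(pip.orbit, frag, local_pairs)
            if dedup == "all":
                if gorb in union_set:
                    continue
            else:
                if gorb in prev_set:
                    continue
            union.append(gorb)
            union_set.add(gorb)
            cur.add(gorb)
        prev_set = cur
    return FragmentedModel(n_atoms=n_atoms, fragments=fragments, morse=morse,
                           max_order=max_order, union_orbits=union, dedup=dedup)
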