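"""Fragment selection, union basis construction, deduplication, and
fragmented-model evaluation."""

from itertools import combinations

import numpy as np
import pytest

import pipchain as pc
from pipchain.chemio import DatasetFile
from pipchain.fragment_basis import (TETRADECANE_FRAGMENTS, FragmentSpec,
                                     build_union_basis,
                                     check_permutation_consistency,
                                     pairwise_max_morse, select_fragment,
                                     union_morse_variables)
from pipchain.pip_basis import MorseSpec, morse_transform
from pipchain.synthetic_data import carbon_hydrogens


class TestPairwiseMaxMorse:
    def test_single_frame_is_its_own_morse_vector(self):
        g = pc.build_alkane(4)
        ds = DatasetFile([g])
        np.testing.assert_array_equal(pairwise_max_morse(ds, MorseSpec(2.0)),
                                      morse_transform(g, MorseSpec(2.0)))

    def test_two_frames_take_shorter_distance(self):
        a = pc.Geometry(["C", "C"], [0, 0, 0, 2.0, 0, 0])
        b = pc.Geometry(["C", "C"], [0, 0, 0, 3.0, 0, 0])
        mm = pairwise_max_morse(DatasetFile([a, b]), MorseSpec(2.0))
        assert mm[0] == pytest.approx(np.exp(-1.0), rel=1e-14)

    def test_bonded_ch_pairs_dominate(self):
        """Bonded C-H contacts carry the largest Morse values in a thermal
        ensemble (they are the shortest distances in an alkane)."""
        ds = pc.sample_dataset(pc.DEFAULT_TOY_PARAMS, 4, pc.SamplerConfig(
            mode="mode_displacement", n_frames=20, seed=5,
            ceiling_cm=30_000))
        mm = pairwise_max_morse(ds, MorseSpec(2.0))
        pairs = [(i, j) for i in range(14) for j in range(i + 1, 14)]
        hyd = carbon_hydrogens(4)
        bonded_ch = {(c, h) for c, hs in enumerate(hyd) for h in hs}
        top = np.argsort(mm)[-10:]
        assert all(pairs[k] in bonded_ch for k in top)

    def test_inconsistent_atom_counts_rejected(self):
        ds = DatasetFile([pc.build_alkane(2)])
        ds.geometries.append(pc.build_alkane(3))  # bypass constructor check
        with pytest.raises(ValueError):
            pairwise_max_morse(ds, MorseSpec(2.0))


def tetradecane_classes():
    return [hs for hs in carbon_hydrogens(14)]


class TestSelectFragment:
    def test_tetradecane_fragments_under_cap_24(self):
        """Greedy closure from centers C1/C7/C13 with cap 24: whole classes
        join as units, the cap is respected, growth stops at the first
        overflowing class (pinned deterministic sizes), and each fragment
        stays a contiguous neighborhood containing its center."""
        g = pc.build_alkane(14)
        mm = pairwise_max_morse(DatasetFile([g]), MorseSpec(2.0))
        sizes = []
        for center in (0, 6, 12):
            frag = select_fragment(center, 24, tetradecane_classes(), mm, 44)
            sizes.append(frag.n_atoms)
            assert frag.n_atoms <= 24
            assert center in frag.atoms
            # every declared H class is wholly inside
            for cls in tetradecane_classes():
                inside = [a for a in cls if a in frag.atoms]
                assert inside == [] or sorted(inside) == sorted(cls)
        assert sizes == [23, 23, 23]

    def test_cap_equal_to_molecule_saturates(self):
        g = pc.build_alkane(4)
        mm = pairwise_max_morse(DatasetFile([g]), MorseSpec(2.0))
        frag = select_fragment(0, 14, [hs for hs in carbon_hydrogens(4)],
                               mm, 14)
        assert sorted(frag.atoms) == list(range(14))

    def test_center_class_exceeding_cap_rejected(self):
        g = pc.build_alkane(4)
        mm = pairwise_max_morse(DatasetFile([g]), MorseSpec(2.0))
        with pytest.raises(ValueError):
            select_fragment(4, 2, [[4, 5, 6]], mm, 14)


class TestUnionBasis:
    def test_union_pair_count_661_for_printed_fragments(self):
        assert len(union_morse_variables(TETRADECANE_FRAGMENTS)) == 661

    def test_inclusion_exclusion_on_pair_sets(self):
        """|A u B u C| from inclusion-exclusion equals the direct union for
        the printed fragments and for random triples."""
        def pairset(f):
            return {frozenset(p) for p in combinations(f.atoms, 2)}

        rng = np.random.default_rng(0)
        triples = [TETRADECANE_FRAGMENTS]
        for _ in range(5):
            frags = []
            for c in range(3):
                atoms = sorted(rng.choice(20, size=rng.integers(4, 9),
                                          replace=False))
                frags.append(FragmentSpec(center=int(atoms[0]),
                                          atoms=[int(a) for a in atoms],
                                          symmetry=(1,) * len(atoms)))
            triples.append(frags)
        for frags in triples:
            A, B, C = (pairset(f) for f in frags)
            ie = (len(A) + len(B) + len(C) - len(A & B) - len(A & C)
                  - len(B & C) + len(A & B & C))
            assert ie == len(A | B | C)
            assert len(A | B | C) == len(union_morse_variables(frags))

    def test_disjoint_fragments_sizes_add(self):
        f1 = FragmentSpec(center=0, atoms=[0, 1, 2], symmetry=(1, 1, 1))
        f2 = FragmentSpec(center=3, atoms=[3, 4, 5], symmetry=(1, 1, 1))
        m = build_union_basis([f1, f2], 2, MorseSpec(2.0), 6)
        m1 = build_union_basis([f1], 2, MorseSpec(2.0), 6)
        assert m.n_pips == 2 * m1.n_pips
        assert len(union_morse_variables([f1, f2])) == 6

    def test_dedup_order_independent_surviving_set(self):
        f1 = FragmentSpec(center=0, atoms=[0, 1, 2, 3], symmetry=(1,) * 4)
        f2 = FragmentSpec(center=2, atoms=[2, 3, 4, 5], symmetry=(1,) * 4)
        a = build_union_basis([f1, f2], 2, MorseSpec(2.0), 6)
        b = build_union_basis([f2, f1], 2, MorseSpec(2.0), 6)
        assert set(a.union_orbits) == set(b.union_orbits)
        # idempotent: rebuilding from the same fragments changes nothing
        again = build_union_basis([f1, f2], 2, MorseSpec(2.0), 6)
        assert again.union_orbits == a.union_orbits

    def test_union_matches_brute_force_set_union(self):
        f1 = FragmentSpec(center=0, atoms=[0, 1, 2, 3], symmetry=(2, 1, 1))
        f2 = FragmentSpec(center=2, atoms=[0, 1, 2, 4], symmetry=(2, 1, 1))
        m = build_union_basis([f1, f2], 2, MorseSpec(2.0), 5)
        seen = set()
        for f in (f1, f2):
            sub = build_union_basis([f], 2, MorseSpec(2.0), 5)
            seen |= set(sub.union_orbits)
        assert set(m.union_orbits) == seen

    def test_inconsistent_shared_classes_rejected(self):
        f1 = FragmentSpec(center=0, atoms=[0, 1, 2], symmetry=(2, 1))
        f2 = FragmentSpec(center=1, atoms=[1, 2, 3], symmetry=(2, 1))
        with pytest.raises(ValueError, match="permut"):
            check_permutation_consistency([f1, f2])


class TestFragmentedEvaluation:
    def test_zero_coefficients_give_constant(self):
        frag = FragmentSpec(center=0, atoms=list(range(8)),
                            symmetry=(1, 1, 3, 3))
        m = build_union_basis([frag], 2, MorseSpec(2.0), 8)
        m.coefficients = np.zeros(m.n_terms)
        m.coefficients[0] = -3.25
        g = pc.build_alkane(2)
        assert m.energy(g) == pytest.approx(-3.25, abs=1e-14)

    def test_declared_methyl_symmetry_exact(self, butane_fragmented_model):
        """Swapping the three H of a declared terminal-methyl class leaves
        the fitted energy unchanged to rounding."""
        model = butane_fragmented_model
        rng = np.random.default_rng(9)
        g0 = pc.build_alkane(4)
        for _ in range(5):
            g = g0.with_coords(g0.coords
                               + rng.normal(scale=0.1, size=g0.coords.size))
            X = g.coords3.copy()
            Xs = X.copy()
            Xs[[4, 5, 6]] = X[[5, 6, 4]]          # cycle methyl H class
            gs = g.with_coords(Xs.ravel())
            assert model.energy(gs) == pytest.approx(model.energy(g),
                                                     rel=1e-12)

    def test_atom_count_mismatch_rejected(self, butane_fragmented_model):
        with pytest.raises(ValueError, match="atoms"):
            butane_fragmented_model.energy(pc.build_alkane(3))

    def test_head_to_tail_interchange_error_small_after_fit(
            self, butane_fragmented_model, butane_dataset):
        """The fragmented basis does not build in head-to-tail interchange
        symmetry (C1<->C4 etc.), but a model fitted to data approximately
        learns it: the RMS energy difference over interchanged pairs is
        within a few data RMSEs."""
        model = butane_fragmented_model
        # butane head-to-tail: C0<->C3, C1<->C2, methyls swap, methylenes swap
        perm = [3, 2, 1, 0, 11, 12, 13, 9, 10, 7, 8, 4, 5, 6]
        rng = np.random.default_rng(4)
        idx = rng.choice(len(butane_dataset), size=100, replace=False)
        diffs = []
        for i in idx:
            g = butane_dataset.geometries[i]
            gp = pc.Geometry(g.elements, g.coords3[perm].ravel())
            diffs.append(model.energy(gp) - model.energy(g))
        rms_cm = float(np.sqrt(np.mean(np.square(diffs)))) * 219474.6313632
        e = butane_dataset.energies()
        pred = model.feature_matrix(butane_dataset.geometries) @ model.coefficients
        fit_rmse_cm = float(np.sqrt(np.mean((pred - e) ** 2))) * 219474.6313632
        assert 0 < rms_cm < 5 * fit_rmse_cm
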