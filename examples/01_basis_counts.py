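"""Enumerate and purify PIP bases; assemble the many-body block table.

Demonstrates the combinatorial backbone of the package: monomial-orbit
enumeration under like-atom permutation symmetry, dissociation-channel
purification, and the assembled many-body coefficient layout.
"""

from pipchain import build_typed_bases, enumerate_pips, purify
from pipchain.fragment_basis import (TETRADECANE_FRAGMENTS, build_union_basis,
                                     union_morse_variables)
from pipchain.pip_basis import MorseSpec

print("Purified PIP counts (symmetry, max order -> raw -> purified):")
for label, sym, n, M in [("A3  (e.g. CCC)", (3,), 3, 8),
                         ("A2B (e.g. CCH)", (2, 1), 3, 8),
                         ("A4  (e.g. CCCC)", (4,), 4, 7),
                         ("A3B (e.g. CCCH)", (3, 1), 4, 7),
                         ("A2B2 (e.g. CCHH)", (2, 2), 4, 7)]:
    raw = enumerate_pips(sym, n, M)
    pur = purify(raw)
    print(f"  {label:16s} order {M}: {len(raw):4d} -> {len(pur):4d}")

model = build_typed_bases()
print("\nMany-body block sizes (coefficients per typed interaction):")
for name, size in model.block_sizes().items():
    print(f"  {name:6s} {size}")
print(f"  total  {model.n_terms}  "
      "(one constant + 2-body powers + purified 3-/4-body PIPs)")

print("\nCanonical three-fragment tetradecane basis:")
print(f"  union Morse variables: {len(union_morse_variables(TETRADECANE_FRAGMENTS))} "
      "of 946 pair distances")
union = build_union_basis(TETRADECANE_FRAGMENTS, 2, MorseSpec(2.0), 44,
                          dedup="chain")
print(f"  union PIP basis at order 2: {union.n_pips} coefficients")
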