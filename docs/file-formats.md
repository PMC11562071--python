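# File formats

## Extended XYZ (datasets)

Plain text, one frame after another:

```
<natoms>
[energy=<float>] [units=<length>,<energy>] [tag=<word>]
<El> <x> <y> <z> [<gx> <gy> <gz>]
...
```

* `units` declares the file's length unit (`bohr` or `angstrom`) and energy
  unit (`hartree` or `cm-1`); a file without the key is read as
  bohr/hartree. Everything converts to bohr/hartree on read.
* `energy` is the frame's reference energy in the declared energy unit.
* Seven-column atom lines carry the energy gradient dE/dx in
  `<energy>/<length>` units as columns 5–7; the column count must be
  consistent within a frame.
* Elements are C and H. The writer emits full-precision `repr` floats, so
  a write/read round trip is bit exact.

The alkane atom-numbering convention used by the builders and the fragment
reports: carbons first along the chain, then hydrogens in carbon order —
three on the first carbon, two per interior carbon, three on the last.
Files and CLI output are 1-based; the API is 0-based.

## Model files (`.pip`)

JSON with a format/version envelope:

```json
{"format": "pipchain-model", "version": 1, "kind": "fragmented" | "manybody",
 "model": {...}}
```

* `fragmented` payload: atom count, order, Morse range, dedup scope, the
  fragment specs (center / atoms / symmetry), every union orbit as global
  ((i, j), power) monomials, and the coefficient vector (constant first).
* `manybody` payload: the NBodyConfig fields and the coefficient vector in
  block order; bases are regenerated deterministically on load.

JSON floats round-trip IEEE doubles exactly (Python `repr` semantics), so
reloaded models reproduce energies bit for bit. Version or kind mismatches
and truncated files raise explicit read errors; no partial model is ever
returned.
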