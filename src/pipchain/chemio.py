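"""Geometry and dataset containers, XYZ / extended-XYZ readers and writers,
and text serialization of fitted models.

The extended-XYZ dialect used here is plain text:

    <natoms>
    [energy=<float>] [units=<length>,<energy>] [tag=<word>]
    <El> <x> <y> <z> [<gx> <gy> <gz>]
    ...

``units`` declares the length unit (``bohr`` or ``angstrom``) and energy unit
(``hartree`` or ``cm-1``) of the file; everything is converted to bohr/hartree
on read.  When the per-atom lines carry seven columns, the last three are the
energy gradient (in <energy>/<length> units).  A file without a ``units`` key
is taken to be in bohr/hartree.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import units

MODEL_FORMAT = "pipchain-model"
MODEL_VERSION = 1

_KNOWN_ELEMENTS = {"H", "C"}


class ChemIOError(Exception):
    """Base error for file parsing and serialization problems."""


class ParseError(ChemIOError):
    pass


@dataclass
class Geometry:
    """A single molecular frame in internal units (bohr / hartree).

    coords is a flat length-3N array in atom order; gradient, when present,
    is dE/dx in hartree/bohr with the same layout.
    """

    elements: list[str]
    coords: np.ndarray
    energy: float | None = None
    gradient: np.ndarray | None = None
    tag: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1)
        if self.coords.size != 3 * len(self.elements):
            raise ValueError(
                f"coords has {self.coords.size} values for {len(self.elements)} atoms"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        for el in self.elements:
            if el not in _KNOWN_ELEMENTS:
                raise ValueError(f"unknown element symbol {el!r}")
        if self.gradient is not None:
            self.gradient = np.asarray(self.gradient, dtype=float).reshape(-1)
            if self.gradient.size != self.coords.size:
                raise ValueError("gradient length does not match 3N")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def coords3(self) -> np.ndarray:
        """(N, 3) view of the coordinates."""
        return self.coords.reshape(-1, 3)

    def with_coords(self, coords, energy=None, gradient=None) -> "Geometry":
        return Geometry(list(self.elements), np.asarray(coords, float).ravel(),
                        energy=energy, gradient=gradient, tag=self.tag)


@dataclass
class DatasetFile:
    """An ordered collection of frames sharing one atom ordering."""

    geometries: list[Geometry]
    length_unit: str = "bohr"
    energy_unit: str = "hartree"
    dialect: str = "extended-xyz"
    ceiling_applied_cm: float | None = field(default=None)

    def __post_init__(self) -> None:
        if self.geometries:
            ref = self.geometries[0].elements
            for g in self.geometries:
                if g.elements != ref:
                    raise ValueError("all frames must share element count and order")

    def __len__(self) -> int:
        return len(self.geometries)

    def energies(self) -> np.ndarray:
        return np.array([g.energy for g in self.geometries], dtype=float)


_LENGTH_TO_BOHR = {"bohr": 1.0, "angstrom": units.BOHR_PER_ANGSTROM}
_ENERGY_TO_HARTREE = {"hartree": 1.0, "cm-1": units.HARTREE_PER_CM}


def read_geometries(path, dialect: str = "extended-xyz") -> DatasetFile:
    """Read a (multi-frame) XYZ or extended-XYZ file into internal units."""
    if dialect not in ("xyz", "extended-xyz"):
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path) as fh:
        lines = fh.read().splitlines()
    geoms: list[Geometry] = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            natoms = int(lines[i].strip())
        except ValueError:
            raise ParseError(f"{path}: line {i + 1}: expected atom count, got "
                             f"{lines[i]!r}") from None
        if i + 1 + natoms >= len(lines) + 1 and i + 1 + natoms > len(lines):
            raise ParseError(f"{path}: line {i + 1}: header says {natoms} atoms "
                             "but the file ends early")
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        keys = _parse_comment(comment) if dialect == "extended-xyz" else {}
        lu, eu = keys.get("units", ("bohr", "hartree"))
        to_bohr = _LENGTH_TO_BOHR[lu]
        to_hartree = _ENERGY_TO_HARTREE[eu]
        elements, xyz, grad = [], [], []
        has_grad = None
        for k in range(natoms):
            ln = i + 2 + k
            if ln >= len(lines) or not lines[ln].split():
                raise ParseError(f"{path}: line {i + 1}: header says {natoms} "
                                 f"atoms but only {k} atom lines follow")
            parts = lines[ln].split()
            if len(parts) not in (4, 7):
                raise ParseError(f"{path}: line {ln + 1}: expected 4 or 7 "
                                 f"columns, got {len(parts)}")
            if has_grad is None:
                has_grad = len(parts) == 7
            elif has_grad != (len(parts) == 7):
                raise ParseError(f"{path}: line {ln + 1}: inconsistent column count")
            el = parts[0]
            if el not in _KNOWN_ELEMENTS:
                raise ParseError(f"{path}: line {ln + 1}: unknown element {el!r}")
            elements.append(el)
            try:
                vals = [float(v) for v in parts[1:]]
            except ValueError:
                raise ParseError(f"{path}: line {ln + 1}: malformed number") from None
            xyz.extend(v * to_bohr for v in vals[:3])
            if has_grad:
                grad.extend(v * to_hartree / to_bohr for v in vals[3:])
        energy = keys.get("energy")
        if energy is not None:
            energy = energy * to_hartree
        geoms.append(Geometry(elements, np.array(xyz), energy=energy,
                              gradient=np.array(grad) if grad else None,
                              tag=keys.get("tag", "")))
        i += 2 + natoms
    return DatasetFile(geoms, dialect=dialect)


def _parse_comment(comment: str) -> dict:
    keys: dict = {}
    for tok in comment.split():
        if "=" not in tok:
            continue
        k, v = tok.split("=", 1)
        if k == "energy":
            keys["energy"] = float(v)
        elif k == "units":
            lu, eu = v.split(",")
            if lu not in _LENGTH_TO_BOHR or eu not in _ENERGY_TO_HARTREE:
                raise ParseError(f"unknown units declaration {v!r}")
            keys["units"] = (lu, eu)
        elif k == "tag":
            keys["tag"] = v
    return keys


def write_geometries(dataset: DatasetFile | list[Geometry], path) -> None:
    """Write frames as extended-XYZ in bohr/hartree at full precision."""
    geoms = dataset.geometries if isinstance(dataset, DatasetFile) else dataset
    with open(path, "w") as fh:
        for g in geoms:
            fh.write(f"{g.n_atoms}\n")
            comment = "units=bohr,hartree"
            if g.energy is not None:
                comment += f" energy={float(g.energy)!r}"
            if g.tag:
                comment += f" tag={g.tag}"
            fh.write(comment + "\n")
            grad = g.gradient.reshape(-1, 3) if g.gradient is not None else None
            for a, (x, y, z) in enumerate(g.coords3):
                line = (f"{g.elements[a]} {float(x)!r} {float(y)!r} "
                        f"{float(z)!r}")
                if grad is not None:
                    line += (f" {float(grad[a, 0])!r} {float(grad[a, 1])!r}"
                             f" {float(grad[a, 2])!r}")
                fh.write(line + "\n")


def write_model(model, path) -> None:
    """Serialize a fitted model to a JSON text file.

    ``repr`` of a Python float round-trips IEEE doubles exactly, and the json
    module uses it, so coefficients survive bit-exactly.
    """
    d = model.to_dict()
    if "coefficients" in d and d["coefficients"] is not None:
        c = np.asarray(d["coefficients"], float)
        if not np.all(np.isfinite(c)):
            raise ChemIOError("refusing to write a model with non-finite coefficients")
    payload = {"format": MODEL_FORMAT, "version": MODEL_VERSION,
               "kind": model.kind, "model": d}
    with open(path, "w") as fh:
        json.dump(payload, fh)


def read_model(path):
    """Load a model written by :func:`write_model`."""
    from .fragment_basis import FragmentedModel
    from .manybody_model import ManyBodyModel

    with open(path) as fh:
        try:
            payload = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ChemIOError(f"{path}: truncated or corrupt model file: {exc}") from None
    if payload.get("format") != MODEL_FORMAT:
        raise ChemIOError(f"{path}: not a {MODEL_FORMAT} file")
    if payload.get("version") != MODEL_VERSION:
        raise ChemIOError(
            f"{path}: model file version {payload.get('version')} "
            f"does not match reader version {MODEL_VERSION}")
    kind = payload.get("kind")
    if kind == "fragmented":
        return FragmentedModel.from_dict(payload["model"])
    if kind == "manybody":
        return ManyBodyModel.from_dict(payload["model"])
    raise ChemIOError(f"{path}: unknown model kind {kind!r}")
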