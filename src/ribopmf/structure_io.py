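"""Minimal multi-model PDB I/O and loop-distance collective variable.

The structural model kept here is deliberately small: ordered residues of
named atoms with coordinates and masses.  It supports exactly what the
downstream annotation and umbrella-sampling analysis need -- ring-atom
lookup, backbone centre-of-mass selections and the loop--loop distance CV.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "StructureModel",
    "LoopDefinition",
    "DEFAULT_BACKBONE_ATOMS",
    "read_pdb",
    "write_pdb",
    "backbone_com",
    "loop_distance",
]

#: Backbone atoms used for the loop centre of mass.  The phosphate oxygens
#: OP1/OP2 are included by default but the set is fully configurable.
DEFAULT_BACKBONE_ATOMS = frozenset(
    {"P", "OP1", "OP2", "O5'", "C5'", "C4'", "C3'", "O3'"}
)

_ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974,
    "S": 32.06, "F": 18.998, "NA": 22.990, "MG": 24.305, "CL": 35.45,
    "K": 39.098, "MN": 54.938, "FE": 55.845, "ZN": 65.38, "BR": 79.904,
    "I": 126.904, "SE": 78.971,
}

# Ribonucleotide residue-name variants: plain, R-prefixed and 5'/3' terminal
# forms all normalize to a single base letter.
_NUC_NAME_RE = re.compile(r"^R?([ACGU])[35]?$")


@dataclass
class Atom:
    """A named atom with position (Å) and mass (amu)."""

    name: str
    residue_index: int
    residue_name: str
    position: np.ndarray
    mass: float

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name}: position must be 3 finite floats")
        if self.mass <= 0:
            raise ValueError(f"atom {self.name}: mass must be positive")


@dataclass
class Residue:
    """An ordered collection of atoms sharing a residue index."""

    index: int
    name: str
    chain: str = "A"
    atoms: list[Atom] = field(default_factory=list)
    is_nucleotide: bool = True

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"residue {self.name}{self.index}: no atom named {name!r}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)


@dataclass
class StructureModel:
    """One MODEL block of a (possibly multi-model) structure."""

    model_id: int
    residues: list[Residue] = field(default_factory=list)

    def nucleotides(self) -> list[Residue]:
        return [r for r in self.residues if r.is_nucleotide]

    def residue(self, index: int, chain: str | None = None) -> Residue:
        for r in self.residues:
            if r.index == index and (chain is None or r.chain == chain):
                return r
        raise KeyError(f"no residue with index {index}")

    def select(self, loop: "LoopDefinition") -> list[Residue]:
        """Nucleotide residues whose index falls in the loop's range."""
        lo, hi = loop.residue_range
        out = [r for r in self.nucleotides() if lo <= r.index <= hi]
        if not out:
            raise ValueError(
                f"loop {loop.label!r}: no nucleotide residues in range {lo}-{hi}"
            )
        return out


@dataclass(frozen=True)
class LoopDefinition:
    """A labelled inclusive residue-index interval, e.g. L2: 20-26."""

    label: str
    residue_range: tuple[int, int]

    def __post_init__(self) -> None:
        lo, hi = self.residue_range
        if hi < lo:
            raise ValueError(f"loop {self.label!r}: empty range {lo}-{hi}")

    @classmethod
    def parse(cls, spec: str) -> "LoopDefinition":
        """Parse ``LABEL:LO-HI``, e.g. ``L2:20-26``."""
        m = re.match(r"^([^:]+):(\d+)-(\d+)$", spec.strip())
        if m is None:
            raise ValueError(f"cannot parse loop definition {spec!r}")
        return cls(m.group(1), (int(m.group(2)), int(m.group(3))))

    def overlaps(self, other: "LoopDefinition") -> bool:
        a, b = self.residue_range, other.residue_range
        return a[0] <= b[1] and b[0] <= a[1]


def _normalize_atom_name(raw: str) -> str:
    # old-style PDBs use * instead of ' for sugar atoms
    return raw.strip().replace("*", "'")


def _normalize_residue_name(raw: str) -> tuple[str, bool]:
    """Map ribonucleotide name variants to A/C/G/U; flag non-nucleotides."""
    name = raw.strip().upper()
    m = _NUC_NAME_RE.match(name)
    if m:
        return m.group(1), True
    return name, False


def _element_of(atom_name: str, element_field: str) -> str:
    el = element_field.strip().upper()
    if el and el in _ATOMIC_MASSES:
        return el
    # infer from the name: strip digits and primes, take leading letters
    stripped = re.sub(r"[0-9'\"]", "", atom_name).upper()
    if not stripped:
        raise ValueError(f"cannot infer element for atom {atom_name!r}")
    if stripped[:2] in _ATOMIC_MASSES and stripped[:2] not in {"CA", "CL", "NA"}:
        return stripped[:2]
    if stripped[0] in _ATOMIC_MASSES:
        return stripped[0]
    if stripped[:2] in _ATOMIC_MASSES:
        return stripped[:2]
    raise ValueError(f"cannot infer element for atom {atom_name!r}")


def read_pdb(path: str | Path) -> list[StructureModel]:
    """Read a (multi-model) PDB file into a list of :class:`StructureModel`.

    One model per MODEL block; a file without MODEL records yields one model.
    Residue names are normalized (``RA``/``A5``/... -> ``A``); ligand and
    solvent residues are kept but flagged ``is_nucleotide=False``.  The first
    alternate location of each atom is kept; insertion codes are rejected.

    Raises
    ------
    ValueError
        On an unparseable coordinate line (the message names the line
        number), on insertion codes, or if no nucleotide residue is found.
    """
    path = Path(path)
    models: list[StructureModel] = []
    current: StructureModel | None = None
    saw_model_record = False

    def _ensure_model() -> StructureModel:
        nonlocal current
        if current is None:
            current = StructureModel(model_id=len(models) + 1)
        return current

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "MODEL":
                saw_model_record = True
                if current is not None and current.residues:
                    models.append(current)
                try:
                    model_id = int(line[6:].split()[0])
                except (IndexError, ValueError):
                    model_id = len(models) + 1
                current = StructureModel(model_id=model_id)
            elif rec == "ENDMDL":
                if current is not None:
                    models.append(current)
                    current = None
            elif rec in ("ATOM", "HETATM"):
                model = _ensure_model()
                try:
                    atom_name = _normalize_atom_name(line[12:16])
                    altloc = line[16].strip()
                    resname_raw = line[17:21].strip()
                    chain = line[21].strip() or "A"
                    resseq = int(line[22:26])
                    icode = line[26].strip()
                    pos = np.array(
                        [float(line[30:38]), float(line[38:46]), float(line[46:54])]
                    )
                    element_field = line[76:78] if len(line) >= 78 else ""
                except (ValueError, IndexError) as exc:
                    raise ValueError(
                        f"{path.name}: unparseable coordinate line {lineno}: {exc}"
                    ) from exc
                if icode:
                    raise ValueError(
                        f"{path.name}: line {lineno}: insertion codes are not supported"
                    )
                resname, is_nuc = _normalize_residue_name(resname_raw)
                residues = model.residues
                if (
                    not residues
                    or residues[-1].index != resseq
                    or residues[-1].chain != chain
                ):
                    residues.append(
                        Residue(index=resseq, name=resname, chain=chain,
                                is_nucleotide=is_nuc)
                    )
                residue = residues[-1]
                if altloc and residue.has_atom(atom_name):
                    continue  # keep the first altloc only
                element = _element_of(atom_name, element_field)
                residue.atoms.append(
                    Atom(atom_name, resseq, resname, pos, _ATOMIC_MASSES[element])
                )
    if current is not None and (current.residues or not saw_model_record):
        models.append(current)
    if not models:
        raise ValueError(f"{path.name}: no coordinate records found")
    if not any(m.nucleotides() for m in models):
        raise ValueError(f"{path.name}: no nucleotide residues found")
    return models


def write_pdb(models: Sequence[StructureModel], path: str | Path) -> None:
    """Write models as a multi-model PDB (MODEL/ENDMDL framing if > 1)."""
    models = list(models)
    multi = len(models) > 1
    with open(path, "w") as fh:
        for model in models:
            if multi:
                fh.write(f"MODEL     {model.model_id:4d}\n")
            serial = 0
            for res in model.residues:
                rec = "ATOM  " if res.is_nucleotide else "HETATM"
                for atom in res.atoms:
                    serial += 1
                    name = atom.name if len(atom.name) >= 4 else f" {atom.name}"
                    el = _element_of(atom.name, "")
                    x, y, z = atom.position
                    fh.write(
                        f"{rec}{serial:5d} {name:<4s} {res.name:>3s} {res.chain}"
                        f"{res.index:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                        f"{1.00:6.2f}{0.00:6.2f}          {el:>2s}\n"
                    )
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


def backbone_com(
    model: StructureModel,
    loop: LoopDefinition,
    atom_set: Iterable[str] = DEFAULT_BACKBONE_ATOMS,
    mass_weighted: bool = True,
) -> np.ndarray:
    """Centre of mass (Å) of the selected backbone atoms of a loop.

    Every residue in the loop range must contribute at least one atom from
    ``atom_set`` (5'-terminal residues lacking P contribute the rest).  With
    ``mass_weighted=False`` the unweighted geometric centroid is returned.
    """
    atom_set = set(atom_set)
    positions: list[np.ndarray] = []
    weights: list[float] = []
    missing: list[str] = []
    for res in model.select(loop):
        atoms = [a for a in res.atoms if a.name in atom_set]
        if not atoms:
            missing.append(f"{res.name}{res.index}")
            continue
        for a in atoms:
            positions.append(a.position)
            weights.append(a.mass if mass_weighted else 1.0)
    if missing:
        raise ValueError(
            f"loop {loop.label!r}: residues with no atom from "
            f"{sorted(atom_set)}: {', '.join(missing)}"
        )
    if not positions:
        raise ValueError(f"loop {loop.label!r}: empty atom selection")
    w = np.asarray(weights)
    p = np.asarray(positions)
    return (w[:, None] * p).sum(axis=0) / w.sum()


def loop_distance(
    model: StructureModel,
    loop_a: LoopDefinition,
    loop_b: LoopDefinition,
    atom_set: Iterable[str] = DEFAULT_BACKBONE_ATOMS,
    mass_weighted: bool = True,
) -> float:
    """Distance L (Å) between the backbone CoMs of two loops.

    Symmetric in loop order and invariant under rigid motion of the model.
    """
    if loop_a.overlaps(loop_b):
        raise ValueError(
            f"loops {loop_a.label!r} and {loop_b.label!r} overlap: "
            f"{loop_a.residue_range} vs {loop_b.residue_range}"
        )
    com_a = backbone_com(model, loop_a, atom_set, mass_weighted)
    com_b = backbone_com(model, loop_b, atom_set, mass_weighted)
    return float(np.linalg.norm(com_a - com_b))
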