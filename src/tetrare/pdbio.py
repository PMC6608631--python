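"""Native fixed-column PDB reading and writing.

Only the records the analysis needs are interpreted: ATOM/HETATM (fixed
columns per the v3.3 format), CRYST1 for cell and space group, and a
``REMARK 3 DPI`` line carrying the Cruickshank diffraction precision
index so that coordinate uncertainty travels with the file.  Everything
else is ignored.  The parser is deliberately strict about the mandatory
columns and reports the offending line number on failure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np

__all__ = ["AtomRecord", "StructureModel", "PDBFormatError", "read_pdb", "write_pdb"]

# two-letter element symbols we may meet in protein/ligand context; used
# only by the fallback element guesser when columns 77-78 are blank
_TWO_LETTER = {
    "RE", "BR", "CL", "NA", "MG", "FE", "ZN", "MN", "CU", "NI", "CO",
    "SE", "CA", "TC", "PT", "AU", "HG", "CD", "OS", "IR", "RU",
}

MAX_SERIAL = 99999


class PDBFormatError(ValueError):
    """Malformed PDB content; carries the 1-based line number."""

    def __init__(self, lineno: int, message: str):
        super().__init__(f"line {lineno}: {message}")
        self.lineno = lineno


@dataclass
class AtomRecord:
    """One ATOM/HETATM record."""

    serial: int
    name: str
    element: str
    residue_name: str
    chain: str
    residue_number: int
    xyz: np.ndarray  # Å
    occupancy: float = 1.0
    b_factor: float = 0.0
    is_het: bool = False
    altloc: str = ""

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (3,) or not np.all(np.isfinite(self.xyz)):
            raise ValueError("xyz must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("occupancy must lie in [0, 1]")
        if not self.element:
            raise ValueError("element must be non-empty")
        self.element = self.element.capitalize()

    def moved(self, xyz) -> "AtomRecord":
        return replace(self, xyz=np.asarray(xyz, float))


@dataclass
class StructureModel:
    """An ordered collection of atoms plus optional crystal metadata."""

    atoms: list[AtomRecord] = field(default_factory=list)
    dpi: float | None = None  # Cruickshank DPI, Å
    cell: tuple[float, float, float, float, float, float] | None = None
    space_group: str | None = None

    def __post_init__(self) -> None:
        if self.dpi is not None and self.dpi < 0:
            raise ValueError("dpi must be >= 0")
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise ValueError("atom serials must be unique within a model")

    def atoms_of_element(self, element: str) -> list[AtomRecord]:
        element = element.capitalize()
        return [a for a in self.atoms if a.element == element]

    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms], dtype=float).reshape(-1, 3)

    def by_residue(self, chain: str, residue_number: int) -> list[AtomRecord]:
        return [
            a
            for a in self.atoms
            if a.chain == chain and a.residue_number == residue_number
        ]


def _guess_element(name: str) -> str:
    stripped = name.strip().lstrip("0123456789")
    alpha = ""
    for ch in stripped:
        if ch.isalpha():
            alpha += ch
        else:
            break
    if len(alpha) >= 2 and alpha[:2].upper() in _TWO_LETTER:
        return alpha[:2].capitalize()
    if alpha:
        return alpha[0].upper()
    raise ValueError(f"cannot infer element from atom name {name!r}")


def _parse_atom_line(line: str, lineno: int) -> AtomRecord:
    if len(line) < 54:
        raise PDBFormatError(lineno, "record shorter than the coordinate columns")
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        altloc = line[16].strip()
        residue_name = line[17:20].strip()
        chain = line[21].strip() or " "
        residue_number = int(line[22:26])
        xyz = (float(line[30:38]), float(line[38:46]), float(line[46:54]))
    except ValueError as exc:
        raise PDBFormatError(lineno, f"malformed mandatory column: {exc}") from None
    occupancy = 1.0
    b_factor = 0.0
    if len(line) >= 60 and line[54:60].strip():
        try:
            occupancy = float(line[54:60])
        except ValueError:
            raise PDBFormatError(lineno, "malformed occupancy") from None
    if len(line) >= 66 and line[60:66].strip():
        try:
            b_factor = float(line[60:66])
        except ValueError:
            raise PDBFormatError(lineno, "malformed B factor") from None
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        element = _guess_element(name)
    return AtomRecord(
        serial=serial,
        name=name,
        element=element,
        residue_name=residue_name,
        chain=chain,
        residue_number=residue_number,
        xyz=np.array(xyz),
        occupancy=occupancy,
        b_factor=b_factor,
        is_het=line.startswith("HETATM"),
        altloc=altloc,
    )


def _dedupe_altlocs(atoms: list[AtomRecord]) -> list[AtomRecord]:
    """Keep the highest-occupancy conformer per site, ties by altloc letter."""
    best: dict[tuple, AtomRecord] = {}
    order: list[tuple] = []
    for atom in atoms:
        key = (atom.chain, atom.residue_number, atom.residue_name, atom.name)
        if not atom.altloc:
            # unambiguous site; keyed by serial so duplicates never collapse
            key = key + (atom.serial,)
        if key not in best:
            best[key] = atom
            order.append(key)
        else:
            held = best[key]
            if atom.occupancy > held.occupancy or (
                atom.occupancy == held.occupancy and atom.altloc < held.altloc
            ):
                best[key] = atom
    return [best[k] for k in order]


def read_pdb(source: str | Path) -> StructureModel:
    """Parse PDB-format text (a path or the text itself) into a model.

    Elements come from columns 77-78, falling back to the leading
    alphabetic characters of the atom name.  Alternate locations are
    collapsed to the highest-occupancy conformer.
    """
    text = source if isinstance(source, str) and "\n" in source else None
    if text is None:
        path = Path(source)
        if path.exists():
            text = path.read_text()
        else:
            text = str(source)
    atoms: list[AtomRecord] = []
    dpi: float | None = None
    cell = None
    space_group = None
    for lineno, line in enumerate(text.splitlines(), 1):
        record = line[:6]
        if record in ("ATOM  ", "HETATM"):
            atoms.append(_parse_atom_line(line, lineno))
        elif record == "CRYST1":
            try:
                cell = tuple(
                    float(line[i : i + 9]) for i in (6, 15, 24)
                ) + tuple(float(line[i : i + 7]) for i in (33, 40, 47))
                space_group = line[55:66].strip() or None
            except ValueError:
                raise PDBFormatError(lineno, "malformed CRYST1") from None
        elif record == "REMARK" and line[7:10].strip() == "3":
            tokens = line.split()
            if len(tokens) >= 4 and tokens[2].upper() == "DPI":
                try:
                    dpi = float(tokens[3])
                except ValueError:
                    raise PDBFormatError(lineno, "malformed REMARK 3 DPI") from None
    if not atoms:
        raise PDBFormatError(0, "no ATOM/HETATM records found")
    return StructureModel(
        atoms=_dedupe_altlocs(atoms), dpi=dpi, cell=cell, space_group=space_group
    )


def _format_name(atom: AtomRecord) -> str:
    # one-letter elements start in column 14, two-letter in column 13
    name = atom.name
    if len(name) >= 4:
        return name[:4]
    if len(atom.element) == 1 and len(name) < 4:
        return f" {name:<3s}"
    return f"{name:<4s}"


def write_pdb(model: StructureModel, destination: str | Path | None = None) -> str:
    """Serialise a model as fixed-column PDB text.

    HETATM is used for the records flagged ``is_het``; occupancy and B are
    written at %6.2f; the element symbol is right-justified in columns
    77-78.  Returns the text, and writes it when a destination is given.
    """
    lines: list[str] = []
    if model.dpi is not None:
        lines.append(f"REMARK   3 DPI {model.dpi:8.4f}")
    if model.cell is not None:
        a, b, c, al, be, ga = model.cell
        sg = (model.space_group or "P 1")[:11]
        lines.append(
            f"CRYST1{a:9.3f}{b:9.3f}{c:9.3f}{al:7.2f}{be:7.2f}{ga:7.2f} {sg:<11s}"
        )
    for atom in model.atoms:
        if atom.serial > MAX_SERIAL:
            raise ValueError(f"serial {atom.serial} exceeds the PDB format limit")
        record = "HETATM" if atom.is_het else "ATOM  "
        x, y, z = atom.xyz
        lines.append(
            f"{record}{atom.serial:5d} {_format_name(atom)}{atom.altloc[:1] or ' '}"
            f"{atom.residue_name:>3s} {atom.chain:1s}{atom.residue_number:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{atom.b_factor:6.2f}"
            f"          {atom.element.upper():>2s}"
        )
    lines.append("END")
    text = "\n".join(lines) + "\n"
    if destination is not None:
        Path(destination).write_text(text)
    return text
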