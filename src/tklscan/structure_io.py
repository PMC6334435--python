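"""Macromolecular coordinate and alignment I/O.

The data model is deliberately small: a :class:`Structure` is an ordered set
of polymer chains plus a flat collection of hetero residues (ligands, metal
ions, waters).  Author residue numbering (with insertion codes) is the
canonical addressing scheme throughout the package, because that is how the
literature cites active-site residues (H77, H110, E366, ...).  Sequential
indices never leak out of a module.

Reading goes through gemmi; writing emits fixed-width PDB records directly so
that round-trip precision (10^-3 A, the PDB field width) is under our
control.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence

import gemmi
import numpy as np
from Bio import AlignIO
from Bio.SeqUtils import seq1

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "Structure",
    "Alignment",
    "ResiduePointer",
    "StructureFormatError",
    "read_structure",
    "write_structure",
    "read_alignment",
    "chain_to_sequence",
]

#: elements treated as metals when partitioning hetero residues
METAL_ELEMENTS = {"MG", "CA", "ZN", "MN", "FE", "NA", "K", "CU", "NI", "CO"}

WATER_NAMES = {"HOH", "WAT", "DOD"}


class StructureFormatError(ValueError):
    """Raised when a coordinate or alignment file cannot be interpreted."""


@dataclass
class Atom:
    """One atom: name, element, Cartesian coordinates in Angstrom."""

    serial: int
    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coords must be a finite 3-vector")
        if not self.element:
            raise ValueError(f"atom {self.name}: element symbol required")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0,1]")


@dataclass(frozen=True)
class ResiduePointer:
    """Author-numbering address of a residue: (chain, number, icode)."""

    chain_id: str
    number: int
    icode: str = ""

    def __str__(self) -> str:
        return f"{self.chain_id}/{self.number}{self.icode}"


@dataclass
class Residue:
    """A polymer residue or hetero group, holding its atoms in file order."""

    name: str
    number: int
    icode: str = ""
    chain_id: str = "A"
    atoms: list[Atom] = field(default_factory=list)
    is_water: bool = False

    @property
    def pointer(self) -> ResiduePointer:
        return ResiduePointer(self.chain_id, self.number, self.icode)

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def is_metal(self) -> bool:
        return len(self.atoms) == 1 and self.atoms[0].element.upper() in METAL_ELEMENTS

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.element.upper() not in ("H", "D")]


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def residue(self, number: int, icode: str = "") -> Optional[Residue]:
        for r in self.residues:
            if r.number == number and r.icode == icode:
                return r
        return None


@dataclass
class Structure:
    """Polymer chains plus hetero residues (ligands, ions, waters)."""

    id: str
    chains: list[Chain] = field(default_factory=list)
    ligands: list[Residue] = field(default_factory=list)
    source_path: str = ""

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r} in structure {self.id}")

    def polymer_atoms(self) -> Iterator[tuple[Residue, Atom]]:
        for c in self.chains:
            for r in c:
                for a in r.atoms:
                    yield r, a

    def ligand_atoms(self, include_waters: bool = False) -> Iterator[tuple[Residue, Atom]]:
        for r in self.ligands:
            if r.is_water and not include_waters:
                continue
            for a in r.atoms:
                yield r, a

    def all_atoms(self) -> Iterator[tuple[Residue, Atom]]:
        yield from self.polymer_atoms()
        for r in self.ligands:
            for a in r.atoms:
                yield r, a

    def find_residue(self, ptr: ResiduePointer) -> Optional[Residue]:
        for c in self.chains:
            if c.id == ptr.chain_id:
                r = c.residue(ptr.number, ptr.icode)
                if r is not None:
                    return r
        for r in self.ligands:
            if r.pointer == ptr:
                return r
        return None

    def copy(self) -> "Structure":
        return copy.deepcopy(self)


@dataclass
class Alignment:
    """Gapped, equal-length sequence rows keyed by identifier."""

    names: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.rows):
            raise ValueError("names and rows differ in count")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            ragged = [n for n, r in zip(self.names, self.rows)
                      if len(r) != len(self.rows[0])]
            raise StructureFormatError(
                f"alignment rows have unequal lengths (offenders: {', '.join(ragged)})"
            )

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, name: str) -> str:
        try:
            return self.rows[self.names.index(name)]
        except ValueError:
            raise KeyError(f"no sequence {name!r} in alignment") from None

    def ungapped(self, name: str) -> str:
        return self.row(name).replace("-", "").replace(".", "")


# ---------------------------------------------------------------------------
# reading

def _resolve_altlocs(atoms: list[Atom], policy: str) -> list[Atom]:
    """Keep one atom per name: highest occupancy, ties broken by altloc char."""
    if policy == "all":
        return atoms
    by_name: dict[str, list[Atom]] = {}
    order: list[str] = []
    for a in atoms:
        if a.name not in by_name:
            order.append(a.name)
        by_name.setdefault(a.name, []).append(a)
    kept = []
    for name in order:
        group = by_name[name]
        if len(group) == 1:
            kept.append(group[0])
        else:
            # ties -> altloc 'A' (smallest altloc char sorts first)
            best = sorted(group, key=lambda a: (-a.occupancy, a.altloc or "~"))[0]
            kept.append(best)
    return kept


def read_structure(
    path: str | Path,
    model_index: int = 0,
    altloc_policy: str = "occupancy",
) -> Structure:
    """Read a PDB (or mmCIF) file into the package data model.

    Parameters
    ----------
    path
        Coordinate file. Format detected by gemmi from the contents.
    model_index
        Which MODEL block to use (0-based). Multi-model NMR-style files keep
        only the selected model.
    altloc_policy
        ``"occupancy"`` (default) keeps, per atom name, the alternate location
        with the highest occupancy, ties resolved toward altloc ``'A'``;
        ``"all"`` keeps every alternate.

    Returns
    -------
    Structure
        Polymer chains and hetero residues partitioned; every atom belongs to
        exactly one of the two sets.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path), merge_chain_parts=True)
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise StructureFormatError(f"{path}: no coordinate models found")
    if model_index >= len(st):
        raise StructureFormatError(
            f"{path}: model index {model_index} out of range ({len(st)} models)"
        )
    st.setup_entities()
    model = st[model_index]

    out = Structure(id=st.name or path.stem, source_path=str(path))
    n_polymer = 0
    n_missing_ca = 0
    for gchain in model:
        chain = Chain(id=gchain.name)
        for gres in gchain:
            atoms = []
            het = gres.het_flag == "H"
            for ga in gres:
                atoms.append(
                    Atom(
                        serial=ga.serial,
                        name=ga.name,
                        element=ga.element.name or ga.name[:1],
                        coords=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                        occupancy=min(max(ga.occ, 0.0), 1.0),
                        altloc="" if ga.altloc in ("\0", " ", "") else ga.altloc,
                        is_hetero=het,
                    )
                )
            atoms = _resolve_altlocs(atoms, altloc_policy)
            res = Residue(
                name=gres.name,
                number=gres.seqid.num,
                icode=(gres.seqid.icode or "").strip(),
                chain_id=gchain.name,
                atoms=atoms,
                is_water=gres.name in WATER_NAMES,
            )
            if het or res.is_water:
                out.ligands.append(res)
            else:
                chain.residues.append(res)
                n_polymer += 1
                if res.atom("CA") is None:
                    n_missing_ca += 1
        if chain.residues:
            out.chains.append(chain)
    if not out.chains:
        raise StructureFormatError(f"{path}: no polymer chains found")
    if n_polymer and n_missing_ca / n_polymer > 0.20:
        import warnings

        warnings.warn(
            f"{path}: {n_missing_ca}/{n_polymer} polymer residues lack a CA atom",
            stacklevel=2,
        )
    return out


# ---------------------------------------------------------------------------
# writing

_PDB_ATOM = (
    "{record:<6s}{serial:>5d} {name:<4s}{altloc:1s}{resname:<3s} {chain:1s}"
    "{resnum:>4d}{icode:1s}   {x:>8.3f}{y:>8.3f}{z:>8.3f}{occ:>6.2f}{b:>6.2f}"
    "          {element:>2s}\n"
)


def _format_atom_name(name: str, element: str) -> str:
    # PDB convention: element right-justified in cols 13-14 for 1-2 char
    # element symbols, so short names of light atoms get a leading space.
    if len(name) >= 4:
        return name[:4]
    if len(element) == 2:
        return f"{name:<4s}"[:4]
    return f" {name:<3s}"[:4]


def write_structure(s: Structure, path: str | Path) -> None:
    """Write ``s`` as a PDB file (ATOM/HETATM/TER/END records).

    Author numbering and insertion codes are preserved. Raises
    :class:`ValueError` naming the atom if a coordinate does not fit the
    fixed-width field (|x| >= 10^4).
    """
    lines: list[str] = []
    serial = 0

    def emit(res: Residue, atom: Atom, record: str) -> None:
        nonlocal serial
        serial += 1
        x, y, z = atom.coords
        if max(abs(x), abs(y), abs(z)) >= 1e4:
            raise ValueError(
                f"coordinate overflow on atom {atom.name} of "
                f"{res.name} {res.pointer}: |coord| >= 10^4 A"
            )
        lines.append(
            _PDB_ATOM.format(
                record=record,
                serial=serial % 100000,
                name=_format_atom_name(atom.name, atom.element),
                altloc=atom.altloc or " ",
                resname=res.name[:3],
                chain=res.chain_id[:1] or "A",
                resnum=res.number,
                icode=res.icode or " ",
                x=x,
                y=y,
                z=z,
                occ=atom.occupancy,
                b=0.0,
                element=atom.element.upper()[:2],
            )
        )

    for chain in s.chains:
        last = None
        for res in chain:
            for atom in res.atoms:
                emit(res, atom, "ATOM")
            last = res
        if last is not None:
            serial += 1
            lines.append(
                f"TER   {serial % 100000:>5d}      {last.name:<3s} "
                f"{last.chain_id[:1]:1s}{last.number:>4d}{last.icode or ' ':1s}\n"
            )
    for res in s.ligands:
        for atom in res.atoms:
            emit(res, atom, "HETATM")
    lines.append("END\n")
    Path(path).write_text("".join(lines))


# ---------------------------------------------------------------------------
# sequences and alignments

def read_alignment(path: str | Path, dialect: str = "fasta") -> Alignment:
    """Read a FASTA or Clustal multiple alignment.

    The alignment is consumed, never computed: it is upstream input in the
    same way the coordinate files are.
    """
    if dialect not in ("fasta", "clustal"):
        raise ValueError(f"unknown alignment dialect {dialect!r}")
    try:
        aln = AlignIO.read(str(path), dialect)
    except ValueError as exc:
        raise StructureFormatError(f"{path}: {exc}") from exc
    names = [rec.id for rec in aln]
    rows = [str(rec.seq).upper() for rec in aln]
    if len(rows) < 2:
        raise StructureFormatError(f"{path}: an alignment needs at least 2 rows")
    return Alignment(names=names, rows=rows)


def chain_to_sequence(
    s: Structure, chain_id: str
) -> tuple[str, list[tuple[int, str]]]:
    """One-letter sequence of a chain with parallel author numbering.

    Non-standard residues become ``'X'``. Numbering gaps are not padded; the
    numbering list records the jump.
    """
    chain = s.chain(chain_id)
    letters = []
    numbering = []
    for res in chain:
        letters.append(seq1(res.name.capitalize(), undef_code="X"))
        numbering.append((res.number, res.icode))
    return "".join(letters), numbering
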