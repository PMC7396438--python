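"""PDB-format coordinate I/O and the selection/geometry primitives.

The in-memory model is a lightweight chain -> residue -> atom hierarchy in
ångströms, in the frame of the input file. Parsing and serialisation are
delegated to gemmi; this module owns the domain model and its contracts:
altloc resolution (first-listed wins), residue identity including insertion
codes, heavy-atom filtering, and minimum inter-residue distances.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import gemmi
import numpy as np
from scipy.spatial.distance import cdist

from .errors import (
    EmptyInputError,
    EmptySelectionError,
    PDBFormatError,
    SelectionError,
)

STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

#: Default alias table mapping non-standard 3-letter codes to a parent
#: amino acid (e.g. a photo-reactive benzophenone site modelled as Phe,
#: selenomethionine as Met). Extendable via ``read_pdb(aliases=...)`` or a
#: two-column text file loaded with :func:`read_alias_table`.
DEFAULT_ALIASES: dict[str, str] = {
    "MSE": "MET",
    "BPA": "PHE",
    "SEC": "CYS",
    "PYL": "LYS",
}

ResidueId = tuple[str, int, str]  # (chain_id, seq_number, insertion_code)


@dataclass
class Atom:
    """A named atom with an element symbol and a 3-vector coordinate in Å."""

    name: str
    element: str
    coord: np.ndarray

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if not self.name:
            raise ValueError("atom name must be non-empty")
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name}: coordinate must be a finite 3-vector")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


@dataclass
class Residue:
    chain_id: str
    seq_number: int
    aa_type: str
    atoms: list[Atom] = field(default_factory=list)
    insertion_code: str = ""

    @property
    def id(self) -> ResidueId:
        return (self.chain_id, self.seq_number, self.insertion_code)

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def get_atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def filtered_atoms(self, atom_filter) -> list[Atom]:
        """Atoms passing ``atom_filter``: "heavy", "all", or a set of names."""
        if atom_filter == "heavy":
            return self.heavy_atoms()
        if atom_filter == "all":
            return list(self.atoms)
        names = set(atom_filter)
        return [a for a in self.atoms if a.name in names]


@dataclass
class Structure:
    """Ordered chains of residues; resolvable by (chain, number, icode)."""

    id: str
    chains: dict[str, list[Residue]] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def residues(self) -> Iterator[Residue]:
        for residues in self.chains.values():
            yield from residues

    def n_residues(self) -> int:
        return sum(len(r) for r in self.chains.values())

    def residue(self, chain_id: str, seq_number: int, icode: str = "") -> Residue:
        for res in self.chains.get(chain_id, []):
            if res.seq_number == seq_number and res.insertion_code == icode:
                return res
        raise SelectionError(
            f"residue {chain_id}:{seq_number}{icode} not found in structure {self.id!r}"
        )

    def has_residue(self, chain_id: str, seq_number: int, icode: str = "") -> bool:
        try:
            self.residue(chain_id, seq_number, icode)
            return True
        except SelectionError:
            return False

    def heavy_coords(self) -> np.ndarray:
        pts = [a.coord for r in self.residues() for a in r.heavy_atoms()]
        return np.array(pts, dtype=float) if pts else np.empty((0, 3))

    def all_coords(self) -> np.ndarray:
        pts = [a.coord for r in self.residues() for a in r.atoms]
        return np.array(pts, dtype=float) if pts else np.empty((0, 3))

    def copy(self) -> "Structure":
        chains = {
            cid: [
                Residue(
                    r.chain_id, r.seq_number, r.aa_type,
                    [Atom(a.name, a.element, a.coord.copy()) for a in r.atoms],
                    r.insertion_code,
                )
                for r in residues
            ]
            for cid, residues in self.chains.items()
        }
        return Structure(self.id, chains, dict(self.metadata))

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Return a copy with every coordinate mapped to R x + t."""
        out = self.copy()
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        for res in out.residues():
            for a in res.atoms:
                a.coord = R @ a.coord + t
        return out

    def centroid(self, heavy_only: bool = True) -> np.ndarray:
        coords = self.heavy_coords() if heavy_only else self.all_coords()
        if coords.size == 0:
            raise EmptyInputError(f"structure {self.id!r} has no atoms")
        return coords.mean(axis=0)


def _element_from_name(name: str) -> str:
    """Guess an element symbol from a PDB atom name (fallback path only)."""
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        return "X"
    if stripped[0] in ("H", "D") and name.strip()[0].isdigit():
        return "H"
    for two in ("CL", "BR", "FE", "ZN", "MG", "SE"):
        if stripped.upper().startswith(two):
            return two.capitalize()
    return stripped[0].upper()


def _prescan_pdb(path: str) -> int:
    """Validate coordinate columns of ATOM/HETATM records; return the count."""
    n = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM  ", "HETATM")):
                n += 1
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    fieldstr = line[lo:hi]
                    try:
                        float(fieldstr)
                    except ValueError:
                        raise PDBFormatError(
                            f"{path}: unparsable coordinate field {fieldstr!r} "
                            f"on line {lineno}"
                        ) from None
    return n


def read_alias_table(path: str) -> dict[str, str]:
    """Load a two-column text alias table (non-standard code -> parent)."""
    table: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) != 2:
                raise PDBFormatError(f"{path}: alias lines need two columns: {line!r}")
            table[cols[0].upper()] = cols[1].upper()
    return table


def read_pdb(path: str, aliases: Mapping[str, str] | None = None) -> Structure:
    """Read a fixed-column PDB file into a :class:`Structure`.

    Rows with a standard amino-acid type (or one aliased to a parent amino
    acid) become atoms; waters/ligands are skipped. Alternate locations keep
    the first-listed conformer. Hydrogens are retained and excluded later by
    the "heavy" atom filter.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    n_records = _prescan_pdb(path)
    if n_records == 0:
        raise EmptyInputError(f"{path}: no ATOM/HETATM records")
    alias_table = dict(DEFAULT_ALIASES)
    if aliases:
        alias_table.update({k.upper(): v.upper() for k, v in aliases.items()})
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - gemmi is lenient
        raise PDBFormatError(f"{path}: {exc}") from exc

    out = Structure(id=st.name or os.path.basename(path))
    model = st[0]
    for chain in model:
        residues: list[Residue] = []
        for res in chain:
            name = res.name.upper()
            if name in alias_table:
                name = alias_table[name]
            if name not in STANDARD_AA:
                continue
            icode = res.seqid.icode.strip()
            residue = Residue(chain.name, res.seqid.num, name, [], icode)
            seen: set[str] = set()
            for atom in res:
                if atom.name in seen:  # altloc duplicates: first-listed wins
                    continue
                seen.add(atom.name)
                element = atom.element.name if atom.element else ""
                if not element or element == "X":
                    element = _element_from_name(atom.name)
                residue.atoms.append(
                    Atom(atom.name, element, np.array([atom.pos.x, atom.pos.y, atom.pos.z]))
                )
            if residue.atoms:
                residues.append(residue)
        if residues:
            out.chains.setdefault(chain.name, []).extend(residues)
    if out.n_residues() == 0:
        raise EmptyInputError(f"{path}: no standard amino-acid residues")
    return out


def write_pdb(s: Structure, path: str) -> None:
    """Write fixed-column ATOM records, one TER per chain.

    ``read_pdb(write_pdb(s))`` preserves identities and coordinates to the
    3-decimal precision of the format.
    """
    if not s.chains or s.n_residues() == 0:
        raise EmptyInputError("cannot write a structure with no residues")
    st = gemmi.Structure()
    st.name = s.id
    model = gemmi.Model("1")
    for cid, residues in s.chains.items():
        chain = gemmi.Chain(cid)
        for res in residues:
            gres = gemmi.Residue()
            gres.name = res.aa_type
            gres.seqid = gemmi.SeqId(res.seq_number, res.insertion_code or " ")
            for atom in res.atoms:
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element)
                ga.occ = 1.0
                ga.b_iso = 0.0
                ga.pos = gemmi.Position(*atom.coord)
                gres.add_atom(ga)
            chain.add_residue(gres)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def select(
    s: Structure, chain: str, numbers: Iterable[int]
) -> tuple[list[Residue], list[int]]:
    """Residues of ``chain`` with the given numbers, in input order.

    Returns (found residues, missing numbers); missing numbers are reported
    rather than silently dropped.
    """
    if chain not in s.chains:
        raise SelectionError(f"chain {chain!r} not in structure {s.id!r}")
    wanted = set(numbers)
    found = [r for r in s.chains[chain] if r.seq_number in wanted]
    present = {r.seq_number for r in found}
    missing = sorted(wanted - present)
    return found, missing


def min_distance(a: Residue, b: Residue, atom_filter="heavy") -> float:
    """Minimum Euclidean distance over the filtered atom-pair cross product."""
    atoms_a = a.filtered_atoms(atom_filter)
    atoms_b = b.filtered_atoms(atom_filter)
    if not atoms_a or not atoms_b:
        raise EmptySelectionError(
            f"atom filter {atom_filter!r} leaves no atoms on "
            f"{a.id if not atoms_a else b.id}"
        )
    ca = np.array([x.coord for x in atoms_a])
    cb = np.array([x.coord for x in atoms_b])
    return float(cdist(ca, cb).min())
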