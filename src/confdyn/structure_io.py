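"""Protein structures, atom selections and coordinate trajectories.

A :class:`Structure` is an ordered collection of :class:`AtomRecord` objects
with a unique ``(chain_id, residue_number, atom_name)`` index, carrying
coordinates in nanometres and author (PDB) residue numbering verbatim.
PDB reading and writing is delegated to :mod:`biotite`, with the package
enforcing its own contracts on top: first-listed altloc kept (with a
warning), insertion codes rejected, duplicate atom keys rejected, and
Å↔nm conversion at the I/O boundary only.

Missing atoms make selections fail loudly rather than being skipped:
a gap-free, prepared structure is the caller's responsibility.
"""

from __future__ import annotations

import io
import os
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile

from .constants import NM_PER_ANGSTROM

__all__ = [
    "AtomRecord",
    "Structure",
    "AtomSelection",
    "Trajectory",
    "PDBParseError",
    "read_pdb",
    "write_pdb",
    "select_coords",
]

# Canonical intra-residue atom ordering: backbone first, then side chain.
_CANONICAL_ORDER = {"N": 0, "CA": 1, "C": 2, "O": 3, "CB": 4}


def _atom_rank(name: str) -> tuple[int, str]:
    return (_CANONICAL_ORDER.get(name, 5), name)


class PDBParseError(ValueError):
    """Raised when a PDB source cannot be parsed into a Structure."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom: identity plus coordinates in nm (author residue numbering)."""

    serial: int
    name: str
    residue_name: str
    chain_id: str
    residue_number: int
    coordinates: np.ndarray
    element: str = ""

    def __post_init__(self) -> None:
        coords = np.asarray(self.coordinates, dtype=float)
        if coords.shape != (3,):
            raise ValueError(f"coordinates must be a 3-vector, got {coords.shape}")
        if not np.all(np.isfinite(coords)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")
        if not self.name:
            raise ValueError("atom name must be nonempty")
        object.__setattr__(self, "coordinates", coords)


class Structure:
    """Ordered atom collection with a unique (chain, resnum, name) index."""

    def __init__(self, atoms: Iterable[AtomRecord]):
        self.atoms: list[AtomRecord] = list(atoms)
        self._index: dict[tuple[str, int, str], int] = {}
        for i, atom in enumerate(self.atoms):
            key = (atom.chain_id, atom.residue_number, atom.name)
            if key in self._index:
                raise ValueError(f"duplicate atom key {key}")
            self._index[key] = i

    def __len__(self) -> int:
        return len(self.atoms)

    def __repr__(self) -> str:
        return f"Structure({len(self.atoms)} atoms)"

    @property
    def coords(self) -> np.ndarray:
        """All coordinates as an (n_atoms, 3) array, nm."""
        if not self.atoms:
            return np.empty((0, 3))
        return np.array([a.coordinates for a in self.atoms])

    def contains(self, chain_id: str, residue_number: int, name: str) -> bool:
        return (chain_id, residue_number, name) in self._index

    def atom_index(self, chain_id: str, residue_number: int, name: str) -> int:
        try:
            return self._index[(chain_id, residue_number, name)]
        except KeyError:
            raise KeyError(
                f"no atom ({chain_id!r}, {residue_number}, {name!r}) in structure"
            ) from None

    def lookup(self, chain_id: str, residue_number: int, name: str) -> AtomRecord:
        return self.atoms[self.atom_index(chain_id, residue_number, name)]

    def chain_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)

    def residue_numbers(self, chain_id: str | None = None) -> list[int]:
        seen: dict[int, None] = {}
        for a in self.atoms:
            if chain_id is None or a.chain_id == chain_id:
                seen.setdefault(a.residue_number, None)
        return sorted(seen)

    def with_coords(self, coords: np.ndarray) -> "Structure":
        """Same topology with replaced coordinates (n_atoms, 3)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError(
                f"coordinate shape {coords.shape} does not match "
                f"({len(self.atoms)}, 3)"
            )
        return Structure(
            AtomRecord(
                serial=a.serial,
                name=a.name,
                residue_name=a.residue_name,
                chain_id=a.chain_id,
                residue_number=a.residue_number,
                coordinates=c,
                element=a.element,
            )
            for a, c in zip(self.atoms, coords)
        )

    def subset(self, indices: Sequence[int]) -> "Structure":
        return Structure(self.atoms[i] for i in indices)


@dataclass(frozen=True)
class AtomSelection:
    """Deterministic atom selection by chain, residue range(s) and atom names.

    ``residue_ranges`` are inclusive ``(first, last)`` pairs in author
    numbering; ``None`` selects every residue.  ``atom_names=None`` selects
    every atom of a residue.  Resolution is ordered by (chain, residue
    number, canonical atom order) and fails loudly when any requested
    residue or atom is absent.
    """

    chain_id: str | None = None
    residue_ranges: tuple[tuple[int, int], ...] | None = None
    atom_names: tuple[str, ...] | None = None

    @staticmethod
    def ca(first: int, last: int, chain_id: str | None = None) -> "AtomSelection":
        """Cα atoms of an inclusive residue range."""
        return AtomSelection(chain_id=chain_id, residue_ranges=((first, last),),
                             atom_names=("CA",))

    @staticmethod
    def backbone(first: int, last: int, chain_id: str | None = None) -> "AtomSelection":
        """Backbone N, CA, C, O of an inclusive residue range."""
        return AtomSelection(chain_id=chain_id, residue_ranges=((first, last),),
                             atom_names=("N", "CA", "C", "O"))

    def _wanted_residues(self, structure: Structure, chain: str) -> list[int]:
        present = structure.residue_numbers(chain)
        if self.residue_ranges is None:
            return present
        wanted: list[int] = []
        for first, last in self.residue_ranges:
            if last < first:
                raise ValueError(f"empty residue range ({first}, {last})")
            wanted.extend(range(first, last + 1))
        return wanted

    def resolve(self, structure: Structure) -> np.ndarray:
        """Ordered atom indices on ``structure``; error listing anything missing."""
        chains = [self.chain_id] if self.chain_id is not None else structure.chain_ids()
        indices: list[int] = []
        missing: list[tuple[str, int, str]] = []
        for chain in chains:
            for resnum in self._wanted_residues(structure, chain):
                names = self._residue_atom_names(structure, chain, resnum)
                for name in names:
                    if structure.contains(chain, resnum, name):
                        indices.append(structure.atom_index(chain, resnum, name))
                    else:
                        missing.append((chain, resnum, name))
        if missing:
            raise KeyError(f"selection atoms missing from structure: {missing}")
        if not indices:
            raise ValueError("selection resolves to no atoms")
        return np.asarray(indices, dtype=int)

    def _residue_atom_names(
        self, structure: Structure, chain: str, resnum: int
    ) -> list[str]:
        if self.atom_names is not None:
            return sorted(self.atom_names, key=_atom_rank)
        names = [
            a.name
            for a in structure.atoms
            if a.chain_id == chain and a.residue_number == resnum
        ]
        if not names:
            # whole residue absent: report its CA as the representative gap
            return ["CA"]
        return sorted(names, key=_atom_rank)


def select_coords(structure: Structure, selection: AtomSelection) -> np.ndarray:
    """Coordinate matrix (n_selected, 3) in nm for a selection.

    Deterministic ordering by (chain, residue number, canonical atom order);
    any missing atom raises with the offending (chain, resnum, name) keys.
    """
    idx = selection.resolve(structure)
    return structure.coords[idx]


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def _as_pdb_text(source: str | Path) -> str:
    if isinstance(source, Path):
        return source.read_text()
    if isinstance(source, str):
        if "\n" not in source and os.path.exists(source):
            return Path(source).read_text()
        return source
    raise TypeError(f"source must be a path or PDB text, got {type(source)}")


def _prescan(text: str) -> None:
    """Reject insertion codes, warn on altlocs, name malformed lines."""
    altloc_warned = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        if len(line) < 54:
            raise PDBParseError(f"line {lineno}: truncated ATOM record")
        if line[26] != " ":
            raise PDBParseError(
                f"line {lineno}: insertion code {line[26]!r} not supported; "
                "renumber the structure first"
            )
        if line[16] not in (" ", "A", "1") and not altloc_warned:
            warnings.warn(
                f"line {lineno}: alternate locations present; keeping the "
                "first-listed conformer",
                stacklevel=3,
            )
            altloc_warned = True
        try:
            int(line[22:26])
            for lo, hi in ((30, 38), (38, 46), (46, 54)):
                float(line[lo:hi])
        except ValueError as exc:
            raise PDBParseError(f"line {lineno}: malformed ATOM record ({exc})") from None


def read_pdb(source: str | Path) -> Structure:
    """Parse PDB text or a PDB file into a :class:`Structure` (coordinates nm).

    One :class:`AtomRecord` per ATOM/HETATM record of the first model; the
    first-listed altloc is kept (with a warning); insertion codes are
    rejected; duplicate (chain, resnum, name) keys after altloc filtering
    raise an error.
    """
    text = _as_pdb_text(source)
    _prescan(text)
    try:
        pdb = PDBFile.read(io.StringIO(text))
        arr = pdb.get_structure(model=1, altloc="first", extra_fields=["atom_id"])
    except PDBParseError:
        raise
    except Exception as exc:  # biotite error types vary; re-raise uniformly
        raise PDBParseError(f"could not parse PDB source: {exc}") from exc
    atoms = [
        AtomRecord(
            serial=int(arr.atom_id[i]),
            name=str(arr.atom_name[i]),
            residue_name=str(arr.res_name[i]),
            chain_id=str(arr.chain_id[i]),
            residue_number=int(arr.res_id[i]),
            coordinates=arr.coord[i] * NM_PER_ANGSTROM,
            element=str(arr.element[i]),
        )
        for i in range(arr.array_length())
    ]
    try:
        return Structure(atoms)
    except ValueError as exc:
        raise PDBParseError(str(exc)) from None


def write_pdb(structure: Structure, destination: str | Path) -> None:
    """Write standard fixed-width ATOM records (nm→Å, serials renumbered 1..N)."""
    destination = Path(destination)
    if not structure.atoms:
        destination.write_text("END\n")
        return
    coords_a = structure.coords / NM_PER_ANGSTROM
    if np.any(coords_a >= 10000.0) or np.any(coords_a <= -1000.0):
        raise ValueError("coordinates overflow fixed-width PDB columns")
    n = len(structure.atoms)
    arr = bst.AtomArray(n)
    arr.coord = coords_a
    arr.chain_id = np.array([a.chain_id for a in structure.atoms])
    arr.res_id = np.array([a.residue_number for a in structure.atoms])
    arr.res_name = np.array([a.residue_name for a in structure.atoms])
    arr.atom_name = np.array([a.name for a in structure.atoms])
    arr.element = np.array([a.element or a.name[0] for a in structure.atoms])
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(destination)
    text = destination.read_text()
    if "END" not in text.rsplit("\n", 2)[-2:][0]:
        destination.write_text(text.rstrip("\n") + "\nEND\n")


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

class Trajectory:
    """Ordered frames of coordinates (nm) over a fixed atom topology.

    Serializable to a simple self-describing whitespace text format
    (portable, diffable; one coordinate triple per line).
    """

    def __init__(
        self,
        topology: Structure,
        coords: np.ndarray,
        times: np.ndarray | None = None,
    ):
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 3 or coords.shape[1] != len(topology) or coords.shape[2] != 3:
            raise ValueError(
                f"coords must be (n_frames, {len(topology)}, 3), got {coords.shape}"
            )
        self.topology = topology
        self.coords = coords
        if times is None:
            times = np.arange(coords.shape[0], dtype=float)
        times = np.asarray(times, dtype=float)
        if times.shape != (coords.shape[0],):
            raise ValueError("times length must equal the number of frames")
        if coords.shape[0] > 1 and np.any(np.diff(times) <= 0):
            raise ValueError("frame times must be strictly increasing")
        self.times = times

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def frame(self, i: int) -> Structure:
        return self.topology.with_coords(self.coords[i])

    def write_text(self, destination: str | Path) -> None:
        destination = Path(destination)
        n_frames, n_atoms, _ = self.coords.shape
        with destination.open("w") as fh:
            fh.write(f"# confdyn-trajectory frames={n_frames} atoms={n_atoms}\n")
            for f in range(n_frames):
                fh.write(f"# frame {f} time {self.times[f]:.10g}\n")
                np.savetxt(fh, self.coords[f], fmt="%.6f")

    @classmethod
    def read_text(cls, source: str | Path, topology: Structure) -> "Trajectory":
        source = Path(source)
        times: list[float] = []
        rows: list[list[float]] = []
        with source.open() as fh:
            header = fh.readline()
            if not header.startswith("# confdyn-trajectory"):
                raise ValueError(f"{source}: not a confdyn trajectory file")
            for line in fh:
                if line.startswith("# frame"):
                    times.append(float(line.split("time")[1]))
                elif line.strip():
                    rows.append([float(x) for x in line.split()])
        n_atoms = len(topology)
        coords = np.asarray(rows).reshape(len(times), n_atoms, 3)
        return cls(topology, coords, np.asarray(times))
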