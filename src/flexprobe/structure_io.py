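"""Structures, trajectories and atom selections.

The on-disk trajectory dialect is multi-model PDB: one ``MODEL``/``ENDMDL``
block per frame, constant atom count and ordering across frames.  All
coordinates are in Å, times in ns, frame indices 0-based, residue numbers as
authored in the source PDB (1-based).

Everything downstream (occlusion scoring, state classification, hydrogen-bond
chronology) consumes the :class:`Trajectory` / :class:`Frame` / :class:`Atom`
types defined here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Frame",
    "Trajectory",
    "AtomSelection",
    "PDBFormatError",
    "read_pdb_models",
    "write_pdb_models",
    "select",
    "selection_indices",
    "vdw_radius",
    "distance",
    "parse_atom_path",
    "find_atom_index",
    "BONDI_RADII",
    "BACKBONE_ATOMS",
]


class PDBFormatError(ValueError):
    """Raised for malformed or internally inconsistent PDB input."""


# ---------------------------------------------------------------------------
# Element properties
# ---------------------------------------------------------------------------

#: van der Waals radii (Å), Bondi (1964).  Overridable per call via the
#: ``table`` argument of :func:`vdw_radius`.
BONDI_RADII: dict[str, float] = {
    "H": 1.20,
    "HE": 1.40,
    "LI": 1.82,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "NE": 1.54,
    "NA": 2.27,
    "MG": 1.73,
    "SI": 2.10,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "AR": 1.88,
    "K": 2.75,
    "NI": 1.63,
    "CU": 1.40,
    "ZN": 1.39,
    "GA": 1.87,
    "AS": 1.85,
    "SE": 1.90,
    "BR": 1.85,
    "KR": 2.02,
    "I": 1.98,
    "XE": 2.16,
}

#: Backbone atom-name class; side-chain-heavy = heavy atoms not in this set.
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O"})

# Two-character element symbols matched first when inferring the element from
# the atom name of a legacy PDB record with a blank element column.
_TWO_CHAR_ELEMENTS = ("CL", "BR", "NA", "MG", "ZN", "FE", "SE")


def vdw_radius(element: str, table: dict[str, float] | None = None) -> float:
    """van der Waals radius of ``element`` in Å (Bondi set by default)."""
    tab = BONDI_RADII if table is None else table
    key = element.strip().upper()
    try:
        return tab[key]
    except KeyError:
        supported = ", ".join(sorted(tab))
        raise KeyError(
            f"unknown element {element!r}; supported elements: {supported}"
        ) from None


def infer_element(atom_name: str) -> str:
    """Infer the element symbol from a PDB atom name.

    Two-character symbols common in proteins and buffers (CL, BR, NA, MG, ZN,
    FE, SE) are matched first; otherwise the first alphabetic character of the
    name is taken (so ``1HG1`` → H, ``NE1`` → N).
    """
    stripped = atom_name.strip().upper()
    if stripped[:2] in _TWO_CHAR_ELEMENTS:
        return stripped[:2]
    for ch in stripped:
        if ch.isalpha():
            return ch
    raise ValueError(f"cannot infer element from atom name {atom_name!r}")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Atom:
    """A single atom: identity plus a Cartesian position in Å."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    chain: str
    position: np.ndarray  # shape (3,), Å

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)
        if not self.element:
            raise ValueError(f"atom {self.name}: element must be non-empty")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() == "H"

    def identity(self) -> tuple[str, int, str, str]:
        return (self.chain, self.residue_number, self.residue_name, self.name)


@dataclass(frozen=True)
class Frame:
    """One trajectory frame: an ordered atom list at a point in time."""

    atoms: tuple[Atom, ...]
    frame_index: int = 0
    time_ns: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "atoms", tuple(self.atoms))

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def coordinates(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array, Å."""
        return np.array([a.position for a in self.atoms], dtype=float)

    def with_coordinates(self, coords: np.ndarray) -> "Frame":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise ValueError("coordinate array shape does not match atom count")
        atoms = tuple(replace(a, position=c) for a, c in zip(self.atoms, coords))
        return Frame(atoms, self.frame_index, self.time_ns)


@dataclass(frozen=True)
class Trajectory:
    """An ordered frame sequence with a fixed save interval.

    Invariants enforced at construction: at least one frame, identical atom
    count and atom identities (chain/residue/name, in order) in every frame.
    """

    frames: tuple[Frame, ...]
    frame_interval_ns: float
    replicate_id: str = "r1"
    system_label: str = ""

    def __post_init__(self) -> None:
        frames = tuple(self.frames)
        if not frames:
            raise ValueError("trajectory must contain at least one frame")
        if self.frame_interval_ns <= 0:
            raise ValueError("frame_interval_ns must be > 0")
        ident0 = [a.identity() for a in frames[0].atoms]
        for i, fr in enumerate(frames[1:], start=1):
            if [a.identity() for a in fr.atoms] != ident0:
                raise ValueError(
                    f"frame {i}: atom identities/order differ from frame 0"
                )
        object.__setattr__(self, "frames", frames)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_atoms(self) -> int:
        return self.frames[0].n_atoms

    def times_ns(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_ns

    def coordinates(self) -> np.ndarray:
        """(n_frames, n_atoms, 3) stacked coordinates, Å."""
        return np.stack([f.coordinates() for f in self.frames])

    def __iter__(self):
        return iter(self.frames)


@dataclass(frozen=True)
class AtomSelection:
    """A deterministic predicate over atoms.

    ``atom_class`` is one of ``"all-heavy"`` (default; every non-hydrogen
    atom), ``"backbone"`` (N, CA, C, O), ``"sidechain-heavy"`` (heavy atoms
    not in the backbone class), or ``"named"`` with ``atom_names`` listing the
    wanted names explicitly.  ``residue_numbers`` may be given as an iterable
    of author residue numbers; ``None`` matches everything for any field.
    """

    chain: str | None = None
    residue_numbers: tuple[int, ...] | None = None
    residue_name: str | None = None
    atom_class: str = "all-heavy"
    atom_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        valid = {"all-heavy", "backbone", "sidechain-heavy", "named", "all"}
        if self.atom_class not in valid:
            raise ValueError(
                f"atom_class {self.atom_class!r} not in {sorted(valid)}"
            )
        if self.atom_class == "named" and not self.atom_names:
            raise ValueError("atom_class 'named' requires atom_names")
        if self.residue_numbers is not None:
            object.__setattr__(
                self, "residue_numbers", tuple(self.residue_numbers)
            )
        if self.atom_names is not None:
            object.__setattr__(self, "atom_names", tuple(self.atom_names))

    def matches(self, atom: Atom) -> bool:
        if self.chain is not None and atom.chain != self.chain:
            return False
        if (
            self.residue_numbers is not None
            and atom.residue_number not in self.residue_numbers
        ):
            return False
        if self.residue_name is not None and atom.residue_name != self.residue_name:
            return False
        cls = self.atom_class
        if cls == "all":
            return True
        if cls == "all-heavy":
            return not atom.is_hydrogen
        if cls == "backbone":
            return atom.name in BACKBONE_ATOMS
        if cls == "sidechain-heavy":
            return not atom.is_hydrogen and atom.name not in BACKBONE_ATOMS
        # named
        return atom.name in self.atom_names  # type: ignore[operator]


def selection_indices(
    frame: Frame, selection: AtomSelection, allow_empty: bool = False
) -> np.ndarray:
    """Indices (into ``frame.atoms``) matched by ``selection``.

    Ordering is stable: sorted by (chain, residue_number, input order), which
    for a well-formed PDB equals the input order.
    """
    hits = [
        (a.chain, a.residue_number, i)
        for i, a in enumerate(frame.atoms)
        if selection.matches(a)
    ]
    hits.sort()
    if not hits and not allow_empty:
        raise ValueError(f"empty selection: {selection}")
    return np.array([i for _, _, i in hits], dtype=int)


def select(
    frame_or_traj: Frame | Trajectory,
    selection: AtomSelection,
    allow_empty: bool = False,
) -> list[Atom] | list[list[Atom]]:
    """Ordered atoms matched by ``selection`` (per-frame lists for a trajectory)."""
    if isinstance(frame_or_traj, Trajectory):
        idx = selection_indices(frame_or_traj.frames[0], selection, allow_empty)
        return [[f.atoms[i] for i in idx] for f in frame_or_traj.frames]
    idx = selection_indices(frame_or_traj, selection, allow_empty)
    return [frame_or_traj.atoms[i] for i in idx]


# ---------------------------------------------------------------------------
# PDB I/O (multi-model trajectory dialect)
# ---------------------------------------------------------------------------


def _parse_atom_line(line: str, lineno: int) -> Atom:
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        residue_name = line[17:20].strip()
        chain = line[21:22].strip() or " "
        residue_number = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError) as exc:
        raise PDBFormatError(
            f"line {lineno}: unparsable ATOM/HETATM record: {line.rstrip()!r}"
        ) from exc
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        element = infer_element(name)
    return Atom(
        serial=serial,
        name=name,
        element=element.upper(),
        residue_name=residue_name,
        residue_number=residue_number,
        chain=chain,
        position=np.array([x, y, z]),
    )


def read_pdb_models(
    path: str | Path,
    frame_interval_ns: float = 1.0,
    replicate_id: str = "r1",
    system_label: str = "",
) -> Trajectory:
    """Read a (multi-)model PDB file as a :class:`Trajectory`.

    Each ``MODEL``/``ENDMDL`` block becomes one frame; a bare coordinate block
    with no MODEL records becomes a single frame.  Atom order is preserved
    exactly as written.  The save interval is not stored in PDB files and must
    be supplied by the caller.
    """
    path = Path(path)
    models: list[list[Atom]] = []
    current: list[Atom] | None = None
    saw_model_record = False
    current_model_no = 0
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                saw_model_record = True
                current_model_no += 1
                current = []
            elif rec == "ENDMDL":
                if current is not None:
                    models.append(current)
                    current = None
            elif rec in ("ATOM  ", "HETATM"):
                if current is None:
                    if saw_model_record:
                        raise PDBFormatError(
                            f"line {lineno}: coordinates outside MODEL block"
                        )
                    current_model_no = 1
                    current = []
                current.append(_parse_atom_line(line, lineno))
    if current:
        models.append(current)
    if not models or not models[0]:
        raise PDBFormatError(f"{path}: no ATOM/HETATM records found")
    n0 = len(models[0])
    for m, atoms in enumerate(models[1:], start=2):
        if len(atoms) != n0:
            raise PDBFormatError(
                f"{path}: atom count mismatch in model {m} "
                f"({len(atoms)} atoms, expected {n0})"
            )
    frames = [
        Frame(tuple(atoms), frame_index=i, time_ns=i * frame_interval_ns)
        for i, atoms in enumerate(models)
    ]
    return Trajectory(
        tuple(frames),
        frame_interval_ns=frame_interval_ns,
        replicate_id=replicate_id,
        system_label=system_label or path.stem,
    )


def _format_atom_name(name: str) -> str:
    # PDB convention: names of <4 chars start in column 14 (blank in 13)
    # unless the element symbol itself is two characters.
    if len(name) >= 4:
        return name[:4]
    return f" {name:<3s}"


def write_pdb_models(traj: Trajectory, path: str | Path) -> None:
    """Write ``traj`` as a standard multi-model PDB (MODEL/ENDMDL per frame).

    Coordinates are serialized at PDB precision (%8.3f), so
    :func:`read_pdb_models` is an inverse up to 1e-3 Å.
    """
    path = Path(path)
    lines: list[str] = []
    for i, frame in enumerate(traj.frames, start=1):
        lines.append(f"MODEL     {i:4d}")
        for atom in frame.atoms:
            x, y, z = atom.position
            lines.append(
                f"ATOM  {atom.serial:5d} {_format_atom_name(atom.name)}"
                f"{atom.residue_name:>4s} {atom.chain:1s}{atom.residue_number:4d}"
                f"    {x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                f"          {atom.element:>2s}"
            )
        lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Atom addressing and geometry
# ---------------------------------------------------------------------------


def parse_atom_path(path: str) -> tuple[str, int, str]:
    """Parse a ``"chain:residue_number:atom_name"`` atom address."""
    parts = path.split(":")
    if len(parts) != 3:
        raise ValueError(
            f"atom path {path!r} must have the form 'chain:resnum:atom_name'"
        )
    chain, resnum, name = parts
    return chain, int(resnum), name


def find_atom_index(frame: Frame, chain: str, residue_number: int, name: str) -> int:
    """Index of the uniquely addressed atom; error if absent."""
    for i, a in enumerate(frame.atoms):
        if a.chain == chain and a.residue_number == residue_number and a.name == name:
            return i
    raise KeyError(f"atom {chain}:{residue_number}:{name} not found in frame")


def distance(atom_a: Atom, atom_b: Atom) -> float:
    """Euclidean distance between two atoms, Å."""
    return float(np.linalg.norm(atom_a.position - atom_b.position))
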