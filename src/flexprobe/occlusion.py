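"""Fractional pocket occlusion against static reference atoms.

A binding pocket is scored as occluded by comparing each frame of a
trajectory against a static set of reference atom positions — e.g. the
side-chain heavy atoms of a ligand residue (Trp110, Tyr123/112) taken from a
bound cocrystal and mapped into the receptor frame.  A reference atom is
*overlapped* in a frame when any probe atom lies strictly inside the clash
radius, the sum of the two van der Waals radii.  The fractional occlusion of
a reference atom is the fraction of frames in which it is overlapped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import (
    Atom,
    AtomSelection,
    Frame,
    Trajectory,
    selection_indices,
    vdw_radius,
)

__all__ = [
    "ReferenceAtom",
    "ReferenceAtomSet",
    "OcclusionProfile",
    "clash_radius",
    "frame_overlaps",
    "fractional_occlusion",
    "occluded_count_series",
    "reference_set_from_residue",
]


@dataclass(frozen=True)
class ReferenceAtom:
    """A static position to test for occlusion, with its vdW radius (Å)."""

    label: str
    position: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,):
            raise ValueError("position must be a 3-vector")
        object.__setattr__(self, "position", pos)
        if self.radius < 0:
            raise ValueError("radius must be >= 0")


@dataclass(frozen=True)
class ReferenceAtomSet:
    """An ordered, uniquely labelled collection of reference atoms."""

    atoms: tuple[ReferenceAtom, ...]
    source: str = ""

    def __post_init__(self) -> None:
        atoms = tuple(self.atoms)
        labels = [a.label for a in atoms]
        if len(set(labels)) != len(labels):
            raise ValueError("reference atom labels must be unique")
        object.__setattr__(self, "atoms", atoms)

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def labels(self) -> list[str]:
        return [a.label for a in self.atoms]

    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    def radii(self) -> np.ndarray:
        return np.array([a.radius for a in self.atoms], dtype=float)


@dataclass(frozen=True)
class OcclusionProfile:
    """Per-reference-atom occlusion fractions over ``n_frames`` frames."""

    fractions: dict[str, float]
    n_frames: int

    def __post_init__(self) -> None:
        for label, f in self.fractions.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"fraction for {label!r} outside [0, 1]: {f}")


def clash_radius(
    ref_atom: ReferenceAtom,
    sim_atom: Atom,
    radius_table: dict[str, float] | None = None,
) -> float:
    """Clash radius: sum of reference and probe vdW radii, Å."""
    return ref_atom.radius + vdw_radius(sim_atom.element, radius_table)


def _frame_overlap_mask(
    probe_coords: np.ndarray,
    probe_radii: np.ndarray,
    ref_coords: np.ndarray,
    ref_radii: np.ndarray,
) -> np.ndarray:
    """Boolean mask over reference atoms: overlapped by any probe.

    kd-tree candidate search at the largest possible clash radius, then an
    exact per-pair strict-inequality check, so results are identical to the
    naive double loop.
    """
    tree = cKDTree(probe_coords)
    max_probe_r = float(probe_radii.max())
    mask = np.zeros(len(ref_coords), dtype=bool)
    for j, (rpos, rrad) in enumerate(zip(ref_coords, ref_radii)):
        candidates = tree.query_ball_point(rpos, r=rrad + max_probe_r)
        if not candidates:
            continue
        cand = np.asarray(candidates, dtype=int)
        d = np.linalg.norm(probe_coords[cand] - rpos, axis=1)
        mask[j] = bool(np.any(d < rrad + probe_radii[cand]))
    return mask


def frame_overlaps(
    frame: Frame,
    ref_set: ReferenceAtomSet,
    probe_selection: AtomSelection | None = None,
    radius_table: dict[str, float] | None = None,
) -> set[str]:
    """Labels of reference atoms overlapped in ``frame``.

    A reference atom is overlapped iff any probe atom lies at a distance
    strictly less than the clash radius (boundary contact is not overlap).
    Probes default to all heavy atoms of the frame.
    """
    if probe_selection is None:
        probe_selection = AtomSelection(atom_class="all-heavy")
    idx = selection_indices(frame, probe_selection)
    probes = [frame.atoms[i] for i in idx]
    probe_coords = np.array([a.position for a in probes])
    probe_radii = np.array([vdw_radius(a.element, radius_table) for a in probes])
    mask = _frame_overlap_mask(
        probe_coords, probe_radii, ref_set.positions(), ref_set.radii()
    )
    return {label for label, hit in zip(ref_set.labels, mask) if hit}


def _trajectory_overlap_matrix(
    traj: Trajectory,
    ref_set: ReferenceAtomSet,
    probe_selection: AtomSelection | None,
    radius_table: dict[str, float] | None,
) -> np.ndarray:
    if len(ref_set) == 0:
        raise ValueError("reference atom set is empty")
    if probe_selection is None:
        probe_selection = AtomSelection(atom_class="all-heavy")
    idx = selection_indices(traj.frames[0], probe_selection)
    elements = [traj.frames[0].atoms[i].element for i in idx]
    probe_radii = np.array([vdw_radius(e, radius_table) for e in elements])
    ref_coords = ref_set.positions()
    ref_radii = ref_set.radii()
    out = np.zeros((traj.n_frames, len(ref_set)), dtype=bool)
    for f, frame in enumerate(traj.frames):
        probe_coords = np.array([frame.atoms[i].position for i in idx])
        out[f] = _frame_overlap_mask(probe_coords, probe_radii, ref_coords, ref_radii)
    return out


def fractional_occlusion(
    traj: Trajectory,
    ref_set: ReferenceAtomSet,
    probe_selection: AtomSelection | None = None,
    radius_table: dict[str, float] | None = None,
) -> OcclusionProfile:
    """Per-reference-atom occlusion fractions over the whole trajectory."""
    overlaps = _trajectory_overlap_matrix(traj, ref_set, probe_selection, radius_table)
    fractions = overlaps.mean(axis=0)
    return OcclusionProfile(
        fractions=dict(zip(ref_set.labels, map(float, fractions))),
        n_frames=traj.n_frames,
    )


def occluded_count_series(
    traj: Trajectory,
    ref_set: ReferenceAtomSet,
    probe_selection: AtomSelection | None = None,
    radius_table: dict[str, float] | None = None,
) -> np.ndarray:
    """Per-frame count of overlapped reference atoms (0 … ``len(ref_set)``)."""
    overlaps = _trajectory_overlap_matrix(traj, ref_set, probe_selection, radius_table)
    return overlaps.sum(axis=1).astype(int)


def reference_set_from_residue(
    frame: Frame,
    chain: str,
    residue_number: int,
    atom_class: str = "sidechain-heavy",
    radius_table: dict[str, float] | None = None,
    source: str = "",
) -> ReferenceAtomSet:
    """Build a reference set from one residue of a (superposed) structure.

    Typical use: take the bound-like ligand residue (e.g. Trp110) from a
    cocrystal frame after superposing the cocrystal receptor onto the
    trajectory's receptor core, so the reference positions live in the
    trajectory's coordinate frame.
    """
    sel = AtomSelection(
        chain=chain, residue_numbers=(residue_number,), atom_class=atom_class
    )
    idx = selection_indices(frame, sel)
    atoms = [frame.atoms[i] for i in idx]
    refs = [
        ReferenceAtom(
            label=f"{a.residue_name}{a.residue_number}:{a.name}",
            position=a.position,
            radius=vdw_radius(a.element, radius_table),
        )
        for a in atoms
    ]
    return ReferenceAtomSet(tuple(refs), source=source or f"{chain}:{residue_number}")
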