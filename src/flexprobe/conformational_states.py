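"""Open/closed classification of interface side chains.

Two binary order parameters describe a flexible receptor interface, modelled
on the PD-1 pocket residues: an RMSD-based label (Asn66-style, side-chain
heavy-atom RMSD to open/closed reference conformations after core
superposition) and a χ1-rotamer label (Ile126-style, nearest reference χ1 on
the circle).  Combining both labels assigns each frame to an interface
macrostate: non-bound-like (NBL), PD-L1-like bound (BL_PDL1, Asn open / Ile
closed), or PD-L2-like bound (BL_PDL2, both open).

Tie-breaks in both classifiers resolve to ``closed``, the dominant apo state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure_io import (
    AtomSelection,
    Frame,
    Trajectory,
    selection_indices,
)
from .timeseries import ScalarSeries

__all__ = [
    "RmsdReference",
    "DihedralReference",
    "StateLabelSeries",
    "MacrostateSeries",
    "superpose",
    "apply_transform",
    "rmsd",
    "rmsd_series",
    "dihedral",
    "chi1",
    "circular_distance_deg",
    "classify_by_rmsd",
    "classify_by_chi1",
    "classify_trajectory",
    "macrostate_series",
    "rotamer_histogram2d",
    "rmsd_reference_from_frame",
    "dihedral_reference_from_frame",
    "CHI1_FOURTH_ATOM",
    "CORE_SUPERPOSE_RESIDUES",
]

OPEN, CLOSED = "open", "closed"

#: Default receptor-core superposition residues: the stable beta-sheet
#: residues restrained in the source simulations (backbone atoms).
CORE_SUPERPOSE_RESIDUES: tuple[int, ...] = tuple(
    n
    for lo, hi in ((50, 55), (80, 81), (96, 98), (106, 109), (120, 122))
    for n in range(lo, hi + 1)
)

#: Fourth atom of the χ1 dihedral (N–CA–CB–X) per residue type; residues not
#: listed use CG.  ALA/GLY have no χ1.
CHI1_FOURTH_ATOM: dict[str, str] = {
    "ILE": "CG1",
    "VAL": "CG1",
    "THR": "OG1",
    "SER": "OG",
    "CYS": "SG",
}


# ---------------------------------------------------------------------------
# Rigid-body superposition (Kabsch)
# ---------------------------------------------------------------------------


def superpose(
    mobile_coords: np.ndarray, target_coords: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid fit of ``mobile`` onto ``target`` (Kabsch).

    Returns ``(rotation, translation, rmsd)`` with the proper rotation
    (det = +1) and translation such that ``R @ x + t`` maps mobile points
    onto the target.  Requires ≥3 non-collinear paired points.
    """
    mobile = np.asarray(mobile_coords, dtype=float)
    target = np.asarray(target_coords, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("coordinate sets must be matching (n, 3) arrays")
    if len(mobile) < 3:
        raise ValueError("superposition requires at least 3 points")
    mob_mean = mobile.mean(axis=0)
    tar_mean = target.mean(axis=0)
    mob_c = mobile - mob_mean
    tar_c = target - tar_mean
    # degenerate (collinear/coincident) point sets leave the rotation
    # about the degenerate axis undetermined
    if np.linalg.matrix_rank(mob_c, tol=1e-8) < 2:
        raise ValueError("degenerate geometry: points are collinear or coincident")
    h = mob_c.T @ tar_c
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = tar_mean - rot @ mob_mean
    fitted = mob_c @ rot.T + tar_mean
    fit_rmsd = float(np.sqrt(np.mean(np.sum((fitted - target) ** 2, axis=1))))
    return rot, trans, fit_rmsd


def apply_transform(coords: np.ndarray, rotation: np.ndarray, translation: np.ndarray) -> np.ndarray:
    return np.asarray(coords, dtype=float) @ np.asarray(rotation).T + translation


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain (no refit) root-mean-square deviation of paired coordinates, Å."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("coordinate sets must have identical shape")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def _matched_indices(
    frame: Frame, reference: Frame, selection: AtomSelection
) -> tuple[np.ndarray, np.ndarray]:
    """Selection indices in frame and reference, verified to pair up."""
    fi = selection_indices(frame, selection)
    ri = selection_indices(reference, selection)
    f_ids = [frame.atoms[i].identity() for i in fi]
    r_ids = [reference.atoms[i].identity() for i in ri]
    if f_ids != r_ids:
        raise ValueError(
            "selection resolves to different atoms in trajectory and reference "
            f"({len(f_ids)} vs {len(r_ids)} atoms)"
        )
    return fi, ri


def rmsd_series(
    traj: Trajectory,
    reference_frame: Frame,
    measure_selection: AtomSelection,
    superpose_selection: AtomSelection,
) -> ScalarSeries:
    """Per-frame RMSD (Å) to a reference after core superposition.

    Each frame is rigidly fitted to the reference on ``superpose_selection``
    (e.g. the stable receptor core) and the RMSD is then measured over
    ``measure_selection`` without refitting — so genuine displacement of the
    measured atoms relative to the core is retained.
    """
    sup_f, sup_r = _matched_indices(traj.frames[0], reference_frame, superpose_selection)
    mea_f, mea_r = _matched_indices(traj.frames[0], reference_frame, measure_selection)
    ref_sup = np.array([reference_frame.atoms[i].position for i in sup_r])
    ref_mea = np.array([reference_frame.atoms[i].position for i in mea_r])
    out = np.empty(traj.n_frames)
    for k, frame in enumerate(traj.frames):
        coords = frame.coordinates()
        rot, trans, _ = superpose(coords[sup_f], ref_sup)
        out[k] = rmsd(apply_transform(coords[mea_f], rot, trans), ref_mea)
    return ScalarSeries(out, unit="A", frame_interval_ns=traj.frame_interval_ns)


# ---------------------------------------------------------------------------
# Dihedrals
# ---------------------------------------------------------------------------


def dihedral(p0, p1, p2, p3) -> np.ndarray | float:
    """Signed dihedral angle p0–p1–p2–p3 in degrees, in (−180, 180].

    Standard atan2 convention: cis (p0 and p3 eclipsed) is 0°, trans is 180°.
    Accepts stacked (..., 3) arrays.
    """
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = b2 / np.linalg.norm(b2, axis=-1, keepdims=True)
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(np.cross(n1, n2) * b2n, axis=-1)
    ang = np.degrees(np.arctan2(y, x))
    ang = np.where(ang <= -180.0, ang + 360.0, ang)
    return float(ang) if ang.ndim == 0 else ang


def _chi1_atom_indices(frame: Frame, chain: str, residue_number: int) -> list[int]:
    atoms = {
        a.name: i
        for i, a in enumerate(frame.atoms)
        if a.chain == chain and a.residue_number == residue_number
    }
    if not atoms:
        raise KeyError(f"residue {chain}:{residue_number} not found")
    resname = next(
        a.residue_name
        for a in frame.atoms
        if a.chain == chain and a.residue_number == residue_number
    )
    if resname in ("ALA", "GLY"):
        raise ValueError(f"residue type {resname} has no χ1 dihedral")
    fourth = CHI1_FOURTH_ATOM.get(resname, "CG")
    indices = []
    for name in ("N", "CA", "CB", fourth):
        if name not in atoms:
            raise KeyError(
                f"χ1 of {chain}:{residue_number} ({resname}): missing atom {name}"
            )
        indices.append(atoms[name])
    return indices


def chi1(frame: Frame, chain: str, residue_number: int) -> float:
    """χ1 side-chain dihedral (N–CA–CB–X) of a residue, degrees."""
    i0, i1, i2, i3 = _chi1_atom_indices(frame, chain, residue_number)
    a = frame.atoms
    return dihedral(a[i0].position, a[i1].position, a[i2].position, a[i3].position)


def circular_distance_deg(a: float, b: float) -> float:
    """Shortest angular distance between two angles, degrees in [0, 180]."""
    d = abs((a - b) % 360.0)
    return min(d, 360.0 - d)


# ---------------------------------------------------------------------------
# References and classifiers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RmsdReference:
    """Side-chain heavy-atom coordinates of one reference conformation.

    ``core_coords`` (optional) are the coordinates of a stable-core atom
    selection in the reference structure's own frame; when present, frames
    are superposed onto them before the side-chain RMSD is measured.
    """

    chain: str
    residue_number: int
    residue_name: str
    atom_names: tuple[str, ...]
    coords: np.ndarray  # (n_atoms, 3)
    state_name: str
    provenance: str = ""
    core_selection: AtomSelection | None = None
    core_coords: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.state_name not in (OPEN, CLOSED):
            raise ValueError("state_name must be 'open' or 'closed'")
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (len(self.atom_names), 3):
            raise ValueError("coords shape must match atom_names")
        if len(self.atom_names) < 1:
            raise ValueError("reference needs at least one atom")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "atom_names", tuple(self.atom_names))
        if self.core_coords is not None:
            object.__setattr__(
                self, "core_coords", np.asarray(self.core_coords, dtype=float)
            )


@dataclass(frozen=True)
class DihedralReference:
    """A reference χ1 rotamer angle for one residue state."""

    chain: str
    residue_number: int
    chi1_deg: float
    state_name: str
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.state_name not in (OPEN, CLOSED):
            raise ValueError("state_name must be 'open' or 'closed'")
        if not -180.0 < self.chi1_deg <= 180.0:
            raise ValueError("chi1_deg must lie in (−180, 180]")


@dataclass(frozen=True)
class StateLabelSeries:
    """Per-frame open/closed labels for one residue."""

    labels: tuple[str, ...]
    chain: str
    residue_number: int
    classifier_kind: str  # "rmsd" | "chi1"

    def __post_init__(self) -> None:
        bad = set(self.labels) - {OPEN, CLOSED}
        if bad:
            raise ValueError(f"invalid labels: {bad}")
        object.__setattr__(self, "labels", tuple(self.labels))

    def __len__(self) -> int:
        return len(self.labels)

    def fraction(self, state: str) -> float:
        return self.labels.count(state) / len(self.labels)


MACROSTATE_MAP: dict[tuple[str, str], str] = {
    (CLOSED, OPEN): "NBL",
    (OPEN, CLOSED): "BL_PDL1",
    (OPEN, OPEN): "BL_PDL2",
    (CLOSED, CLOSED): "unassigned",
}


@dataclass(frozen=True)
class MacrostateSeries:
    """Per-frame interface macrostate labels."""

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        bad = set(self.labels) - set(MACROSTATE_MAP.values())
        if bad:
            raise ValueError(f"invalid macrostate labels: {bad}")
        object.__setattr__(self, "labels", tuple(self.labels))

    def __len__(self) -> int:
        return len(self.labels)


def _residue_sidechain_coords(
    frame: Frame, chain: str, residue_number: int, atom_names: tuple[str, ...]
) -> np.ndarray:
    by_name = {
        a.name: a.position
        for a in frame.atoms
        if a.chain == chain and a.residue_number == residue_number
    }
    missing = [n for n in atom_names if n not in by_name]
    if missing:
        raise KeyError(
            f"residue {chain}:{residue_number}: missing atoms {missing}"
        )
    return np.array([by_name[n] for n in atom_names])


def _check_ref_pair(open_ref: RmsdReference, closed_ref: RmsdReference) -> None:
    if open_ref.atom_names != closed_ref.atom_names:
        raise ValueError(
            "open and closed references must share an identical atom-name set: "
            f"{open_ref.atom_names} vs {closed_ref.atom_names}"
        )
    if open_ref.state_name != OPEN or closed_ref.state_name != CLOSED:
        raise ValueError("references passed in the wrong open/closed slots")


def classify_by_rmsd(
    frame: Frame,
    open_ref: RmsdReference,
    closed_ref: RmsdReference,
    superpose_selection: AtomSelection | None = None,
) -> str:
    """Label a frame by the reference with the smaller side-chain RMSD.

    When ``superpose_selection`` is given (and the open reference carries
    ``core_coords``), the frame is first rigidly fitted to the reference core
    so both side chains are compared in a common frame.  Exact ties resolve
    to ``closed``.
    """
    _check_ref_pair(open_ref, closed_ref)
    coords = _residue_sidechain_coords(
        frame, open_ref.chain, open_ref.residue_number, open_ref.atom_names
    )
    sup = superpose_selection or open_ref.core_selection
    if sup is not None and open_ref.core_coords is not None:
        idx = selection_indices(frame, sup)
        frame_core = np.array([frame.atoms[i].position for i in idx])
        rot, trans, _ = superpose(frame_core, open_ref.core_coords)
        coords = apply_transform(coords, rot, trans)
    d_open = rmsd(coords, open_ref.coords)
    d_closed = rmsd(coords, closed_ref.coords)
    return OPEN if d_open < d_closed else CLOSED


def classify_by_chi1(
    frame: Frame,
    open_ref: DihedralReference,
    closed_ref: DihedralReference,
) -> str:
    """Label a frame by the reference χ1 at the smaller circular distance.

    Invariant under adding ±360° to any angle; exact ties resolve to
    ``closed``.
    """
    angle = chi1(frame, open_ref.chain, open_ref.residue_number)
    d_open = circular_distance_deg(angle, open_ref.chi1_deg)
    d_closed = circular_distance_deg(angle, closed_ref.chi1_deg)
    return OPEN if d_open < d_closed else CLOSED


def classify_trajectory(traj: Trajectory, classifier) -> StateLabelSeries:
    """Apply an open/closed classifier to every frame of a trajectory.

    ``classifier`` is either a pair of :class:`DihedralReference` (χ1 mode)
    or a pair of :class:`RmsdReference` (RMSD mode), given as
    ``(open_ref, closed_ref)``.
    """
    open_ref, closed_ref = classifier
    if isinstance(open_ref, DihedralReference):
        kind = "chi1"
        i0, i1, i2, i3 = _chi1_atom_indices(
            traj.frames[0], open_ref.chain, open_ref.residue_number
        )
        coords = traj.coordinates()
        angles = dihedral(
            coords[:, i0], coords[:, i1], coords[:, i2], coords[:, i3]
        )
        d_open = np.minimum(
            np.abs((angles - open_ref.chi1_deg) % 360.0),
            360.0 - np.abs((angles - open_ref.chi1_deg) % 360.0),
        )
        d_closed = np.minimum(
            np.abs((angles - closed_ref.chi1_deg) % 360.0),
            360.0 - np.abs((angles - closed_ref.chi1_deg) % 360.0),
        )
        labels = tuple(OPEN if o < c else CLOSED for o, c in zip(d_open, d_closed))
    elif isinstance(open_ref, RmsdReference):
        kind = "rmsd"
        labels = tuple(
            classify_by_rmsd(frame, open_ref, closed_ref) for frame in traj.frames
        )
    else:
        raise TypeError(f"unsupported classifier reference type: {type(open_ref)}")
    return StateLabelSeries(
        labels=labels,
        chain=open_ref.chain,
        residue_number=open_ref.residue_number,
        classifier_kind=kind,
    )


def macrostate_series(
    asn66_series: StateLabelSeries, ile126_series: StateLabelSeries
) -> MacrostateSeries:
    """Combine the two binary order parameters into interface macrostates.

    (Asn closed, Ile open) → NBL; (open, closed) → BL_PDL1;
    (open, open) → BL_PDL2; (closed, closed) → unassigned.
    """
    if len(asn66_series) != len(ile126_series):
        raise ValueError("state series lengths differ")
    labels = tuple(
        MACROSTATE_MAP[(a, b)]
        for a, b in zip(asn66_series.labels, ile126_series.labels)
    )
    return MacrostateSeries(labels)


def rotamer_histogram2d(
    series_a: np.ndarray, series_b: np.ndarray, bin_width: float
) -> tuple[np.ndarray, np.ndarray]:
    """2-D χ1 histogram over periodic bins covering (−180, 180]².

    Returns ``(counts, edges)`` where counts has one row/column per bin of
    ``series_a`` / ``series_b`` and ``counts.sum() == n_frames``.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("series lengths differ")
    n_bins = int(np.ceil(360.0 / bin_width))
    edges = -180.0 + bin_width * np.arange(n_bins + 1)

    def _bin(x: np.ndarray) -> np.ndarray:
        wrapped = (x - 180.0) % 360.0 - 180.0  # (-180, 180)
        wrapped = np.where(np.isclose(x % 360.0, 180.0), 180.0, wrapped)
        idx = np.floor((wrapped + 180.0) / bin_width).astype(int)
        return np.clip(idx, 0, n_bins - 1)

    counts = np.zeros((n_bins, n_bins), dtype=int)
    np.add.at(counts, (_bin(a), _bin(b)), 1)
    return counts, edges


def rmsd_reference_from_frame(
    frame: Frame,
    chain: str,
    residue_number: int,
    state_name: str,
    provenance: str = "",
    core_selection: AtomSelection | None = None,
) -> RmsdReference:
    """Extract a side-chain RMSD reference from a structure frame."""
    sel = AtomSelection(
        chain=chain, residue_numbers=(residue_number,), atom_class="sidechain-heavy"
    )
    idx = selection_indices(frame, sel)
    atoms = [frame.atoms[i] for i in idx]
    core_coords = None
    if core_selection is not None:
        core_idx = selection_indices(frame, core_selection)
        core_coords = np.array([frame.atoms[i].position for i in core_idx])
    return RmsdReference(
        chain=chain,
        residue_number=residue_number,
        residue_name=atoms[0].residue_name,
        atom_names=tuple(a.name for a in atoms),
        coords=np.array([a.position for a in atoms]),
        state_name=state_name,
        provenance=provenance,
        core_selection=core_selection,
        core_coords=core_coords,
    )


def dihedral_reference_from_frame(
    frame: Frame,
    chain: str,
    residue_number: int,
    state_name: str,
    provenance: str = "",
) -> DihedralReference:
    """Extract a χ1 reference angle from a structure frame."""
    return DihedralReference(
        chain=chain,
        residue_number=residue_number,
        chi1_deg=chi1(frame, chain, residue_number),
        state_name=state_name,
        provenance=provenance,
    )
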