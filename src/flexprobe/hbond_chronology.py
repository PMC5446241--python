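"""Hydrogen-bond presence and time-to-formation chronology.

A hydrogen bond is judged present in a frame by a geometric criterion:
donor–acceptor heavy-atom distance ≤ 3.5 Å and, when an explicit hydrogen is
given, donor–H–acceptor angle ≥ 135°.  A bond counts as *formed* at the
first frame at which it is present inside the first window (1 ns by
default) whose occupancy reaches 80% — transient single-frame contacts do
not count.  Chronologies report, per bond, the lag Δt from a reference
event (here the formation of a key receptor–ligand hydrogen bond) to the
bond's own stable formation, averaged over replicate trajectories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .structure_io import Frame, Trajectory, find_atom_index, parse_atom_path

__all__ = [
    "HBondSpec",
    "BondPresenceSeries",
    "FormationRecord",
    "Persistence",
    "hbond_present",
    "bond_series",
    "formation_time",
    "chronology_table",
    "aggregate_chronologies",
    "DEFAULT_DISTANCE_CUTOFF",
    "DEFAULT_ANGLE_CUTOFF",
]

DEFAULT_DISTANCE_CUTOFF = 3.5  # Å, donor–acceptor heavy atoms
DEFAULT_ANGLE_CUTOFF = 135.0  # degrees, donor–H–acceptor

_WATER_RESIDUES = frozenset({"HOH", "WAT", "TIP3", "SOL"})


@dataclass(frozen=True)
class HBondSpec:
    """Geometric specification of one hydrogen bond.

    Atom identities are ``"chain:resnum:atom_name"`` paths.  ``hydrogen`` is
    optional; without it the criterion is distance-only.  ``water_mediated``
    (experimental) accepts a bridge through any single water oxygen: both
    legs must satisfy the distance cutoff.
    """

    donor: str
    acceptor: str
    hydrogen: str | None = None
    distance_cutoff: float = DEFAULT_DISTANCE_CUTOFF
    angle_cutoff: float = DEFAULT_ANGLE_CUTOFF
    water_mediated: bool = False
    label: str = ""

    def __post_init__(self) -> None:
        if self.distance_cutoff <= 0 or self.angle_cutoff <= 0:
            raise ValueError("cutoffs must be positive")
        if self.angle_cutoff > 180.0:
            raise ValueError("angle cutoff cannot exceed 180°")
        if not self.label:
            object.__setattr__(self, "label", f"{self.donor}—{self.acceptor}")


@dataclass(frozen=True)
class BondPresenceSeries:
    """Per-frame presence booleans for one bond spec."""

    present: np.ndarray
    spec: HBondSpec
    frame_interval_ns: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "present", np.asarray(self.present, dtype=bool))

    def __len__(self) -> int:
        return len(self.present)

    def occupancy(self) -> float:
        return float(self.present.mean())


@dataclass(frozen=True)
class Persistence:
    """Stable-formation rule: first window of ``window_ns`` with occupancy
    ≥ ``min_occupancy``."""

    window_ns: float = 1.0
    min_occupancy: float = 0.8

    def __post_init__(self) -> None:
        if self.window_ns <= 0:
            raise ValueError("window_ns must be positive")
        if not 0.0 < self.min_occupancy <= 1.0:
            raise ValueError("min_occupancy must lie in (0, 1]")


@dataclass(frozen=True)
class FormationRecord:
    """Time from a reference event to stable formation of one bond (ns)."""

    spec: HBondSpec
    formation_time_ns: float | None
    reference_event_time_ns: float
    delta_t_ns: float | None

    @property
    def formed(self) -> bool:
        return self.formation_time_ns is not None


def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    v1 = a - b
    v2 = c - b
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def _water_bridged(frame: Frame, dpos: np.ndarray, apos: np.ndarray, cutoff: float) -> bool:
    for atom in frame.atoms:
        if atom.residue_name in _WATER_RESIDUES and atom.element == "O":
            w = atom.position
            if (
                np.linalg.norm(dpos - w) <= cutoff
                and np.linalg.norm(apos - w) <= cutoff
            ):
                return True
    return False


def hbond_present(frame: Frame, spec: HBondSpec) -> bool:
    """Whether the bond's geometric criterion is satisfied in ``frame``."""
    dpos = frame.atoms[find_atom_index(frame, *parse_atom_path(spec.donor))].position
    apos = frame.atoms[find_atom_index(frame, *parse_atom_path(spec.acceptor))].position
    if spec.water_mediated:
        return _water_bridged(frame, dpos, apos, spec.distance_cutoff)
    if float(np.linalg.norm(dpos - apos)) > spec.distance_cutoff:
        return False
    if spec.hydrogen is not None:
        hpos = frame.atoms[
            find_atom_index(frame, *parse_atom_path(spec.hydrogen))
        ].position
        if _angle_deg(dpos, hpos, apos) < spec.angle_cutoff:
            return False
    return True


def bond_series(traj: Trajectory, spec: HBondSpec) -> BondPresenceSeries:
    """Evaluate the bond criterion in every frame."""
    present = np.array([hbond_present(f, spec) for f in traj.frames])
    return BondPresenceSeries(present, spec, traj.frame_interval_ns)


def formation_time(
    series: BondPresenceSeries | np.ndarray,
    frame_interval_ns: float | None = None,
    persistence: Persistence = Persistence(),
) -> float | None:
    """Time (ns) of stable bond formation, or ``None`` if never formed.

    The bond is formed at the first *present* frame inside the first window
    of ``persistence.window_ns`` whose occupancy reaches
    ``persistence.min_occupancy``; a bond present throughout forms at 0 ns.
    """
    if isinstance(series, BondPresenceSeries):
        present = series.present
        interval = series.frame_interval_ns
    else:
        present = np.asarray(series, dtype=bool)
        if frame_interval_ns is None:
            raise ValueError("frame_interval_ns required for a bare boolean series")
        interval = frame_interval_ns
    n = len(present)
    window = max(1, int(round(persistence.window_ns / interval)))
    if window > n:
        raise ValueError(
            f"persistence window ({window} frames) exceeds trajectory length ({n})"
        )
    needed = persistence.min_occupancy * window
    running = np.convolve(present.astype(int), np.ones(window, dtype=int), "valid")
    # first qualifying window, then the first present frame inside it
    qualifying = np.nonzero(running >= needed - 1e-12)[0]
    if len(qualifying) == 0:
        return None
    start = int(qualifying[0])
    first_present = start + int(np.argmax(present[start : start + window]))
    return first_present * interval


def chronology_table(
    traj: Trajectory,
    bonds: list[HBondSpec],
    reference_bond: HBondSpec,
    persistence: Persistence = Persistence(),
) -> list[FormationRecord]:
    """Per-bond formation lag Δt after the reference bond, one trajectory.

    The reference bond must form; bonds that never form yield records with
    ``delta_t_ns=None`` and are excluded from replicate means.  Records are
    sorted by ascending Δt (never-formed last).
    """
    t_ref = formation_time(bond_series(traj, reference_bond), persistence=persistence)
    if t_ref is None:
        raise ValueError(
            f"reference event absent: bond {reference_bond.label!r} never forms"
        )
    records = []
    for spec in bonds:
        t = formation_time(bond_series(traj, spec), persistence=persistence)
        records.append(
            FormationRecord(
                spec=spec,
                formation_time_ns=t,
                reference_event_time_ns=t_ref,
                delta_t_ns=None if t is None else t - t_ref,
            )
        )
    records.sort(key=lambda r: (r.delta_t_ns is None, r.delta_t_ns))
    return records


def aggregate_chronologies(
    replicate_records: list[list[FormationRecord]],
) -> list[dict]:
    """Mean ± sample SD of Δt per bond across replicates.

    Replicates in which a bond never formed are excluded from that bond's
    mean; ``n_formed`` records how many contributed.  Rows are sorted by
    ascending mean Δt (never-formed bonds last).
    """
    by_label: dict[str, list[FormationRecord]] = {}
    order: list[str] = []
    for records in replicate_records:
        for rec in records:
            if rec.spec.label not in by_label:
                by_label[rec.spec.label] = []
                order.append(rec.spec.label)
            by_label[rec.spec.label].append(rec)
    rows = []
    for label in order:
        recs = by_label[label]
        dts = [r.delta_t_ns for r in recs if r.delta_t_ns is not None]
        rows.append(
            {
                "bond": label,
                "dt_mean_ns": float(np.mean(dts)) if dts else math.nan,
                "dt_sd_ns": float(np.std(dts, ddof=1)) if len(dts) > 1 else 0.0,
                "n_formed": len(dts),
                "n_replicates": len(recs),
            }
        )
    rows.sort(key=lambda r: (math.isnan(r["dt_mean_ns"]), r["dt_mean_ns"]))
    return rows
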