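"""Synthetic trajectories with known ground truth.

Three generators cover the statistical structure the analysis pipeline
assumes, so every stage is testable without running an MD engine:

* a residue whose side chain interconverts between two rotamer states
  (open/closed) as a two-state Markov chain with a prescribed equilibrium
  open probability and switching rate, plus isotropic Gaussian coordinate
  noise — the ground truth behind state classification and ΔG recovery;
* a probe atom that overlaps a static reference atom in an exact,
  pre-scheduled fraction of frames — the ground truth for occlusion;
* a donor/acceptor pair that approaches to hydrogen-bonding geometry at a
  prescribed frame — the ground truth for formation-time chronology.

Side-chain templates are ideal-geometry Asn/Ile fragments built from
internal coordinates; they are synthetic stand-ins for crystal/NMR reference
conformations, with the open and closed states placed in the χ1 wells at
−60° and 180°.  Every generator records its parameters, seed and hidden
states in a :class:`FixtureManifest` sufficient to recompute expected
outputs exactly.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .conformational_states import (
    CLOSED,
    OPEN,
    DihedralReference,
    RmsdReference,
)
from .hbond_chronology import HBondSpec
from .occlusion import ReferenceAtom, ReferenceAtomSet
from .structure_io import Atom, Frame, Trajectory, vdw_radius

__all__ = [
    "TwoStateModel",
    "FixtureManifest",
    "build_residue",
    "generate_two_state_trajectory",
    "generate_occlusion_fixture",
    "generate_hbond_fixture",
    "default_chi1_references",
    "default_rmsd_references",
]


# ---------------------------------------------------------------------------
# Ideal-geometry residue templates (internal-coordinate construction)
# ---------------------------------------------------------------------------


def _place_atom(a, b, c, bond: float, angle_deg: float, dihedral_deg: float):
    """Position atom D bonded to C with angle B–C–D and dihedral A–B–C–D."""
    ang = math.radians(angle_deg)
    dih = math.radians(dihedral_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array(
        [
            -bond * math.cos(ang),
            bond * math.sin(ang) * math.cos(dih),
            bond * math.sin(ang) * math.sin(dih),
        ]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


# (name, element) of side-chain heavy atoms past CB, with the internal
# coordinates used to place them; the first entry's dihedral is χ1.
_SIDECHAINS = {
    "ASN": [
        ("CG", "C", ("N", "CA", "CB"), 1.52, 112.6, None),  # χ1
        ("OD1", "O", ("CA", "CB", "CG"), 1.23, 120.8, -58.0),
        ("ND2", "N", ("CA", "CB", "CG"), 1.33, 116.5, 122.0),
    ],
    "ILE": [
        ("CG1", "C", ("N", "CA", "CB"), 1.53, 110.4, None),  # χ1
        ("CG2", "C", ("N", "CA", "CB"), 1.52, 110.5, None),  # χ1 − 122°
        ("CD1", "C", ("CA", "CB", "CG1"), 1.51, 113.8, 180.0),
    ],
}


def build_residue(
    residue_name: str,
    chi1_deg: float,
    chain: str = "A",
    residue_number: int = 66,
    serial_start: int = 1,
) -> tuple[Atom, ...]:
    """Build an ideal-geometry residue (backbone + side chain) at a given χ1.

    Synthetic coordinates: the backbone (N, CA, C, O, CB) is fixed and the
    side chain beyond CB is placed by standard internal coordinates with the
    requested χ1 (N–CA–CB–X) dihedral.
    """
    if residue_name not in _SIDECHAINS:
        raise ValueError(
            f"no template for residue {residue_name!r}; "
            f"available: {sorted(_SIDECHAINS)}"
        )
    pos: dict[str, np.ndarray] = {}
    pos["N"] = np.array([0.0, 0.0, 0.0])
    pos["CA"] = np.array([1.458, 0.0, 0.0])
    pos["C"] = pos["CA"] + 1.525 * np.array(
        [math.cos(math.radians(69.0)), math.sin(math.radians(69.0)), 0.0]
    )
    pos["O"] = _place_atom(pos["N"], pos["CA"], pos["C"], 1.23, 121.0, 0.0)
    pos["CB"] = _place_atom(pos["C"], pos["N"], pos["CA"], 1.53, 110.5, 122.5)
    elements = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}
    names = ["N", "CA", "C", "O", "CB"]
    for name, element, (a, b, c), bond, angle, dih in _SIDECHAINS[residue_name]:
        if dih is None:
            dih_val = chi1_deg if name != "CG2" else chi1_deg - 122.0
        else:
            dih_val = dih
        pos[name] = _place_atom(pos[a], pos[b], pos[c], bond, angle, dih_val)
        elements[name] = element
        names.append(name)
    return tuple(
        Atom(
            serial=serial_start + i,
            name=n,
            element=elements[n],
            residue_name=residue_name,
            residue_number=residue_number,
            chain=chain,
            position=pos[n],
        )
        for i, n in enumerate(names)
    )


# ---------------------------------------------------------------------------
# Two-state Markov side-chain dynamics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TwoStateModel:
    """Parameters of the two-state (open/closed) side-chain Markov chain.

    ``k_switch`` is the per-frame switching attempt rate; transition
    probabilities P(closed→open) = k·p_open and P(open→closed) =
    k·(1 − p_open) make the stationary distribution exactly
    (p_open, 1 − p_open).  ``noise_sigma`` is the isotropic per-atom Gaussian
    coordinate noise in Å (default 0.1 Å, small against the ≥1 Å open/closed
    template separation).
    """

    p_open: float
    k_switch: float = 0.2
    residue_name: str = "ASN"
    chain: str = "A"
    residue_number: int = 66
    open_chi1: float = -60.0
    closed_chi1: float = 180.0
    noise_sigma: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.p_open < 1.0:
            raise ValueError("p_open must lie in (0, 1)")
        if not 0.0 < self.k_switch <= 1.0:
            raise ValueError("k_switch must lie in (0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass(frozen=True)
class FixtureManifest:
    """Ground truth written alongside every synthetic fixture."""

    kind: str
    parameters: dict
    seed: int
    hidden_states: tuple[str, ...] | None = None
    occluded_frames: tuple[int, ...] | None = None
    event_frame: int | None = None

    def to_json(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def _simulate_chain(model: TwoStateModel, n_frames: int, rng) -> np.ndarray:
    """Hidden open(1)/closed(0) states of the Markov chain."""
    p_co = model.k_switch * model.p_open  # closed -> open
    p_oc = model.k_switch * (1.0 - model.p_open)  # open -> closed
    states = np.empty(n_frames, dtype=int)
    states[0] = int(rng.random() < model.p_open)
    u = rng.random(n_frames - 1) if n_frames > 1 else np.empty(0)
    for i in range(1, n_frames):
        if states[i - 1] == 1:
            states[i] = 0 if u[i - 1] < p_oc else 1
        else:
            states[i] = 1 if u[i - 1] < p_co else 0
    return states


def generate_two_state_trajectory(
    model: TwoStateModel,
    n_frames: int,
    frame_interval_ns: float = 0.1,
    replicate_id: str = "r1",
    system_label: str = "two-state",
) -> tuple[Trajectory, FixtureManifest]:
    """A trajectory whose side chain hops between open/closed templates.

    Each frame places the residue at the open or closed ideal-geometry
    template according to the hidden Markov state and adds isotropic
    Gaussian noise to every atom.  The manifest records the hidden states.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(model.seed)
    states = _simulate_chain(model, n_frames, rng)
    templates = {
        1: build_residue(
            model.residue_name, model.open_chi1, model.chain, model.residue_number
        ),
        0: build_residue(
            model.residue_name, model.closed_chi1, model.chain, model.residue_number
        ),
    }
    template_coords = {
        s: np.array([a.position for a in atoms]) for s, atoms in templates.items()
    }
    base_atoms = templates[0]
    frames = []
    for i, s in enumerate(states):
        coords = template_coords[int(s)]
        if model.noise_sigma > 0:
            coords = coords + rng.normal(0.0, model.noise_sigma, coords.shape)
        atoms = tuple(
            dataclasses.replace(a, position=c) for a, c in zip(base_atoms, coords)
        )
        frames.append(Frame(atoms, frame_index=i, time_ns=i * frame_interval_ns))
    traj = Trajectory(
        tuple(frames),
        frame_interval_ns=frame_interval_ns,
        replicate_id=replicate_id,
        system_label=system_label,
    )
    manifest = FixtureManifest(
        kind="two_state",
        parameters={
            "p_open": model.p_open,
            "k_switch": model.k_switch,
            "residue_name": model.residue_name,
            "open_chi1": model.open_chi1,
            "closed_chi1": model.closed_chi1,
            "noise_sigma": model.noise_sigma,
            "n_frames": n_frames,
            "frame_interval_ns": frame_interval_ns,
        },
        seed=model.seed,
        hidden_states=tuple(OPEN if s else CLOSED for s in states),
    )
    return traj, manifest


def default_chi1_references(
    model: TwoStateModel,
) -> tuple[DihedralReference, DihedralReference]:
    """(open, closed) χ1 references matching the generator's templates."""
    mk = lambda angle, state: DihedralReference(
        chain=model.chain,
        residue_number=model.residue_number,
        chi1_deg=angle,
        state_name=state,
        provenance="synthetic ideal-geometry template",
    )
    return mk(model.open_chi1, OPEN), mk(model.closed_chi1, CLOSED)


def default_rmsd_references(
    model: TwoStateModel,
) -> tuple[RmsdReference, RmsdReference]:
    """(open, closed) side-chain RMSD references from the templates."""

    def mk(angle: float, state: str) -> RmsdReference:
        atoms = build_residue(
            model.residue_name, angle, model.chain, model.residue_number
        )
        side = [a for a in atoms if a.name not in ("N", "CA", "C", "O")]
        return RmsdReference(
            chain=model.chain,
            residue_number=model.residue_number,
            residue_name=model.residue_name,
            atom_names=tuple(a.name for a in side),
            coords=np.array([a.position for a in side]),
            state_name=state,
            provenance="synthetic ideal-geometry template",
        )

    return mk(model.open_chi1, OPEN), mk(model.closed_chi1, CLOSED)


# ---------------------------------------------------------------------------
# Scheduled occlusion and hydrogen-bond fixtures
# ---------------------------------------------------------------------------


def generate_occlusion_fixture(
    target_fraction: float,
    n_frames: int,
    seed: int = 0,
    frame_interval_ns: float = 0.1,
) -> tuple[Trajectory, ReferenceAtomSet, FixtureManifest]:
    """A probe atom overlapping a reference in an exact fraction of frames.

    The probe (carbon) sits well inside the clash radius of a static carbon
    reference atom at the origin in exactly ``round(target_fraction ·
    n_frames)`` frames — the first k frames, a deterministic schedule — and
    far outside it otherwise.  The random seed only varies the approach
    direction, never the schedule.
    """
    if not 0.0 <= target_fraction <= 1.0:
        raise ValueError("target_fraction must lie in [0, 1]")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    r_c = vdw_radius("C")
    clash = 2 * r_c
    k = round(target_fraction * n_frames)
    frames = []
    for i in range(n_frames):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        dist = 0.3 * clash if i < k else 3.0 * clash
        atom = Atom(
            serial=1,
            name="CA",
            element="C",
            residue_name="GLY",
            residue_number=1,
            chain="A",
            position=dist * direction,
        )
        frames.append(Frame((atom,), frame_index=i, time_ns=i * frame_interval_ns))
    traj = Trajectory(
        tuple(frames), frame_interval_ns=frame_interval_ns, system_label="occlusion"
    )
    ref_set = ReferenceAtomSet(
        (ReferenceAtom("REF:C", np.zeros(3), r_c),),
        source="synthetic occlusion fixture",
    )
    manifest = FixtureManifest(
        kind="occlusion",
        parameters={
            "target_fraction": target_fraction,
            "n_frames": n_frames,
            "frame_interval_ns": frame_interval_ns,
            "n_occluded": k,
        },
        seed=seed,
        occluded_frames=tuple(range(k)),
    )
    return traj, ref_set, manifest


def generate_hbond_fixture(
    formation_frame: int,
    n_frames: int,
    frame_interval_ns: float = 0.1,
) -> tuple[Trajectory, HBondSpec, FixtureManifest]:
    """A donor/acceptor pair forming a hydrogen bond at a prescribed frame.

    Before ``formation_frame`` the donor–acceptor distance is 6 Å (outside
    the default 3.5 Å cutoff); from ``formation_frame`` on it is 2.9 Å with
    a collinear donor hydrogen (angle 180°).  ``formation_frame ==
    n_frames`` yields a bond that never forms.
    """
    if not 0 <= formation_frame <= n_frames:
        raise ValueError("formation_frame must lie in [0, n_frames]")
    spec = HBondSpec(donor="A:1:ND2", hydrogen="A:1:HD21", acceptor="B:2:OD1")
    donor_pos = np.zeros(3)
    axis = np.array([1.0, 0.0, 0.0])
    frames = []
    for i in range(n_frames):
        d = 2.9 if i >= formation_frame else 6.0
        atoms = (
            Atom(1, "ND2", "N", "ASN", 1, "A", donor_pos),
            Atom(2, "HD21", "H", "ASN", 1, "A", donor_pos + 1.0 * axis),
            Atom(3, "OD1", "O", "ASP", 2, "B", donor_pos + d * axis),
        )
        frames.append(Frame(atoms, frame_index=i, time_ns=i * frame_interval_ns))
    traj = Trajectory(
        tuple(frames), frame_interval_ns=frame_interval_ns, system_label="hbond"
    )
    manifest = FixtureManifest(
        kind="hbond",
        parameters={
            "formation_frame": formation_frame,
            "n_frames": n_frames,
            "frame_interval_ns": frame_interval_ns,
        },
        seed=0,
        event_frame=formation_frame if formation_frame < n_frames else None,
    )
    return traj, spec, manifest
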