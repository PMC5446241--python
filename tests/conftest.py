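import numpy as np
import pytest
from hypothesis import settings

from flexprobe.structure_io import Atom, Frame, Trajectory

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


def make_atom(serial=1, name="CA", element="C", resname="GLY", resnum=1,
              chain="A", position=(0.0, 0.0, 0.0)):
    return Atom(
        serial=serial, name=name, element=element, residue_name=resname,
        residue_number=resnum, chain=chain, position=np.asarray(position, float),
    )


def make_frame(positions, names=None, elements=None, resnums=None,
               resname="GLY", chain="A", frame_index=0, time_ns=0.0):
    """A frame from bare coordinates, with optional atom naming."""
    positions = np.asarray(positions, float)
    n = len(positions)
    names = names or [f"C{i}" for i in range(n)]
    elements = elements or ["C"] * n
    resnums = resnums or [1] * n
    atoms = tuple(
        make_atom(serial=i + 1, name=names[i], element=elements[i],
                  resname=resname, resnum=resnums[i], chain=chain,
                  position=positions[i])
        for i in range(n)
    )
    return Frame(atoms, frame_index=frame_index, time_ns=time_ns)


def make_trajectory(frame_positions, frame_interval_ns=0.1, **frame_kwargs):
    """A trajectory from an (n_frames, n_atoms, 3) coordinate stack."""
    frames = tuple(
        make_frame(pos, frame_index=i, time_ns=i * frame_interval_ns,
                   **frame_kwargs)
        for i, pos in enumerate(frame_positions)
    )
    return Trajectory(frames, frame_interval_ns=frame_interval_ns)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
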