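"""Project atomistic trajectories onto coarse-grained bead coordinates.

A bead position is the mass-weighted (default) or unweighted mean of its
member atoms.  Under periodic boundaries, member atoms are first made whole
by minimum-image unwrapping relative to the bead's first member atom, so a
molecule straddling the box edge does not produce a bead in the box centre.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from cgstack.core_io import BeadDefinition, Frame, MolecularTopology, Trajectory
from cgstack.errors import CGStackError


@dataclass
class CGFrame:
    """Bead coordinates (nm) for one frame."""

    bead_coordinates: np.ndarray
    box: Optional[np.ndarray] = None
    time: float = 0.0

    def __post_init__(self):
        self.bead_coordinates = np.asarray(self.bead_coordinates, dtype=float)
        if self.bead_coordinates.ndim != 2 or self.bead_coordinates.shape[1] != 3:
            raise ValueError("bead_coordinates must have shape (n_beads, 3)")
        if not np.all(np.isfinite(self.bead_coordinates)):
            raise ValueError("bead coordinates must be finite")

    @property
    def n_beads(self) -> int:
        return self.bead_coordinates.shape[0]


@dataclass
class CGTrajectory:
    """Ordered CG frames with constant bead count."""

    frames: list[CGFrame]

    def __post_init__(self):
        if not self.frames:
            raise ValueError("CG trajectory must contain at least one frame")
        n = self.frames[0].n_beads
        for k, fr in enumerate(self.frames):
            if fr.n_beads != n:
                raise ValueError(f"frame {k} has {fr.n_beads} beads, expected {n}")

    @property
    def bead_count(self) -> int:
        return self.frames[0].n_beads

    def __len__(self):
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def coordinate_array(self) -> np.ndarray:
        """Stack all frames into an (n_frames, n_beads, 3) array."""
        return np.stack([fr.bead_coordinates for fr in self.frames])


def _bead_weights(bead: BeadDefinition, masses: np.ndarray) -> np.ndarray:
    idx = np.asarray(bead.member_atoms)
    if bead.weighting == "mass":
        w = masses[idx]
    else:
        w = np.ones(idx.size)
    return w / w.sum()


def map_frame(frame: Frame, scheme: Sequence[BeadDefinition],
              topology: MolecularTopology) -> CGFrame:
    """Map one atomistic frame to bead coordinates.

    With a box, each bead's member atoms are shifted by whole box lengths to
    the image nearest the first member atom before averaging.
    """
    coords = frame.coordinates
    n_atoms = coords.shape[0]
    masses = topology.masses
    if masses.shape[0] != n_atoms:
        raise CGStackError(
            f"topology has {masses.shape[0]} atoms but frame has {n_atoms}"
        )
    out = np.empty((len(scheme), 3))
    for b, bead in enumerate(scheme):
        idx = np.asarray(bead.member_atoms)
        if idx.max() >= n_atoms:
            raise CGStackError(
                f"bead {bead.bead_name!r} references atom {int(idx.max())} "
                f"out of range for {n_atoms} atoms"
            )
        member = coords[idx]
        if not np.all(np.isfinite(member)):
            raise CGStackError(
                f"bead {bead.bead_name!r} has a member atom with non-finite coordinates"
            )
        if frame.box is not None:
            ref = member[0]
            delta = member - ref
            member = member - np.round(delta / frame.box) * frame.box
        w = _bead_weights(bead, masses)
        out[b] = w @ member
    return CGFrame(out, box=None if frame.box is None else frame.box.copy(),
                   time=frame.time)


def map_trajectory(trajectory: Trajectory, scheme: Sequence[BeadDefinition],
                   topology: MolecularTopology) -> CGTrajectory:
    """Map every frame; frame count and times are preserved."""
    frames = []
    for k, fr in enumerate(trajectory):
        try:
            frames.append(map_frame(fr, scheme, topology))
        except CGStackError as exc:
            raise CGStackError(f"frame {k}: {exc}") from exc
    return CGTrajectory(frames)
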