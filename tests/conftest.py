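"""Shared builders for small synthetic topologies, frames and spectra."""

from __future__ import annotations

import numpy as np
import pytest

from pepagg.traj.model import Frame, Topology, Trajectory


def point_topology(n_molecules: int, radius: float = 0.15,
                   hydrophobic: bool = True) -> Topology:
    """n single-atom molecules (one residue each)."""
    n = n_molecules
    return Topology(
        molecule_of_atom=np.arange(n),
        residue_of_atom=np.arange(n),
        atom_names=[f"A{i}" for i in range(n)],
        elements=["C"] * n,
        radii=np.full(n, radius),
        is_donor=np.zeros(n, dtype=bool),
        is_acceptor=np.zeros(n, dtype=bool),
        is_hydrophobic=np.full(n, hydrophobic),
        h_parent=np.full(n, -1),
        residue_names=[f"RES" for _ in range(n)],
        residue_molecule=np.arange(n),
    )


def chain_topology(n_molecules: int, beads: int, radius: float = 0.15
                   ) -> Topology:
    """n rigid bead-chain molecules, one residue per bead (RES1..RESk)."""
    n = n_molecules * beads
    mol = np.repeat(np.arange(n_molecules), beads)
    return Topology(
        molecule_of_atom=mol,
        residue_of_atom=np.arange(n),
        atom_names=[f"C{i % beads + 1}" for i in range(n)],
        elements=["C"] * n,
        radii=np.full(n, radius),
        is_donor=np.zeros(n, dtype=bool),
        is_acceptor=np.zeros(n, dtype=bool),
        is_hydrophobic=np.ones(n, dtype=bool),
        h_parent=np.full(n, -1),
        residue_names=[f"RES{i % beads + 1}" for i in range(n)],
        residue_molecule=mol.copy(),
    )


def frame_of(points, box=10.0, time=0.0) -> Frame:
    pts = np.asarray(points, dtype=float)
    return Frame(pts, np.broadcast_to(np.asarray(box, float), (3,)).copy(),
                 time)


def traj_of(frames_points, topology, box=10.0, dt=1.0) -> Trajectory:
    frames = [frame_of(p, box, time=i * dt)
              for i, p in enumerate(frames_points)]
    return Trajectory(topology, frames)


@pytest.fixture
def make_point_traj():
    """Factory: trajectory of single-atom molecules from per-frame positions."""

    def build(frames_points, box=10.0, dt=1.0):
        n = len(frames_points[0])
        return traj_of(frames_points, point_topology(n), box=box, dt=dt)

    return build


def brute_force_components(contact: np.ndarray) -> list[tuple[int, ...]]:
    """Independent connected-components oracle: BFS on the boolean matrix."""
    n = contact.shape[0]
    seen = [False] * n
    comps = []
    for start in range(n):
        if seen[start]:
            continue
        stack, comp = [start], []
        seen[start] = True
        while stack:
            u = stack.pop()
            comp.append(u)
            for v in range(n):
                if contact[u, v] and not seen[v]:
                    seen[v] = True
                    stack.append(v)
        comps.append(tuple(sorted(comp)))
    return sorted(comps, key=lambda c: c[0])


def brute_force_min_image(a, b, box) -> float:
    """Independent minimum-image distance: explicit search over 27 images."""
    a, b, box = (np.asarray(v, dtype=float) for v in (a, b, box))
    best = np.inf
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                shift = np.array([dx, dy, dz]) * box
                best = min(best, float(np.linalg.norm(a - (b + shift))))
    return best
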