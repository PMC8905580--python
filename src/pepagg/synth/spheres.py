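"""Sticky-sphere Brownian toy simulator for exercising aggregation analytics.

Rigid bead-chain molecules diffuse in a periodic cubic box; when two unbound
molecules come within a contact cutoff they bind with probability ``p_bind``
(their clusters then move as one rigid unit, held at a rest separation), and
each bond breaks with probability ``p_unbind`` per step, after which the
freed cluster is pushed just beyond the cutoff so the unbinding is resolvable
at the frame rate (a stand-in for local escape).  A short rebind refractory
keeps a freshly separated pair from re-registering immediately.

This is ground-truth plumbing, not a physical MD surrogate: its purpose is
that stickiness ranks, irreversibility limits and event counts are *known*,
so the clustering, event-detection and CAP code can be validated end to end.
The generator records its own bind/unbind decisions in the ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ..traj.model import Frame, Topology, Trajectory, write_trajectory

__all__ = ["StickySphereConfig", "simulate_sticky_spheres", "bead_chain_topology"]


@dataclass
class StickySphereConfig:
    """Simulator conditions.

    The defaults mirror the reference setup the analytics are aimed at: 20
    molecules in a 15 nm cubic box (about 10 mM).  ``diffusion_step_sd`` is
    the per-step RMS displacement per axis of a free molecule; clusters of k
    molecules move with sd / sqrt(k).
    """

    n_molecules: int = 20
    box: float = 15.0
    beads_per_molecule: int = 3
    bead_spacing: float = 0.3
    bead_radius: float = 0.15
    residue_names: tuple[str, ...] | None = None
    diffusion_step_sd: float = 0.25
    p_bind: float = 1.0
    p_unbind: float = 0.0
    contact_cutoff: float = 0.5
    bind_rest_distance: float = 0.4
    unbind_push: float = 0.15
    rebind_refractory_steps: int = 5
    n_steps: int = 1000
    dt_ns: float = 0.5
    save_every: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_molecules < 2:
            raise ValueError("need at least 2 molecules")
        if self.box <= 0:
            raise ValueError("box edge must be positive")
        for name in ("p_bind", "p_unbind"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.residue_names is not None and \
                len(self.residue_names) != self.beads_per_molecule:
            raise ValueError("residue_names length must equal beads_per_molecule")


def bead_chain_topology(cfg: StickySphereConfig) -> Topology:
    """One residue per bead, all beads carbon-like and flagged hydrophobic."""
    nb = cfg.beads_per_molecule
    names = cfg.residue_names or tuple(f"BD{k + 1}" for k in range(nb))
    n = cfg.n_molecules * nb
    mol = np.repeat(np.arange(cfg.n_molecules), nb)
    res_of_atom = np.arange(n)  # one residue per bead
    residue_names = [names[k % nb] for k in range(n)]
    residue_molecule = mol.copy()
    return Topology(
        molecule_of_atom=mol,
        residue_of_atom=res_of_atom,
        atom_names=[f"C{k % nb + 1}" for k in range(n)],
        elements=["C"] * n,
        radii=np.full(n, cfg.bead_radius),
        is_donor=np.zeros(n, dtype=bool),
        is_acceptor=np.zeros(n, dtype=bool),
        is_hydrophobic=np.ones(n, dtype=bool),
        h_parent=np.full(n, -1),
        residue_names=residue_names,
        residue_molecule=residue_molecule,
    )


def _bead_offsets(cfg: StickySphereConfig) -> np.ndarray:
    """Rigid linear-chain offsets along x, centered on the molecule origin."""
    nb = cfg.beads_per_molecule
    xs = (np.arange(nb) - (nb - 1) / 2.0) * cfg.bead_spacing
    out = np.zeros((nb, 3))
    out[:, 0] = xs
    return out


def _min_image(d: np.ndarray, box: float) -> np.ndarray:
    return d - box * np.round(d / box)


def _pair_min_distance(ci: np.ndarray, cj: np.ndarray, offsets: np.ndarray,
                       box: float) -> tuple[float, np.ndarray]:
    """Min bead-bead distance between two molecules and the i->j center vector."""
    sep = _min_image(cj - ci, box)
    d = sep[None, None, :] + offsets[None, :, :] - offsets[:, None, :]
    dist = np.sqrt(np.sum(d * d, axis=-1))
    return float(dist.min()), sep


def _clusters(n: int, bonds: set[tuple[int, int]]) -> list[list[int]]:
    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i, j in bonds:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri
    groups: dict[int, list[int]] = {}
    for m in range(n):
        groups.setdefault(find(m), []).append(m)
    return list(groups.values())


def simulate_sticky_spheres(cfg: StickySphereConfig,
                            outdir: str | Path | None = None,
                            ) -> tuple[Trajectory, dict]:
    """Run the simulator; optionally write the plain dialect plus ground truth.

    Returns ``(trajectory, ground_truth)``.  The ground truth records the
    simulator's own bind/unbind decisions (counts and times), the final bond
    list, and the full config, so analytics run on the trajectory can be
    checked against what actually happened.
    """
    ss = np.random.SeedSequence(cfg.seed)
    rng_init, rng_moves, rng_events = (np.random.default_rng(s)
                                       for s in ss.spawn(3))
    n, box = cfg.n_molecules, cfg.box
    offsets = _bead_offsets(cfg)
    centers = rng_init.uniform(0.0, box, size=(n, 3))
    bonds: set[tuple[int, int]] = set()
    refractory: dict[tuple[int, int], int] = {}
    n_bind_sim = 0
    n_unbind_sim = 0
    n_unbind_trials = 0  # bond-steps: one Bernoulli(p_unbind) trial each
    topo = bead_chain_topology(cfg)
    frames: list[Frame] = []

    def snapshot(step: int) -> None:
        coords = (centers[:, None, :] + offsets[None, :, :]).reshape(-1, 3)
        coords = np.mod(coords, box)
        frames.append(Frame(coords, np.array([box, box, box]),
                            time=step * cfg.dt_ns))

    snapshot(0)
    for step in range(1, cfg.n_steps + 1):
        # rigid cluster diffusion
        for cl in _clusters(n, bonds):
            disp = rng_moves.normal(
                0.0, cfg.diffusion_step_sd / np.sqrt(len(cl)), size=3)
            centers[cl] += disp
        centers = np.mod(centers, box)

        for key in list(refractory):
            refractory[key] -= 1
            if refractory[key] <= 0:
                del refractory[key]

        # unbinding: break bonds, push freed clusters just past the cutoff
        for bond in sorted(bonds):
            n_unbind_trials += 1
            if rng_events.random() < cfg.p_unbind:
                bonds.discard(bond)
                n_unbind_sim += 1
                i, j = bond
                cl_map = {m: ci for ci, cl in enumerate(_clusters(n, bonds))
                          for m in cl}
                if cl_map[i] != cl_map[j]:
                    dmin, sep = _pair_min_distance(centers[i], centers[j],
                                                   offsets, box)
                    target = cfg.contact_cutoff + cfg.unbind_push
                    if dmin < target:
                        norm = np.linalg.norm(sep)
                        direction = (sep / norm if norm > 0
                                     else np.array([1.0, 0.0, 0.0]))
                        shift = (target - dmin) * direction
                        members = [m for m, c in cl_map.items()
                                   if c == cl_map[j]]
                        centers[members] = np.mod(centers[members] + shift, box)
                if cfg.rebind_refractory_steps > 0:
                    refractory[bond] = cfg.rebind_refractory_steps

        # binding: unbound molecule pairs in contact stick with p_bind
        cl_map = {m: ci for ci, cl in enumerate(_clusters(n, bonds))
                  for m in cl}
        for i in range(n):
            for j in range(i + 1, n):
                if cl_map[i] == cl_map[j] or (i, j) in refractory:
                    continue
                dmin, sep = _pair_min_distance(centers[i], centers[j],
                                               offsets, box)
                if dmin > cfg.contact_cutoff:
                    continue
                if rng_events.random() < cfg.p_bind:
                    # snap the joining cluster to the rest separation
                    if dmin > 1e-12:
                        norm = np.linalg.norm(sep)
                        direction = (sep / norm if norm > 0
                                     else np.array([1.0, 0.0, 0.0]))
                        shift = (cfg.bind_rest_distance - dmin) * direction
                        members = [m for m, c in cl_map.items()
                                   if c == cl_map[j]]
                        centers[members] = np.mod(centers[members] + shift,
                                                  box)
                    bonds.add((i, j))
                    n_bind_sim += 1
                    cl_map = {m: ci for ci, cl in
                              enumerate(_clusters(n, bonds)) for m in cl}

        if step % cfg.save_every == 0:
            snapshot(step)

    traj = Trajectory(topo, frames)
    truth = {
        "n_bind_sim": n_bind_sim,
        "n_unbind_sim": n_unbind_sim,
        "n_unbind_trials": n_unbind_trials,
        "final_bonds": sorted(list(b) for b in bonds),
        "config": {
            "n_molecules": n, "box_nm": box,
            "beads_per_molecule": cfg.beads_per_molecule,
            "p_bind": cfg.p_bind, "p_unbind": cfg.p_unbind,
            "contact_cutoff_nm": cfg.contact_cutoff,
            "n_steps": cfg.n_steps, "dt_ns": cfg.dt_ns,
            "save_every": cfg.save_every, "seed": cfg.seed,
        },
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_trajectory(traj, outdir / "trajectory.dat",
                         outdir / "topology.dat")
        (outdir / "ground_truth.json").write_text(json.dumps(truth, indent=2))
    return traj, truth
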