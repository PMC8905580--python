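"""Residue contact maps, geometric hydrogen bonds, and hydrophobic SASA.

These analytics characterize *how* molecules touch once aggregated:

* :func:`contact_map` — average inter-molecular residue-residue contact
  frequency per frame, optionally normalized by a reference total so maps of
  different species are comparable on one scale;
* :func:`count_hbonds` — geometric hydrogen-bond counting (donor-acceptor
  distance plus H-donor-acceptor angle), partitioned into peptide-peptide
  and peptide-water bonds;
* :func:`shrake_rupley_sasa` — solvent-accessible surface area by the
  Shrake-Rupley test-point method on a deterministic golden-spiral lattice,
  with the hydrophobic subtotal (hSASA) per molecule.

All geometry is minimum-image in the orthorhombic box.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import (Frame, Topology, Trajectory, min_image_displacement,
                    _pairwise_min_image_dist)

__all__ = [
    "ContactMap",
    "HBondCriterion",
    "HBondCounts",
    "SasaResult",
    "contact_map",
    "count_hbonds",
    "shrake_rupley_sasa",
    "golden_spiral_points",
]


# ---------------------------------------------------------------------------
# residue-residue contact maps


@dataclass
class ContactMap:
    """Mean inter-molecular residue-residue contact counts per frame.

    ``frequency[a, b]`` is the average number of molecule pairs per frame in
    which residue ``a`` of one molecule touches residue ``b`` of the other
    (any atom pair within the cutoff), symmetrized over the two orderings.
    ``normalization_reference`` is the scalar the matrix was divided by (1.0
    when no external reference is supplied); ``total`` is the matrix sum
    before that division, usable as the reference for another species' map.
    """

    residue_labels: list[str]
    frequency: np.ndarray
    normalization_reference: float
    total: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.frequency, index=self.residue_labels,
                            columns=self.residue_labels)


def contact_map(traj: Trajectory, contact_cutoff: float = 0.5,
                reference_total: float | None = None,
                stride: int = 1) -> ContactMap:
    """Average inter-peptide residue-residue contact frequencies.

    Requires a homomeric system (every molecule shares one residue
    template).  For each frame and each ordered molecule pair (i != j), a
    residue pair (a, b) contributes one contact when the minimum atom-atom
    minimum-image distance between residue a of molecule i and residue b of
    molecule j is within ``contact_cutoff``.  Counting both orderings makes
    the matrix symmetric; the result is averaged over frames and divided by
    ``reference_total`` when given.
    """
    topo = traj.topology
    template = topo.residue_template()  # raises for heteromeric systems
    nres = len(template)
    labels = [f"{k + 1}:{name}" for k, name in enumerate(template)]
    # per molecule, per template position: atom indices
    res_atoms: list[list[np.ndarray]] = []
    for mi in range(topo.n_molecules):
        rids = topo.molecule_residues(mi)
        res_atoms.append([np.flatnonzero(topo.residue_of_atom == ri)
                          for ri in rids])
    freq = np.zeros((nres, nres))
    frames = traj.strided(stride).frames
    for frame in frames:
        for i in range(topo.n_molecules):
            for j in range(topo.n_molecules):
                if i == j:
                    continue
                for a in range(nres):
                    xa = frame.coordinates[res_atoms[i][a]]
                    for b in range(nres):
                        xb = frame.coordinates[res_atoms[j][b]]
                        dmin = _pairwise_min_image_dist(xa, xb, frame.box).min()
                        if dmin <= contact_cutoff:
                            freq[a, b] += 1.0
    freq /= len(frames)
    freq = 0.5 * (freq + freq.T)  # exact symmetry despite float summation order
    total = float(freq.sum())
    ref = float(reference_total) if reference_total is not None else 1.0
    if reference_total is not None:
        if reference_total <= 0:
            raise ValueError("reference_total must be positive")
        freq = freq / ref
    return ContactMap(labels, freq, ref, total)


# ---------------------------------------------------------------------------
# hydrogen bonds

WATER_RESNAMES = {"SOL", "WAT", "HOH", "TIP3"}


@dataclass(frozen=True)
class HBondCriterion:
    """Geometric criterion: D-A distance and H-D-A angle cutoffs.

    Defaults (0.35 nm, 30 degrees) are the conventional geometric hydrogen
    bond definition for aqueous simulations.
    """

    da_max: float = 0.35
    angle_max: float = 30.0

    def __post_init__(self) -> None:
        if self.da_max <= 0:
            raise ValueError("da_max must be > 0")
        if not 0 < self.angle_max <= 90:
            raise ValueError("angle_max must be in (0, 90] degrees")


@dataclass
class HBondCounts:
    """Hydrogen-bond totals of one frame, partitioned by molecule class."""

    peptide_peptide: int = 0
    peptide_water: int = 0
    water_water: int = 0
    skipped_donors: list[int] = field(default_factory=list)


def count_hbonds(frame: Frame, topology: Topology,
                 criterion: HBondCriterion = HBondCriterion(),
                 water_resnames: set[str] = WATER_RESNAMES) -> HBondCounts:
    """Count hydrogen bonds in one frame by the geometric criterion.

    A bond is a (donor D, attached hydrogen H, acceptor A) triple with the
    D-A minimum-image distance within ``criterion.da_max`` and the H-D-A
    angle within ``criterion.angle_max``; intra-molecular triples are
    excluded.  Donors without an attached hydrogen (``h_parent`` never
    pointing at them) are skipped with a warning and reported in
    ``skipped_donors``.  Molecules whose residues are all in
    ``water_resnames`` count as water.
    """
    donors = np.flatnonzero(topology.is_donor)
    acceptors = np.flatnonzero(topology.is_acceptor)
    if donors.size == 0 or acceptors.size == 0:
        return HBondCounts()
    hydrogens_of = {int(d): np.flatnonzero(topology.h_parent == d)
                    for d in donors}

    def is_water(mi: int) -> bool:
        rids = topology.molecule_residues(mi)
        return all(topology.residue_names[ri] in water_resnames for ri in rids)

    water_mol = np.array([is_water(m) for m in range(topology.n_molecules)])
    counts = HBondCounts()
    cos_max = np.cos(np.deg2rad(criterion.angle_max))
    xyz = frame.coordinates
    box = frame.box
    acc_pos = xyz[acceptors]
    for d in donors:
        hs = hydrogens_of[int(d)]
        if hs.size == 0:
            warnings.warn(f"donor atom {d} has no attached hydrogen; skipped",
                          stacklevel=2)
            counts.skipped_donors.append(int(d))
            continue
        mol_d = topology.molecule_of_atom[d]
        da = min_image_displacement(acc_pos, xyz[d], box)  # D -> A
        dist = np.linalg.norm(da, axis=1)
        ok = (dist <= criterion.da_max)
        ok &= topology.molecule_of_atom[acceptors] != mol_d
        if not ok.any():
            continue
        for a_idx in np.flatnonzero(ok):
            a = acceptors[a_idx]
            v_da = da[a_idx] / dist[a_idx]
            for h in hs:
                v_dh = min_image_displacement(xyz[h], xyz[d], box)
                nh = np.linalg.norm(v_dh)
                if nh == 0:
                    continue
                if float(v_dh @ v_da) / nh >= cos_max:  # angle <= angle_max
                    mol_a = topology.molecule_of_atom[a]
                    wd, wa = water_mol[mol_d], water_mol[mol_a]
                    if wd and wa:
                        counts.water_water += 1
                    elif wd or wa:
                        counts.peptide_water += 1
                    else:
                        counts.peptide_peptide += 1
    return counts


# ---------------------------------------------------------------------------
# Shrake-Rupley SASA


@dataclass
class SasaResult:
    """Per-atom accessible areas (nm^2) and per-molecule hydrophobic subtotal."""

    per_atom_area: np.ndarray
    hsasa_per_molecule: np.ndarray
    total_per_molecule: np.ndarray
    probe_radius: float
    n_sphere_points: int

    @property
    def total(self) -> float:
        return float(self.per_atom_area.sum())


def golden_spiral_points(n: int) -> np.ndarray:
    """``n`` near-uniform unit-sphere points on a deterministic golden-spiral
    lattice, so SASA is reproducible bit for bit at fixed ``n``."""
    i = np.arange(n)
    z = 1.0 - 2.0 * (i + 0.5) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    rho = np.sqrt(1.0 - z * z)
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def shrake_rupley_sasa(frame: Frame, topology: Topology,
                       probe: float = 0.14,
                       n_points: int = 960) -> SasaResult:
    """Solvent-accessible surface area by Shrake-Rupley test points.

    Each atom's sphere is expanded by the probe radius (default 0.14 nm, a
    water molecule) and sampled with ``n_points`` lattice points; a point is
    accessible when no other atom's expanded sphere covers it
    (minimum-image).  The per-atom area is the accessible fraction of the
    expanded sphere, 4*pi*(r+probe)^2.  hSASA per molecule sums the atoms
    flagged hydrophobic.
    """
    if probe < 0:
        raise ValueError("probe radius must be >= 0")
    xyz = frame.coordinates
    box = frame.box
    n = topology.n_atoms
    expanded = topology.radii + probe
    unit = golden_spiral_points(n_points)
    areas = np.empty(n)
    for i in range(n):
        ri = expanded[i]
        pts = xyz[i] + ri * unit
        accessible = np.ones(n_points, dtype=bool)
        # neighbor prefilter: only atoms whose expanded spheres can reach
        d_to_others = np.linalg.norm(
            min_image_displacement(xyz, xyz[i], box), axis=1)
        neigh = np.flatnonzero((d_to_others < ri + expanded) &
                               (np.arange(n) != i))
        for j in neigh:
            d = min_image_displacement(pts, xyz[j], box)
            accessible &= np.einsum("ij,ij->i", d, d) > expanded[j] ** 2
            if not accessible.any():
                break
        areas[i] = 4.0 * np.pi * ri * ri * accessible.mean()
    hsasa = np.zeros(topology.n_molecules)
    tot = np.zeros(topology.n_molecules)
    for m in range(topology.n_molecules):
        idx = topology.molecule_atoms(m)
        tot[m] = areas[idx].sum()
        hsasa[m] = areas[idx[topology.is_hydrophobic[idx]]].sum()
    return SasaResult(areas, hsasa, tot, probe, n_points)
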