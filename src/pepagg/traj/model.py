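"""Molecule-grouped trajectory model with an orthorhombic periodic box.

The container is deliberately small: a :class:`Topology` (molecules ->
residues -> atoms, with per-atom radii and donor/acceptor/hydrophobic flags),
a list of :class:`Frame` objects holding coordinates in nm, and minimum-image
geometry primitives.  Everything downstream (aggregate clustering, events,
contact maps, hydrogen bonds, SASA) is built on these.

Two sources are supported: a plain multi-frame text dialect (the canonical
fixture format, written by the synthetic simulator) and, when MDAnalysis is
installed, standard structure + trajectory formats (PDB/GRO + XTC/TRR or
multi-model PDB) through an adapter that converts to nm on ingest.

Boxes are orthorhombic only; triclinic boxes are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Topology",
    "Frame",
    "Trajectory",
    "box_concentration_mM",
    "min_image_displacement",
    "min_image_distance",
    "molecule_min_distance",
    "molecule_contact_matrix",
    "read_trajectory",
    "write_trajectory",
    "read_plain_topology",
    "write_plain_topology",
]

AVOGADRO = 6.02214076e23  # 1/mol


def box_concentration_mM(n_molecules: int, box_nm: float | Sequence[float]) -> float:
    """Molar concentration (mM) of ``n_molecules`` in an orthorhombic box.

    A cubic 15 nm box with 20 molecules computes to about 9.8 mM — the usual
    way a simulation box is matched to an experimental concentration.
    """
    box = np.broadcast_to(np.asarray(box_nm, dtype=float), (3,))
    if np.any(box <= 0):
        raise ValueError("box edges must be positive")
    volume_l = float(np.prod(box)) * 1e-24  # nm^3 -> L
    return n_molecules / (AVOGADRO * volume_l) * 1e3


# default van der Waals radii (nm) for the adapter when a source format
# carries no radii of its own
_DEFAULT_RADII = {"H": 0.110, "C": 0.170, "N": 0.155, "O": 0.152,
                  "S": 0.180, "P": 0.180, "CL": 0.175, "NA": 0.227,
                  "X": 0.150}


@dataclass
class Topology:
    """Static atom hierarchy: which atom belongs to which residue/molecule.

    All per-atom attributes are parallel arrays of length ``n_atoms``:

    * ``molecule_of_atom`` — molecule index (surjective onto 0..n_molecules-1)
    * ``residue_of_atom`` — global residue index
    * ``atom_names``, ``elements`` — labels
    * ``radii`` — van der Waals radii in nm, all > 0
    * ``is_donor``, ``is_acceptor``, ``is_hydrophobic`` — boolean flags
    * ``h_parent`` — for a hydrogen covalently attached to a donor heavy
      atom, that donor's atom index; -1 otherwise

    Residues carry ``residue_names`` and ``residue_molecule`` (length
    ``n_residues``).
    """

    molecule_of_atom: np.ndarray
    residue_of_atom: np.ndarray
    atom_names: list[str]
    elements: list[str]
    radii: np.ndarray
    is_donor: np.ndarray
    is_acceptor: np.ndarray
    is_hydrophobic: np.ndarray
    h_parent: np.ndarray
    residue_names: list[str]
    residue_molecule: np.ndarray

    def __post_init__(self) -> None:
        self.molecule_of_atom = np.asarray(self.molecule_of_atom, dtype=int)
        self.residue_of_atom = np.asarray(self.residue_of_atom, dtype=int)
        self.radii = np.asarray(self.radii, dtype=float)
        self.is_donor = np.asarray(self.is_donor, dtype=bool)
        self.is_acceptor = np.asarray(self.is_acceptor, dtype=bool)
        self.is_hydrophobic = np.asarray(self.is_hydrophobic, dtype=bool)
        self.h_parent = np.asarray(self.h_parent, dtype=int)
        self.residue_molecule = np.asarray(self.residue_molecule, dtype=int)
        n = self.molecule_of_atom.size
        for name, arr in (("residue_of_atom", self.residue_of_atom),
                          ("radii", self.radii), ("is_donor", self.is_donor),
                          ("is_acceptor", self.is_acceptor),
                          ("is_hydrophobic", self.is_hydrophobic),
                          ("h_parent", self.h_parent)):
            if arr.size != n:
                raise ValueError(f"{name} length {arr.size} != n_atoms {n}")
        if len(self.atom_names) != n or len(self.elements) != n:
            raise ValueError("atom_names/elements length mismatch")
        if np.any(self.radii <= 0):
            raise ValueError("all atomic radii must be > 0")
        mols = np.unique(self.molecule_of_atom)
        if not np.array_equal(mols, np.arange(mols.size)):
            raise ValueError("molecule indices must be contiguous from 0")
        # cached atom-index lists per molecule
        self._mol_atoms = [np.flatnonzero(self.molecule_of_atom == m)
                           for m in range(mols.size)]

    @property
    def n_atoms(self) -> int:
        return self.molecule_of_atom.size

    @property
    def n_molecules(self) -> int:
        return len(self._mol_atoms)

    @property
    def n_residues(self) -> int:
        return len(self.residue_names)

    def molecule_atoms(self, mi: int) -> np.ndarray:
        """Atom indices of molecule ``mi``."""
        return self._mol_atoms[mi]

    def molecule_residues(self, mi: int) -> np.ndarray:
        """Global residue indices of molecule ``mi``."""
        return np.flatnonzero(self.residue_molecule == mi)

    def residue_template(self) -> list[str]:
        """Per-molecule residue-name sequence; raises if molecules differ.

        Contact maps assume a homomeric system (all molecules share one
        residue sequence); heteromeric topologies are out of modelled scope.
        """
        template: list[str] | None = None
        for mi in range(self.n_molecules):
            names = [self.residue_names[ri] for ri in self.molecule_residues(mi)]
            if template is None:
                template = names
            elif names != template:
                raise ValueError(
                    "heteromeric topology: molecules do not share one "
                    "residue template"
                )
        assert template is not None
        return template


@dataclass
class Frame:
    """One time point: coordinates (nm), orthorhombic box edges (nm), time (ns)."""

    coordinates: np.ndarray
    box: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must have shape (n_atoms, 3)")
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ValueError("box must be three positive edge lengths (nm)")


@dataclass
class Trajectory:
    """A topology plus time-ordered frames with a constant atom count."""

    topology: Topology
    frames: list[Frame] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = self.topology.n_atoms
        last_t = -np.inf
        for i, f in enumerate(self.frames):
            if f.coordinates.shape[0] != n:
                raise ValueError(
                    f"frame {i}: {f.coordinates.shape[0]} atoms, topology "
                    f"has {n}"
                )
            if f.time <= last_t:
                raise ValueError(f"frame {i}: times must strictly increase")
            last_t = f.time

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def strided(self, stride: int) -> "Trajectory":
        """Every ``stride``-th frame (stride >= 1), emulating coarser sampling."""
        if stride < 1:
            raise ValueError("stride must be >= 1")
        return Trajectory(self.topology, self.frames[::stride])


# ---------------------------------------------------------------------------
# minimum-image geometry


def min_image_displacement(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Displacement a - b to the nearest periodic image, broadcasting over rows."""
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    box = np.asarray(box, dtype=float)
    return d - box * np.round(d / box)


def min_image_distance(a, b, box) -> float:
    """Euclidean distance between ``a`` and the nearest periodic image of ``b``."""
    return float(np.linalg.norm(min_image_displacement(a, b, box)))


def _pairwise_min_image_dist(xa: np.ndarray, xb: np.ndarray,
                             box: np.ndarray) -> np.ndarray:
    """(len(xa), len(xb)) matrix of minimum-image distances."""
    d = xa[:, None, :] - xb[None, :, :]
    d -= box * np.round(d / box)
    return np.sqrt(np.sum(d * d, axis=-1))


def molecule_min_distance(mi: int, mj: int, frame: Frame,
                          topology: Topology) -> float:
    """Minimum atom-atom minimum-image distance between two molecules."""
    if mi == mj:
        raise ValueError("molecule indices must differ")
    xa = frame.coordinates[topology.molecule_atoms(mi)]
    xb = frame.coordinates[topology.molecule_atoms(mj)]
    return float(_pairwise_min_image_dist(xa, xb, frame.box).min())


def molecule_contact_matrix(frame: Frame, topology: Topology,
                            cutoff: float) -> np.ndarray:
    """Boolean matrix: molecules i, j share an atom pair within ``cutoff`` nm.

    This is the contact criterion behind aggregate clustering: two molecules
    belong to the same aggregate if *any* of their constituent atoms lie
    within the cutoff distance (default 0.5 nm downstream).
    """
    n = topology.n_molecules
    contact = np.zeros((n, n), dtype=bool)
    coords = [frame.coordinates[topology.molecule_atoms(m)] for m in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            dmin = _pairwise_min_image_dist(coords[i], coords[j], frame.box).min()
            if dmin <= cutoff:
                contact[i, j] = contact[j, i] = True
    return contact


# ---------------------------------------------------------------------------
# plain multi-frame dialect
#
# coordinates file, repeated per frame:
#     natoms box_x box_y box_z time_ns
#     mol_index residue_name atom_name x y z        (natoms lines)
#
# topology sidecar, one line per atom after an optional '#' header:
#     mol_index residue_name atom_name element radius_nm \
#         is_donor is_acceptor is_hydrophobic h_parent


def write_plain_topology(topology: Topology, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# mol residue atom element radius_nm donor acceptor "
                 "hydrophobic h_parent\n")
        for i in range(topology.n_atoms):
            ri = topology.residue_of_atom[i]
            fh.write(
                f"{topology.molecule_of_atom[i]} {topology.residue_names[ri]} "
                f"{topology.atom_names[i]} {topology.elements[i]} "
                f"{float(topology.radii[i])!r} {int(topology.is_donor[i])} "
                f"{int(topology.is_acceptor[i])} "
                f"{int(topology.is_hydrophobic[i])} {topology.h_parent[i]}\n"
            )


def read_plain_topology(path: str | Path) -> Topology:
    mols, res_of_atom = [], []
    names, elements, radii = [], [], []
    donor, acceptor, hydrophobic, h_parent = [], [], [], []
    residue_names: list[str] = []
    residue_molecule: list[int] = []
    current_res: tuple[int, str] | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 9:
                raise ValueError(
                    f"{path}, line {lineno}: expected 9 fields, got {len(parts)}"
                )
            mi = int(parts[0])
            rname = parts[1]
            if current_res != (mi, rname) or (mols and mi != mols[-1]):
                residue_names.append(rname)
                residue_molecule.append(mi)
                current_res = (mi, rname)
            mols.append(mi)
            res_of_atom.append(len(residue_names) - 1)
            names.append(parts[2])
            elements.append(parts[3])
            radii.append(float(parts[4]))
            donor.append(bool(int(parts[5])))
            acceptor.append(bool(int(parts[6])))
            hydrophobic.append(bool(int(parts[7])))
            h_parent.append(int(parts[8]))
    return Topology(np.array(mols), np.array(res_of_atom), names, elements,
                    np.array(radii), np.array(donor), np.array(acceptor),
                    np.array(hydrophobic), np.array(h_parent),
                    residue_names, np.array(residue_molecule))


def _read_plain_frames(path: str | Path, n_atoms_expected: int | None):
    frames: list[Frame] = []
    with open(path) as fh:
        lines = [ln for ln in fh if ln.strip() and not ln.lstrip().startswith("#")]
    pos = 0
    frame_idx = 0
    while pos < len(lines):
        header = lines[pos].split()
        if len(header) != 5:
            raise ValueError(
                f"{path}: frame {frame_idx} header must be "
                f"'natoms box_x box_y box_z time_ns'"
            )
        natoms = int(header[0])
        box = np.array([float(v) for v in header[1:4]])
        time = float(header[4])
        if n_atoms_expected is not None and natoms != n_atoms_expected:
            raise ValueError(
                f"{path}: frame {frame_idx} has {natoms} atoms, topology "
                f"has {n_atoms_expected}"
            )
        body = lines[pos + 1: pos + 1 + natoms]
        if len(body) < natoms:
            raise ValueError(f"{path}: frame {frame_idx} truncated")
        coords = np.empty((natoms, 3))
        mol_idx = np.empty(natoms, dtype=int)
        res_names: list[str] = []
        atom_names: list[str] = []
        for k, ln in enumerate(body):
            parts = ln.split()
            if len(parts) != 6:
                raise ValueError(
                    f"{path}: frame {frame_idx}, atom {k}: expected "
                    f"'mol residue atom x y z'"
                )
            mol_idx[k] = int(parts[0])
            res_names.append(parts[1])
            atom_names.append(parts[2])
            coords[k] = [float(parts[3]), float(parts[4]), float(parts[5])]
        frames.append(Frame(coords, box, time))
        if frame_idx == 0:
            first_meta = (mol_idx, res_names, atom_names)
        pos += 1 + natoms
        frame_idx += 1
    if not frames:
        raise ValueError(f"{path}: no frames found")
    return frames, first_meta


def _topology_from_plain_meta(mol_idx, res_names, atom_names) -> Topology:
    """Fallback topology (default radii, no flags) from coordinate metadata."""
    n = mol_idx.size
    residue_names: list[str] = []
    residue_molecule: list[int] = []
    res_of_atom = np.empty(n, dtype=int)
    current: tuple[int, str] | None = None
    for i in range(n):
        key = (int(mol_idx[i]), res_names[i])
        if current != key:
            residue_names.append(res_names[i])
            residue_molecule.append(int(mol_idx[i]))
            current = key
        res_of_atom[i] = len(residue_names) - 1
    elements = [an[0].upper() if an else "X" for an in atom_names]
    radii = np.array([_DEFAULT_RADII.get(e, _DEFAULT_RADII["X"]) for e in elements])
    false = np.zeros(n, dtype=bool)
    return Topology(mol_idx, res_of_atom, list(atom_names), elements, radii,
                    false.copy(), false.copy(), false.copy(),
                    np.full(n, -1), residue_names, np.array(residue_molecule))


def read_trajectory(topology_path: str | Path | None,
                    coords_path: str | Path) -> Trajectory:
    """Read a trajectory from the plain dialect or standard MD formats.

    Plain-dialect coordinate files (``.dat``/``.txt``/``.xyzm``) pair with a
    plain topology sidecar; with ``topology_path=None`` a fallback topology
    (default radii, no donor/acceptor flags) is built from the coordinate
    metadata — enough for clustering and events, not for H-bonds or SASA.
    Other extensions are handed to the MDAnalysis adapter, which converts
    Angstrom-based formats to nm.
    """
    coords_path = Path(coords_path)
    if coords_path.suffix.lower() in {".dat", ".txt", ".xyzm"}:
        topo = (read_plain_topology(topology_path)
                if topology_path is not None else None)
        frames, meta = _read_plain_frames(
            coords_path, topo.n_atoms if topo else None)
        if topo is None:
            topo = _topology_from_plain_meta(*meta)
        return Trajectory(topo, frames)
    return _read_mdanalysis(topology_path, coords_path)


def write_trajectory(traj: Trajectory, coords_path: str | Path,
                     topology_path: str | Path | None = None) -> None:
    """Write the plain dialect (and optionally the topology sidecar)."""
    topo = traj.topology
    with open(coords_path, "w") as fh:
        for f in traj.frames:
            fh.write(f"{topo.n_atoms} {float(f.box[0])!r} "
                     f"{float(f.box[1])!r} {float(f.box[2])!r} "
                     f"{float(f.time)!r}\n")
            for i in range(topo.n_atoms):
                ri = topo.residue_of_atom[i]
                x, y, z = f.coordinates[i]
                fh.write(f"{topo.molecule_of_atom[i]} "
                         f"{topo.residue_names[ri]} {topo.atom_names[i]} "
                         f"{float(x)!r} {float(y)!r} {float(z)!r}\n")
    if topology_path is not None:
        write_plain_topology(topo, topology_path)


def _read_mdanalysis(topology_path, coords_path) -> Trajectory:
    """Adapter for PDB/GRO + XTC/TRR (or multi-model PDB) via MDAnalysis."""
    try:
        import MDAnalysis as mda
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError(
            "reading standard MD formats requires MDAnalysis; "
            "the plain dialect needs no extra dependency"
        ) from exc
    u = (mda.Universe(str(topology_path), str(coords_path))
         if topology_path is not None else mda.Universe(str(coords_path)))
    ag = u.atoms
    elements = []
    for a in ag:
        try:
            elements.append(a.element.upper())
        except Exception:
            elements.append(a.name[0].upper())
    radii = np.array([_DEFAULT_RADII.get(e, _DEFAULT_RADII["X"])
                      for e in elements])
    # molecule = MDAnalysis fragment if bonds exist, else segment/residue chain
    try:
        frag_of_atom = np.array([a.fragindex for a in ag])
    except Exception:
        _, frag_of_atom = np.unique([a.segindex for a in ag], return_inverse=True)
    res_of_atom = np.array([a.resindex for a in ag])
    residue_names = [r.resname for r in u.residues]
    residue_molecule = np.array([frag_of_atom[r.atoms[0].index]
                                 for r in u.residues])
    heavy_da = np.isin(elements, ["N", "O"])
    hydro = np.isin(elements, ["C"])
    h_parent = np.full(ag.n_atoms, -1)
    topo = Topology(frag_of_atom, res_of_atom, [a.name for a in ag],
                    elements, radii, heavy_da.copy(), heavy_da.copy(),
                    hydro, h_parent, residue_names, residue_molecule)
    frames = []
    t_prev = -np.inf
    for ts in u.trajectory:
        dims = ts.dimensions
        if dims is None or np.any(dims[:3] <= 0):
            raise ValueError(f"frame {ts.frame}: missing or invalid box")
        if not np.allclose(dims[3:], 90.0):
            raise ValueError(
                f"frame {ts.frame}: triclinic box not supported "
                "(orthorhombic only)"
            )
        t = float(ts.time) / 1000.0  # ps -> ns
        if t <= t_prev:
            t = t_prev + 1e-9
        t_prev = t
        frames.append(Frame(ts.positions / 10.0, dims[:3] / 10.0, t))
    return Trajectory(topo, frames)
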