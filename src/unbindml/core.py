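"""Shared data layer: topology, trajectories, I/O, superposition and RMSD.

Units are fixed package-wide: coordinates and distances in Angstrom (Å),
times in nanoseconds (ns).  Frame indices are 0-based; residue ids are taken
verbatim from the input file (1-based for PDB).  Atom roles (protein /
ligand / water / other) are assigned from residue names, with the ligand
residue name(s) supplied by the caller because ligands are arbitrary HETATM
residues.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import MDAnalysis as mda
from MDAnalysis.coordinates.memory import MemoryReader
from scipy.spatial.transform import Rotation

from .errors import (
    ConfigurationError,
    GeometryError,
    ParseError,
    StructuralError,
)

ROLES = ("protein", "ligand", "water", "other")

#: residue names recognised as water
WATER_RESNAMES = frozenset({"HOH", "TIP3", "TIP3P", "WAT", "SOL", "SPC", "TIP4"})

#: the 20 standard amino acids plus common variants
PROTEIN_RESNAMES = frozenset(
    {
        "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
        "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
        "HSD", "HSE", "HSP", "HID", "HIE", "HIP", "CYX", "ASH", "GLH", "LYN",
    }
)

_EQUAL_SPACING_TOL_NS = 1e-9


@dataclass(frozen=True)
class AtomRecord:
    """One atom of the system, with role metadata used by every selection."""

    atom_id: int
    name: str
    element: str
    is_hydrogen: bool
    residue_id: int
    residue_name: str
    role: str

    def __post_init__(self):
        if self.role not in ROLES:
            raise ConfigurationError(
                f"unknown role {self.role!r} for atom {self.atom_id}; "
                f"expected one of {ROLES}"
            )


@dataclass(frozen=True)
class Selection:
    """Declarative atom selection: by role, heavy-only, residue-id range."""

    role: str | None = None
    heavy_only: bool = True
    residue_range: tuple[int, int] | None = None

    def __post_init__(self):
        if self.role is not None and self.role not in ROLES:
            raise ConfigurationError(f"unknown role {self.role!r}")
        if self.residue_range is not None:
            first, last = self.residue_range
            if first > last:
                raise ConfigurationError(
                    f"residue_range first ({first}) > last ({last})"
                )


class Topology:
    """Immutable atom table with cached per-field arrays.

    Invariants enforced at construction: atom ids are dense in file order
    (0..N-1) and residue ids are non-decreasing within each contiguous block
    of a single role.
    """

    def __init__(self, atoms: list[AtomRecord]):
        if not atoms:
            raise ConfigurationError("topology must contain at least one atom")
        self.atoms = tuple(atoms)
        ids = np.array([a.atom_id for a in atoms])
        if not np.array_equal(ids, np.arange(len(atoms))):
            raise StructuralError("atom_ids must be dense 0..N-1 in file order")
        self.names = np.array([a.name for a in atoms])
        self.elements = np.array([a.element for a in atoms])
        self.is_hydrogen = np.array([a.is_hydrogen for a in atoms], dtype=bool)
        self.residue_ids = np.array([a.residue_id for a in atoms], dtype=int)
        self.residue_names = np.array([a.residue_name for a in atoms])
        self.roles = np.array([a.role for a in atoms])
        self._check_residue_monotone()

    def _check_residue_monotone(self):
        block_start = 0
        for i in range(1, self.n_atoms + 1):
            if i == self.n_atoms or self.roles[i] != self.roles[block_start]:
                block = self.residue_ids[block_start:i]
                if np.any(np.diff(block) < 0):
                    raise StructuralError(
                        "residue ids decrease within a "
                        f"{self.roles[block_start]!r} block"
                    )
                block_start = i

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def select(self, selection: Selection) -> np.ndarray:
        """Resolve a :class:`Selection` to an array of atom indices."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if selection.role is not None:
            mask &= self.roles == selection.role
        if selection.heavy_only:
            mask &= ~self.is_hydrogen
        if selection.residue_range is not None:
            first, last = selection.residue_range
            mask &= (self.residue_ids >= first) & (self.residue_ids <= last)
        return np.flatnonzero(mask)

    # frequently used selections
    def heavy(self, role: str) -> np.ndarray:
        return self.select(Selection(role=role, heavy_only=True))

    @property
    def ligand_heavy(self) -> np.ndarray:
        return self.heavy("ligand")

    @property
    def protein_heavy(self) -> np.ndarray:
        return self.heavy("protein")

    def water_molecules(self) -> dict[int, np.ndarray]:
        """Map water residue id -> atom indices of that molecule."""
        out: dict[int, list[int]] = {}
        for i in np.flatnonzero(self.roles == "water"):
            out.setdefault(int(self.residue_ids[i]), []).append(int(i))
        return {rid: np.array(ix) for rid, ix in out.items()}

    def require_pipeline_atoms(self):
        if len(self.ligand_heavy) == 0:
            raise ConfigurationError("no ligand heavy atoms in topology")
        if len(self.protein_heavy) == 0:
            raise ConfigurationError("no protein heavy atoms in topology")


@dataclass
class Trajectory:
    """Frames of Cartesian coordinates bound to a topology.

    coordinates: (F, N, 3) in Å; times: (F,) in ns, strictly increasing and
    equally spaced.
    """

    topology: Topology
    coordinates: np.ndarray
    times: np.ndarray

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise StructuralError("coordinates must have shape (F, N, 3)")
        if self.coordinates.shape[0] < 1:
            raise StructuralError("trajectory must contain at least one frame")
        if self.coordinates.shape[1] != self.topology.n_atoms:
            raise StructuralError(
                f"coordinate atom count {self.coordinates.shape[1]} != "
                f"topology atom count {self.topology.n_atoms}"
            )
        if not np.all(np.isfinite(self.coordinates)):
            raise StructuralError("coordinates contain non-finite values")
        if len(self.times) != self.coordinates.shape[0]:
            raise StructuralError("len(times) must equal number of frames")
        if len(self.times) > 1:
            dts = np.diff(self.times)
            if np.any(dts <= 0):
                raise StructuralError("times must be strictly increasing")
            if np.ptp(dts) > _EQUAL_SPACING_TOL_NS:
                raise StructuralError("frames must be equally spaced in time")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def frame_spacing(self) -> float:
        """Time between consecutive frames (ns); 0 for single-frame input."""
        if self.n_frames < 2:
            return 0.0
        return float(self.times[1] - self.times[0])

    def frame(self, index: int) -> np.ndarray:
        return self.coordinates[index]

    def window(self, t_start: float, t_end: float) -> "Trajectory":
        """Sub-trajectory with times in the half-open interval
        [t_start, t_end): a 0.05 ns window at 2e-5 ns spacing holds exactly
        2500 frames."""
        mask = (self.times >= t_start - 1e-12) & (self.times < t_end - 1e-12)
        if not mask.any():
            raise ConfigurationError(
                f"no frames in window [{t_start}, {t_end}] ns"
            )
        return replace(
            self, coordinates=self.coordinates[mask], times=self.times[mask]
        )


# ---------------------------------------------------------------------------
# structure / trajectory I/O (PDB via MDAnalysis; DCD/XTC for frames)
# ---------------------------------------------------------------------------

def _guess_element(name: str) -> str:
    """PDB fallback: element from the atom name when the element column is
    absent — strip digits, take the leading alphabetic character(s)."""
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        return "X"
    if len(stripped) >= 2 and stripped[:2].upper() in {"CL", "BR", "NA", "MG",
                                                       "ZN", "FE", "CA"}:
        # two-letter elements only when the name is exactly the element
        if stripped.upper() in {"CL", "BR", "NA", "MG", "ZN", "FE"}:
            return stripped.capitalize()
    return stripped[0].upper()


def _find_bad_pdb_line(path) -> int | None:
    """Locate the first malformed ATOM/HETATM record, for error reporting."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM", "HETATM")):
                try:
                    float(line[30:38])
                    float(line[38:46])
                    float(line[46:54])
                    int(line[22:26])
                except (ValueError, IndexError):
                    return lineno
    return None


def _assign_role(resname: str, ligand_resnames: frozenset[str]) -> str:
    rn = resname.strip().upper()
    if rn in ligand_resnames:
        return "ligand"
    if rn in WATER_RESNAMES:
        return "water"
    if rn in PROTEIN_RESNAMES:
        return "protein"
    return "other"


def read_structure(
    path, ligand_resnames=("LIG",)
) -> tuple[Topology, np.ndarray]:
    """Read a PDB file into a :class:`Topology` plus one coordinate frame.

    Parameters
    ----------
    path : str or Path
        PDB file.
    ligand_resnames : iterable of str or None
        Residue names treated as the ligand.  ``None`` disables the
        no-ligand-found check (topology-only uses).

    Returns
    -------
    (Topology, ndarray of shape (N, 3))
    """
    check_ligand = ligand_resnames is not None
    lig = frozenset(s.upper() for s in (ligand_resnames or ()))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path))
    except Exception as exc:  # MDAnalysis raises many types here
        raise ParseError(
            f"cannot parse PDB file {path}: {exc}",
            line_number=_find_bad_pdb_line(path),
        ) from exc

    try:
        elements = [str(e) for e in u.atoms.elements]
        if any(not e.strip() for e in elements):
            raise mda.exceptions.NoDataError("blank elements")
    except (mda.exceptions.NoDataError, AttributeError):
        elements = [_guess_element(n) for n in u.atoms.names]

    atoms = []
    for i, at in enumerate(u.atoms):
        elem = elements[i].strip().capitalize() or _guess_element(at.name)
        atoms.append(
            AtomRecord(
                atom_id=i,
                name=str(at.name),
                element=elem,
                is_hydrogen=elem.upper() == "H",
                residue_id=int(at.resid),
                residue_name=str(at.resname),
                role=_assign_role(str(at.resname), lig),
            )
        )
    topology = Topology(atoms)
    if check_ligand and not np.any(topology.roles == "ligand"):
        raise ConfigurationError(
            f"no residue matching ligand_resnames={sorted(lig)} in {path}"
        )
    coords = np.asarray(u.atoms.positions, dtype=float)
    return topology, coords


def write_structure(path, topology: Topology, coordinates: np.ndarray):
    """Write a single-frame PDB (fixture and restart support)."""
    coordinates = np.asarray(coordinates, dtype=float)
    u = mda.Universe.empty(
        topology.n_atoms,
        n_residues=len(np.unique(topology.residue_ids)),
        atom_resindex=np.unique(topology.residue_ids, return_inverse=True)[1],
        trajectory=True,
    )
    u.add_TopologyAttr("names", list(topology.names))
    u.add_TopologyAttr("elements", list(topology.elements))
    u.add_TopologyAttr(
        "resids", list(np.unique(topology.residue_ids))
    )
    resnames = []
    seen = set()
    for rid, rname in zip(topology.residue_ids, topology.residue_names):
        if rid not in seen:
            seen.add(rid)
            resnames.append(rname)
    u.add_TopologyAttr("resnames", resnames)
    u.atoms.positions = coordinates
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


def read_trajectory(
    path, topology: Topology, frame_spacing: float | None = None
) -> Trajectory:
    """Read DCD/XTC frames against an existing topology.

    Times come from ``frame_spacing`` (ns) when given, otherwise from the
    file header (converted from MDAnalysis' ps to ns).
    """
    u = mda.Universe.empty(topology.n_atoms, trajectory=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u.load_new(str(path))
    except ValueError as exc:
        msg = str(exc)
        if "atoms" in msg or "natoms" in msg:
            raise StructuralError(
                f"atom count in {path} does not match topology "
                f"({topology.n_atoms} atoms expected): {exc}"
            ) from exc
        raise
    frames = []
    n_good = 0
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for ts in u.trajectory:
                if ts.positions.shape[0] != topology.n_atoms:
                    raise StructuralError(
                        f"frame {n_good} has {ts.positions.shape[0]} atoms, "
                        f"topology has {topology.n_atoms}"
                    )
                frames.append(ts.positions.copy())
                n_good += 1
    except (EOFError, OSError) as exc:
        raise IOError(
            f"truncated trajectory {path}: last good frame {n_good - 1}"
        ) from exc
    coords = np.asarray(frames, dtype=float)
    if frame_spacing is not None:
        times = np.arange(len(frames)) * frame_spacing
    else:
        dt_ps = getattr(u.trajectory, "dt", 1.0) or 1.0
        times = np.arange(len(frames)) * (dt_ps / 1000.0)
    return Trajectory(topology=topology, coordinates=coords, times=times)


def write_trajectory(path, traj: Trajectory):
    """Write a DCD/XTC file (fixture support)."""
    u = mda.Universe.empty(traj.topology.n_atoms, trajectory=True)
    dt_ps = (traj.frame_spacing or 1e-3) * 1000.0
    u.load_new(
        traj.coordinates.astype(np.float32), format=MemoryReader, dt=dt_ps
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=traj.topology.n_atoms) as w:
            for ts in u.trajectory:
                w.write(u.atoms)


# ---------------------------------------------------------------------------
# superposition and RMSD
# ---------------------------------------------------------------------------

def _fit_rotation(mobile: np.ndarray, reference: np.ndarray):
    """Least-squares rigid-body fit of `mobile` onto `reference`.

    Returns (rotation matrix, mobile centroid, reference centroid) such that
    ``(x - mob_c) @ R.T + ref_c`` superposes any point set rigidly attached
    to `mobile`.
    """
    mob_c = mobile.mean(axis=0)
    ref_c = reference.mean(axis=0)
    a = mobile - mob_c
    b = reference - ref_c
    # collinear point sets leave a rotation axis undetermined
    s = np.linalg.svd(b, compute_uv=False)
    if len(b) < 3 or s[1] < 1e-8 * max(s[0], 1.0):
        raise GeometryError(
            "superposition selection must contain >= 3 non-collinear atoms"
        )
    rot, _ = Rotation.align_vectors(b, a)
    return rot.as_matrix(), mob_c, ref_c


def superpose_frames(
    traj: Trajectory,
    reference: np.ndarray,
    selection: Selection = Selection(role="protein", heavy_only=True),
) -> Trajectory:
    """Rigid-body superpose every frame onto `reference` coordinates.

    The optimal rotation/translation is fitted on the selection atoms and
    applied to all atoms of the frame.
    """
    idx = traj.topology.select(selection)
    if len(idx) < 3:
        raise GeometryError(
            f"selection resolves {len(idx)} atoms; need >= 3 for superposition"
        )
    ref_sel = np.asarray(reference, dtype=float)[idx]
    out = np.empty_like(traj.coordinates)
    for f in range(traj.n_frames):
        rmat, mob_c, ref_c = _fit_rotation(traj.coordinates[f][idx], ref_sel)
        out[f] = (traj.coordinates[f] - mob_c) @ rmat.T + ref_c
    return replace(traj, coordinates=out)


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain root-mean-square deviation between matched coordinate sets."""
    d = np.asarray(a, float) - np.asarray(b, float)
    return float(np.sqrt((d * d).sum(axis=1).mean()))


def ligand_rmsd(
    traj: Trajectory, frame_a: int, frame_b: int, superpose: bool = True
) -> float:
    """Ligand-heavy-atom RMSD between two frames (Å).

    Convention: frame_b is first superposed onto frame_a using the protein
    heavy atoms, then the RMSD is computed over ligand heavy atoms with no
    additional fitting — the ligand displacement is measured in the receptor
    frame.
    """
    lig = traj.topology.ligand_heavy
    if len(lig) == 0:
        raise ConfigurationError("no ligand heavy atoms for RMSD")
    ca = traj.coordinates[frame_a]
    cb = traj.coordinates[frame_b]
    if superpose:
        prot = traj.topology.protein_heavy
        rmat, mob_c, ref_c = _fit_rotation(cb[prot], ca[prot])
        cb = (cb - mob_c) @ rmat.T + ref_c
    return rmsd(ca[lig], cb[lig])
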