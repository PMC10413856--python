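"""Synthetic systems with known ground truth.

Three generators stand in for molecular-dynamics data:

* :func:`make_downhill_ensemble` — ensembles of overdamped-Langevin paths on
  a 1-D double well started at the saddle, wrapped as feature matrices in
  which a small planted subset of features tracks the reaction coordinate
  and the rest are pure noise.  The committor of any starting point is
  available in closed form, so classifier ensembles and importance metrics
  can be tested against ground truth.

* :func:`make_toy_receptor_trajectory` — pseudo-atom receptor/ligand/water
  frames in which designated ligand-protein (and water) distances follow
  Ornstein-Uhlenbeck processes with requested means, variances and
  relaxation times, while all other distances stay far beyond any cutoff.
  This gives exact control over pair-interaction occupancies.

* :func:`make_funnel_system` — a single-ligand funnel: a Gaussian binding
  well at the pocket, harmonic confinement to an exit axis, and a line of
  "channel" protein atoms the ligand passes on its way out, propagated by
  overdamped Langevin dynamics under the protocol's harmonic CV restraint.

All generators are deterministic per seed: identical specs and seeds give
bitwise-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import AtomRecord, Topology, Trajectory
from .cv import ProtocolConfig, RestraintSpec
from .errors import ConfigurationError, GenerationError
from .featurize import FeatureDescriptor, FeatureMatrix

KCAL_PER_KT = 0.593  # kT at ~298 K in kcal/mol, used by the funnel propagator


# ---------------------------------------------------------------------------
# topology builders
# ---------------------------------------------------------------------------

def build_toy_topology(
    n_protein: int, n_ligand: int, n_waters: int, atoms_per_residue: int = 4
) -> Topology:
    """Pseudo-atom topology: all-heavy protein residues, one ligand residue,
    single-site (oxygen-only) waters."""
    atoms = []
    aid = 0
    for i in range(n_protein):
        atoms.append(
            AtomRecord(
                atom_id=aid,
                name=f"C{i % atoms_per_residue + 1}",
                element="C",
                is_hydrogen=False,
                residue_id=i // atoms_per_residue + 1,
                residue_name="ALA",
                role="protein",
            )
        )
        aid += 1
    n_prot_res = (n_protein + atoms_per_residue - 1) // atoms_per_residue
    for j in range(n_ligand):
        atoms.append(
            AtomRecord(
                atom_id=aid,
                name=f"L{j + 1}",
                element="C",
                is_hydrogen=False,
                residue_id=n_prot_res + 1,
                residue_name="LIG",
                role="ligand",
            )
        )
        aid += 1
    for w in range(n_waters):
        atoms.append(
            AtomRecord(
                atom_id=aid,
                name="O",
                element="O",
                is_hydrogen=False,
                residue_id=n_prot_res + 2 + w,
                residue_name="HOH",
                role="water",
            )
        )
        aid += 1
    return Topology(atoms)


# ---------------------------------------------------------------------------
# 1-D double well with analytic committor
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DoubleWell:
    """V(x) = barrier * ((x/a)^2 - 1)^2 with minima at ±a and saddle at 0.

    The IN basin is at -a (ligand re-binds; distances shrink), the OUT basin
    at +a.  Energies are in kT units, lengths in Å.
    """

    barrier: float
    a: float
    kT: float = 1.0

    def potential(self, x):
        u = np.asarray(x, float) / self.a
        return self.barrier * (u * u - 1.0) ** 2

    def force(self, x):
        x = np.asarray(x, float)
        u = x / self.a
        return -4.0 * self.barrier * u * (u * u - 1.0) / self.a

    def committor(self, x: float) -> float:
        """Analytic probability of reaching +a before -a from x.

        p(x) = int_{-a}^{x} e^{V/kT} dy / int_{-a}^{a} e^{V/kT} dy.
        """
        if x <= -self.a:
            return 0.0
        if x >= self.a:
            return 1.0
        grid = np.linspace(-self.a, self.a, 20001)
        w = np.exp(self.potential(grid) / self.kT)
        cum = np.concatenate([[0.0], np.cumsum((w[1:] + w[:-1]) / 2.0)])
        total = cum[-1]
        return float(np.interp(x, grid, cum) / total)


@dataclass(frozen=True)
class ToySystemSpec:
    """Conditions of the synthetic downhill-committor system.

    The defaults define the study conditions used throughout the tests:
    an 8 kT barrier over a 2 Å basin separation with unit friction
    (diffusion coefficient 1 Å²/ns), 50 features of which 3 track the
    reaction coordinate with unit gain over N(0, 0.25 Å) noise, started at
    the saddle, mirroring an ensemble of ~150 trajectories with frames
    recorded every 2 ps.
    """

    barrier_height: float = 8.0       # kT
    basin_separation: float = 2.0     # Å between the two minima
    friction: float = 1.0             # 1/ns; diffusion D = kT/friction
    temperature_factor: float = 1.0   # kT
    dt: float = 0.001                 # ns, integration step
    n_features: int = 50
    informative_ids: tuple[int, ...] = (0, 1, 2)
    informative_gain: float = 1.0
    noise_sigma: float = 0.25         # Å
    seed: int = 0
    n_frames: int = 2500
    frame_spacing: float = 0.002      # ns between recorded frames
    start_position: float = 0.0       # Å along the reaction coordinate
    baseline_distance: float = 5.0    # Å offset so features look like distances
    max_extra_time: float = 50.0      # ns of unrecorded extension for labeling

    def __post_init__(self):
        if self.barrier_height <= 0:
            raise ConfigurationError("barrier_height must be positive")
        if self.basin_separation <= 0:
            raise ConfigurationError("basin_separation must be positive")
        if self.noise_sigma <= 0:
            raise ConfigurationError("noise_sigma must be positive")
        if self.informative_gain <= 0:
            raise ConfigurationError("informative_gain must be positive")
        bad = [i for i in self.informative_ids
               if not 0 <= i < self.n_features]
        if bad:
            raise ConfigurationError(
                f"informative_ids {bad} outside [0, {self.n_features})"
            )
        sub = self.frame_spacing / self.dt
        if abs(sub - round(sub)) > 1e-9 or round(sub) < 1:
            raise ConfigurationError(
                "frame_spacing must be a positive integer multiple of dt"
            )

    @property
    def well(self) -> DoubleWell:
        return DoubleWell(
            barrier=self.barrier_height,
            a=self.basin_separation / 2.0,
            kT=self.temperature_factor,
        )

    @property
    def diffusion(self) -> float:
        return self.temperature_factor / self.friction


@dataclass(frozen=True)
class GroundTruth:
    """What the generator planted: informative features, start committor
    (probability of OUT before IN from the start point), and the basin rule."""

    informative_ids: tuple[int, ...]
    start_committor: float
    basin_rule: str
    n_undecided: int = 0

    def __post_init__(self):
        if not 0.0 <= self.start_committor <= 1.0:
            raise ConfigurationError("committor must lie in [0, 1]")


def _step_overdamped(x, well: DoubleWell, D: float, dt: float, rng):
    """One Euler-Maruyama step of overdamped dynamics, vectorized."""
    drift = well.force(x) * (D / well.kT) * dt
    return x + drift + np.sqrt(2.0 * D * dt) * rng.standard_normal(x.shape)


def simulate_double_well_paths(
    spec: ToySystemSpec, n_traj: int, rng=None
) -> tuple[np.ndarray, np.ndarray]:
    """Reaction-coordinate paths and first-touch basin labels.

    Returns ``(paths, committed)`` where paths has shape (n_traj, n_frames)
    and committed is -1 (IN, reached -a first), +1 (OUT) or 0 (never
    committed within the recorded span plus ``max_extra_time``).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    well = spec.well
    a = well.a
    D = spec.diffusion
    substeps = int(round(spec.frame_spacing / spec.dt))
    x = np.full(n_traj, float(spec.start_position))
    committed = np.zeros(n_traj, dtype=np.int8)
    paths = np.empty((n_traj, spec.n_frames))
    paths[:, 0] = x
    for f in range(1, spec.n_frames):
        for _ in range(substeps):
            x = _step_overdamped(x, well, D, spec.dt, rng)
            fresh = committed == 0
            committed[fresh & (x <= -a)] = -1
            committed[fresh & (x >= a)] = 1
        paths[:, f] = x
    # extend (unrecorded) until everything commits or the extension budget
    # ends; commitment is first-touch, so it must be tested every step
    extra_steps = int(spec.max_extra_time / spec.dt)
    idx = np.flatnonzero(committed == 0)
    xp = x[idx]
    for _ in range(extra_steps):
        if idx.size == 0:
            break
        xp = _step_overdamped(xp, well, D, spec.dt, rng)
        hit_in = xp <= -a
        hit_out = xp >= a
        if hit_in.any() or hit_out.any():
            committed[idx[hit_in]] = -1
            committed[idx[hit_out]] = 1
            keep = ~(hit_in | hit_out)
            idx = idx[keep]
            xp = xp[keep]
    return paths, committed


def make_downhill_ensemble(
    spec: ToySystemSpec, n_traj: int = 150
) -> tuple[FeatureMatrix, np.ndarray, GroundTruth]:
    """Labeled feature ensemble with planted informative features.

    Informative features are ``baseline + gain * x(t) + N(0, sigma)``; the
    remaining features are ``baseline + N(0, sigma)`` pure noise.  The label
    is the basin reached first (IN at -a, OUT at +a).  Trajectories that
    never commit are dropped (and counted in the ground truth); if none
    commit a :class:`GenerationError` advises longer paths.
    """
    if n_traj < 10:
        raise ConfigurationError("need n_traj >= 10 for a usable ensemble")
    rng = np.random.default_rng(spec.seed)
    paths, committed = simulate_double_well_paths(spec, n_traj, rng)
    decided = committed != 0
    if not decided.any():
        raise GenerationError(
            "no trajectory committed to a basin; increase max_extra_time or "
            "n_frames (longer paths)"
        )
    labels = np.where(committed[decided] == -1, "IN", "OUT")
    x = paths[decided]
    n_dec, n_frames = x.shape
    values = spec.baseline_distance + spec.noise_sigma * rng.standard_normal(
        (n_dec, n_frames, spec.n_features)
    )
    for fid in spec.informative_ids:
        values[:, :, fid] += spec.informative_gain * x
    descriptors = tuple(
        FeatureDescriptor(
            kind="pair_distance",
            ligand_atom_id=0,
            protein_atom_id=d + 1,
            residue_id=d + 1,
        )
        for d in range(spec.n_features)
    )
    times = np.arange(n_frames) * spec.frame_spacing
    fm = FeatureMatrix(
        values=values, descriptors=descriptors, times=times, labels=labels
    )
    truth = GroundTruth(
        informative_ids=tuple(spec.informative_ids),
        start_committor=spec.well.committor(spec.start_position),
        basin_rule=(
            f"IN if x reaches -{spec.well.a:g} Å first, "
            f"OUT if +{spec.well.a:g} Å first"
        ),
        n_undecided=int(n_traj - n_dec),
    )
    return fm, labels, truth


def estimate_committor(
    spec: ToySystemSpec, x0: float, n_paths: int, seed: int = 0
) -> float:
    """Monte-Carlo committor: fraction of short paths from x0 reaching +a
    before -a (UNDECIDED paths excluded)."""
    rng = np.random.default_rng(seed)
    well = spec.well
    a = well.a
    x = np.full(n_paths, float(x0))
    committed = np.zeros(n_paths, dtype=np.int8)
    max_steps = int(spec.max_extra_time / spec.dt)
    for _ in range(max_steps):
        pending = committed == 0
        if not pending.any():
            break
        xp = _step_overdamped(x[pending], well, spec.diffusion, spec.dt, rng)
        x[pending] = xp
        idx = np.flatnonzero(pending)
        committed[idx[xp <= -a]] = -1
        committed[idx[xp >= a]] = 1
    decided = committed != 0
    if not decided.any():
        raise GenerationError("no committor path committed; longer paths needed")
    return float((committed[decided] == 1).mean())


def make_null_labels(labels, seed: int) -> np.ndarray:
    """Seed-deterministic permutation of the label multiset (null control)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ConfigurationError(
            "label shuffling needs at least two classes present"
        )
    rng = np.random.default_rng(seed)
    return labels[rng.permutation(len(labels))]


# ---------------------------------------------------------------------------
# committor windows along the toy path (TS bisection fixture)
# ---------------------------------------------------------------------------

def make_committor_windows(
    spec: ToySystemSpec,
    starts,
    n_shots: int = 50,
    seed: int = 0,
):
    """Candidate windows along the reaction coordinate with downhill shots.

    Each window fires ``n_shots`` unbiased paths from its start position and
    records the first-touch basin labels.  Window ids are 1-based in path
    order (IN side first).
    """
    from .downhill import CandidateWindow, OutcomeLabel

    windows = []
    for i, x0 in enumerate(starts):
        shot_spec = ToySystemSpec(
            **{
                **spec.__dict__,
                "start_position": float(x0),
                "seed": spec.seed + 1000 * (i + 1) + seed,
                "n_frames": 2,
            }
        )
        _, committed = simulate_double_well_paths(shot_spec, n_shots)
        labels = [
            OutcomeLabel.IN if c == -1
            else OutcomeLabel.OUT if c == 1
            else OutcomeLabel.UNDECIDED
            for c in committed
        ]
        windows.append(CandidateWindow(window_id=i + 1, labels=labels))
    return windows


# ---------------------------------------------------------------------------
# OU-distance receptor generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairDynamics:
    """One controlled ligand-protein distance: an OU process with the given
    stationary mean/sd and relaxation time."""

    ligand_atom: int      # index within the ligand atoms (0-based)
    protein_atom: int     # index within the protein atoms (0-based)
    mean: float           # Å
    sigma: float = 0.2    # Å, stationary standard deviation
    tau: float = 0.05     # ns, relaxation time

    def __post_init__(self):
        if self.mean <= 0:
            raise ConfigurationError("pair mean distance must be positive")
        if self.sigma <= 0 or self.tau <= 0:
            raise ConfigurationError("sigma and tau must be positive")


@dataclass(frozen=True)
class WaterDynamics:
    """One controlled water-anchor distance (anchor is a ligand or protein
    atom); same OU parameterization as :class:`PairDynamics`."""

    water_index: int
    anchor_role: str = "ligand"
    anchor_index: int = 0
    mean: float = 3.0
    sigma: float = 0.2
    tau: float = 0.05

    def __post_init__(self):
        if self.anchor_role not in ("ligand", "protein"):
            raise ConfigurationError("anchor_role must be ligand or protein")
        if self.mean <= 0 or self.sigma <= 0 or self.tau <= 0:
            raise ConfigurationError("mean, sigma, tau must be positive")


@dataclass(frozen=True)
class ReceptorSpec:
    """Pseudo-atom receptor system with controlled pair-distance dynamics."""

    n_protein_atoms: int = 20
    n_ligand_atoms: int = 4
    n_waters: int = 10
    pairs: tuple[PairDynamics, ...] = ()
    waters: tuple[WaterDynamics, ...] = ()
    frame_spacing: float = 0.01  # ns
    seed: int = 0

    def __post_init__(self):
        for name in ("n_protein_atoms", "n_ligand_atoms", "n_waters"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        seen = set()
        for p in self.pairs:
            if not 0 <= p.ligand_atom < self.n_ligand_atoms:
                raise ConfigurationError(
                    f"pair ligand_atom {p.ligand_atom} out of range"
                )
            if not 0 <= p.protein_atom < self.n_protein_atoms:
                raise ConfigurationError(
                    f"pair protein_atom {p.protein_atom} out of range"
                )
            if p.ligand_atom in seen:
                raise ConfigurationError(
                    f"ligand atom {p.ligand_atom} anchored by more than one pair"
                )
            seen.add(p.ligand_atom)
        for w in self.waters:
            if not 0 <= w.water_index < self.n_waters:
                raise ConfigurationError(
                    f"water_index {w.water_index} out of range"
                )
            limit = (
                self.n_ligand_atoms
                if w.anchor_role == "ligand"
                else self.n_protein_atoms
            )
            if not 0 <= w.anchor_index < limit:
                raise ConfigurationError(
                    f"water anchor_index {w.anchor_index} out of range"
                )


_GRID_SPACING = 20.0  # Å between protein base positions; beyond every cutoff


def _protein_base_positions(n: int) -> np.ndarray:
    idx = np.arange(n)
    return _GRID_SPACING * np.stack(
        [idx % 5, (idx // 5) % 5, idx // 25], axis=1
    ).astype(float)


def _ou_series(rng, n: int, mean: float, sigma: float, tau: float, dt: float):
    """Exact-discretization OU path, stationary initial condition."""
    rho = np.exp(-dt / tau)
    innov = sigma * np.sqrt(1.0 - rho * rho)
    x = np.empty(n)
    x[0] = mean + sigma * rng.standard_normal()
    noise = rng.standard_normal(n - 1)
    for k in range(1, n):
        x[k] = mean + rho * (x[k - 1] - mean) + innov * noise[k - 1]
    return np.maximum(x, 0.05)


def _random_unit(rng) -> np.ndarray:
    v = rng.standard_normal(3)
    return v / np.linalg.norm(v)


def make_toy_receptor_trajectory(
    spec: ReceptorSpec, n_frames: int
) -> Trajectory:
    """Receptor-ligand-water frames with controlled pair distances.

    Protein atoms sit on a fixed coarse grid (20 Å spacing, beyond every
    interaction cutoff).  Each controlled ligand atom rides an OU distance
    process along a fixed random direction from its protein anchor;
    controlled waters do the same relative to their anchor atom.  All
    uncontrolled atoms are parked far from everything.
    """
    if n_frames < 2:
        raise ConfigurationError("n_frames must be >= 2")
    rng = np.random.default_rng(spec.seed)
    top = build_toy_topology(
        spec.n_protein_atoms, spec.n_ligand_atoms, spec.n_waters
    )
    dt = spec.frame_spacing
    prot_base = _protein_base_positions(spec.n_protein_atoms)
    coords = np.zeros((n_frames, top.n_atoms, 3))
    coords[:, : spec.n_protein_atoms, :] = prot_base[None, :, :]

    lig_offset = spec.n_protein_atoms
    anchored = {p.ligand_atom: p for p in spec.pairs}
    for j in range(spec.n_ligand_atoms):
        ai = lig_offset + j
        if j in anchored:
            p = anchored[j]
            u = _random_unit(rng)
            r = _ou_series(rng, n_frames, p.mean, p.sigma, p.tau, dt)
            coords[:, ai, :] = prot_base[p.protein_atom] + r[:, None] * u
        else:
            coords[:, ai, :] = np.array([-60.0, -60.0, -60.0 - 20.0 * j])

    wat_offset = lig_offset + spec.n_ligand_atoms
    anchored_w = {w.water_index: w for w in spec.waters}
    for k in range(spec.n_waters):
        ai = wat_offset + k
        if k in anchored_w:
            w = anchored_w[k]
            u = _random_unit(rng)
            r = _ou_series(rng, n_frames, w.mean, w.sigma, w.tau, dt)
            if w.anchor_role == "ligand":
                anchor = coords[:, lig_offset + w.anchor_index, :]
            else:
                anchor = prot_base[w.anchor_index][None, :]
            coords[:, ai, :] = anchor + r[:, None] * u
        else:
            coords[:, ai, :] = np.array([150.0, 150.0, 150.0 + 20.0 * k])

    times = np.arange(n_frames) * dt
    return Trajectory(topology=top, coordinates=coords, times=times)


# ---------------------------------------------------------------------------
# funnel system + Langevin propagator for the unbinding protocol
# ---------------------------------------------------------------------------

class LangevinFunnelPropagator:
    """Overdamped Langevin dynamics of the ligand in a funnel.

    Forces (kcal/mol, Å): a Gaussian binding well at the pocket center, a
    harmonic confinement to the exit axis, a soft back wall behind the
    pocket, and — when a restraint is supplied — the harmonic CV bias
    ``0.5 * k * (CV - center)^2`` acting through every member pair.
    Protein and water atoms are held fixed.

    Satisfies the protocol's Propagator contract:
    ``propagator(coords, restraint_or_None, n_frames, seed) -> Trajectory``.
    """

    def __init__(
        self,
        topology: Topology,
        pocket_center=(0.0, 0.0, 0.0),
        axis=(1.0, 0.0, 0.0),
        well_depth: float = 4.0,    # kcal/mol
        well_width: float = 1.5,    # Å
        k_confine: float = 1.0,     # kcal/mol/Å^2 toward the axis
        k_wall: float = 5.0,        # kcal/mol/Å^2 behind the pocket
        wall_at: float = -1.0,      # Å along the axis
        kT: float = KCAL_PER_KT,
        diffusion: float = 1.0,     # Å^2/ns
        dt: float = 0.0005,         # ns
        record_stride: int = 10,
    ):
        self.topology = topology
        self.pocket_center = np.asarray(pocket_center, float)
        axis = np.asarray(axis, float)
        self.axis = axis / np.linalg.norm(axis)
        self.well_depth = well_depth
        self.well_width = well_width
        self.k_confine = k_confine
        self.k_wall = k_wall
        self.wall_at = wall_at
        self.kT = kT
        self.diffusion = diffusion
        self.dt = dt
        self.record_stride = record_stride
        self._lig = topology.ligand_heavy

    def _forces(self, lig_xyz: np.ndarray, frame: np.ndarray,
                restraint: RestraintSpec | None) -> np.ndarray:
        rel = lig_xyz - self.pocket_center
        w2 = self.well_width**2
        gauss = np.exp(-(rel * rel).sum(axis=1) / (2.0 * w2))
        f = -(self.well_depth / w2) * gauss[:, None] * rel
        s = rel @ self.axis
        perp = rel - s[:, None] * self.axis
        f -= self.k_confine * perp
        behind = s < self.wall_at
        f[behind] -= (
            self.k_wall * (s[behind] - self.wall_at)[:, None] * self.axis
        )
        if restraint is not None and restraint.pairs:
            pairs = np.asarray(restraint.pairs, int)
            diff = frame[pairs[:, 0]] - frame[pairs[:, 1]]
            d = np.linalg.norm(diff, axis=1)
            g = -restraint.force_constant * (d.sum() - restraint.center)
            lig_pos = {a: i for i, a in enumerate(self._lig)}
            for (la, _), dv, dd in zip(restraint.pairs, diff, d):
                if la in lig_pos and dd > 1e-9:
                    f[lig_pos[la]] += g * dv / dd
        return f

    def __call__(
        self,
        coordinates: np.ndarray,
        restraint: RestraintSpec | None,
        n_frames: int,
        seed: int,
    ) -> Trajectory:
        rng = np.random.default_rng(seed)
        frame = np.array(coordinates, float)
        lig = self._lig
        mobility = self.diffusion / self.kT
        noise_scale = np.sqrt(2.0 * self.diffusion * self.dt)
        out = np.empty((n_frames, self.topology.n_atoms, 3))
        out[0] = frame
        for f_idx in range(1, n_frames):
            for _ in range(self.record_stride):
                forces = self._forces(frame[lig], frame, restraint)
                frame[lig] += mobility * forces * self.dt
                frame[lig] += noise_scale * rng.standard_normal((len(lig), 3))
            out[f_idx] = frame
        times = np.arange(n_frames) * (self.dt * self.record_stride)
        return Trajectory(topology=self.topology, coordinates=out, times=times)


@dataclass
class FunnelSystem:
    """Bundled toy unbinding system: topology, an unrestrained initial
    segment for pair detection, the Langevin propagator, and a protocol
    configuration scaled to the funnel's geometry."""

    topology: Topology
    initial: Trajectory
    propagator: LangevinFunnelPropagator
    config: ProtocolConfig


#: pocket cage (4 atoms around the origin) then channel atoms along +x
_FUNNEL_PROTEIN_XYZ = np.array(
    [
        [0.0, 2.9, 0.0],
        [0.0, -2.9, 0.0],
        [0.0, 0.0, 2.9],
        [0.0, 0.0, -2.9],
        [5.0, 2.5, 0.0],
        [9.0, -2.5, 0.0],
        [13.0, 0.0, 2.5],
        [17.0, 0.0, -2.5],
    ]
)


def make_funnel_system(seed: int = 0) -> FunnelSystem:
    """The bundled funnel: one ligand atom caged by 4 pocket atoms, a line
    of channel atoms along the exit axis, and a protocol configuration whose
    per-pair center increment (0.5 Å) suits the funnel's ~10 Å exit."""
    top = build_toy_topology(n_protein=8, n_ligand=1, n_waters=1)
    coords = np.zeros((top.n_atoms, 3))
    coords[:8] = _FUNNEL_PROTEIN_XYZ
    coords[8] = [0.0, 0.0, 0.0]          # ligand at the pocket center
    coords[9] = [200.0, 200.0, 200.0]    # parked water (inert)
    config = ProtocolConfig(
        delta_per_pair=0.5,
        initial_detection_frames=150,
        iteration_frames=120,
        stop_displacement=10.0,
        seed=seed,
    )
    propagator = LangevinFunnelPropagator(top)
    initial = propagator(
        coords, None, config.initial_detection_frames, seed=seed
    )
    return FunnelSystem(
        topology=top, initial=initial, propagator=propagator, config=config
    )
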