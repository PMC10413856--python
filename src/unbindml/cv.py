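"""Adaptive interacting-pair collective variable and restraint protocol.

The unbinding CV is the sum of the distances of all currently "interacting"
ligand-protein heavy-atom pairs.  A pair is interacting when its distance is
below ``d_interact`` (default 3.5 Å) for strictly more than ``occ_threshold``
(default 50%) of a detection segment.  Between biased segments the pair
ledger is updated: newly interacting pairs join the CV, and pairs whose
segment-mean distance exceeds ``d_discard`` (default 11 Å) are dropped.  The
harmonic restraint ``0.5 * k * (CV - center)**2`` uses a force constant of
10 kcal mol^-1 Å^-2 by default, and the restraint center is monotonically
increased until the ligand is displaced from its initial position or the
iteration budget (default 25) is spent.

The center schedule is ``max(previous center, CV(current frame) +
delta_per_pair * n_active_pairs)``: the increment scales with the CV
dimension, and the max-clamp guarantees monotonicity.  The discard rule is
evaluated on the segment-*mean* pair distance, which is robust to
single-frame excursions; a discarded pair may be re-admitted later if it
qualifies again under the ordinary detection rule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Callable, Protocol

import numpy as np

from .core import Topology, Trajectory
from .errors import ConfigurationError, ParseError, ProtocolError


@dataclass(frozen=True)
class ProtocolConfig:
    """Tunable parameters of the adaptive unbinding protocol (Å, kcal/mol)."""

    d_interact: float = 3.5
    occ_threshold: float = 0.5
    d_discard: float = 11.0
    force_constant: float = 10.0
    max_iterations: int = 25
    delta_per_pair: float = 0.1
    initial_detection_frames: int = 200
    iteration_frames: int = 100
    stop_displacement: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.d_interact < self.d_discard:
            raise ConfigurationError(
                "need 0 < d_interact < d_discard "
                f"(got {self.d_interact}, {self.d_discard})"
            )
        if not 0 < self.occ_threshold < 1:
            raise ConfigurationError("occ_threshold must be in (0, 1)")
        if self.force_constant <= 0:
            raise ConfigurationError("force_constant must be positive")
        if self.max_iterations < 1:
            raise ConfigurationError("max_iterations must be >= 1")


@dataclass
class InteractionPair:
    """One ligand-protein heavy-atom pair in the CV ledger."""

    ligand_atom_id: int
    protein_atom_id: int
    occupancy: float
    iteration_added: int
    status: str = "active"
    discard_iteration: int | None = None

    def __post_init__(self):
        if self.status not in ("active", "discarded"):
            raise ConfigurationError(f"bad pair status {self.status!r}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ConfigurationError("occupancy must lie in [0, 1]")
        if self.status == "discarded" and self.discard_iteration is None:
            raise ConfigurationError(
                "discarded pair must record its discard_iteration"
            )

    @property
    def key(self) -> tuple[int, int]:
        return (self.ligand_atom_id, self.protein_atom_id)


@dataclass(frozen=True)
class UnbindingCV:
    """Sum-of-distances CV over an ordered set of interacting pairs."""

    pairs: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if len(set(self.pairs)) != len(self.pairs):
            raise ConfigurationError("duplicate pairs in CV")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class RestraintSpec:
    """Harmonic bias 0.5 * k * (CV - center)^2 on a distance-sum CV."""

    pairs: tuple[tuple[int, int], ...]
    center: float
    force_constant: float

    def __post_init__(self):
        if self.force_constant <= 0:
            raise ConfigurationError("force_constant must be positive")

    @property
    def cv(self) -> UnbindingCV:
        return UnbindingCV(pairs=self.pairs)


@dataclass
class ProtocolState:
    """Full history of an adaptive-CV run: pair ledger, centers, events."""

    iteration: int = 0
    center_history: list[float] = field(default_factory=list)
    ledger: dict[tuple[int, int], InteractionPair] = field(default_factory=dict)
    events: list[dict] = field(default_factory=list)
    segments: list[Trajectory] = field(default_factory=list)
    stop_reason: str | None = None

    def active_pairs(self) -> list[InteractionPair]:
        pairs = [p for p in self.ledger.values() if p.status == "active"]
        pairs.sort(key=lambda p: (p.iteration_added, p.key))
        return pairs

    def cv(self) -> UnbindingCV:
        return UnbindingCV(pairs=tuple(p.key for p in self.active_pairs()))

    def _log(self, event: str, pair: InteractionPair | None = None, **extra):
        record = {"event": event, "iteration": self.iteration, **extra}
        if pair is not None:
            record["pair"] = list(pair.key)
            record["occupancy"] = pair.occupancy
        self.events.append(record)

    def write_events(self, path):
        """Ledger log as JSON-lines, one record per pair event."""
        with open(path, "w") as fh:
            for record in self.events:
                fh.write(json.dumps(record) + "\n")


def replay_events(events: list[dict]) -> ProtocolState:
    """Reconstruct a ProtocolState's ledger/centers from its event log."""
    state = ProtocolState()
    for record in events:
        state.iteration = record["iteration"]
        if record["event"] == "pair_added":
            key = tuple(record["pair"])
            state.ledger[key] = InteractionPair(
                ligand_atom_id=key[0],
                protein_atom_id=key[1],
                occupancy=record["occupancy"],
                iteration_added=record["iteration"],
            )
        elif record["event"] == "pair_readmitted":
            key = tuple(record["pair"])
            pair = state.ledger[key]
            pair.status = "active"
            pair.discard_iteration = None
            pair.occupancy = record["occupancy"]
        elif record["event"] == "pair_discarded":
            key = tuple(record["pair"])
            pair = state.ledger[key]
            pair.status = "discarded"
            pair.discard_iteration = record["iteration"]
        elif record["event"] == "center_scheduled":
            state.center_history.append(record["center"])
        elif record["event"] == "stopped":
            state.stop_reason = record["reason"]
    return state


# ---------------------------------------------------------------------------
# distance kernels and pair detection
# ---------------------------------------------------------------------------

def interatomic_distances(traj: Trajectory, pairs) -> np.ndarray:
    """Per-frame Euclidean distances for a pair list; shape (F, P)."""
    pairs = np.asarray(list(pairs), dtype=int).reshape(-1, 2)
    n = traj.topology.n_atoms
    if pairs.size and (pairs.min() < 0 or pairs.max() >= n):
        raise IndexError(
            f"pair atom ids outside [0, {n}): "
            f"{pairs[(pairs < 0).any(1) | (pairs >= n).any(1)].tolist()}"
        )
    if pairs.size == 0:
        return np.zeros((traj.n_frames, 0))
    diff = traj.coordinates[:, pairs[:, 0], :] - traj.coordinates[:, pairs[:, 1], :]
    return np.sqrt((diff * diff).sum(axis=-1))


def detect_interacting_pairs(
    traj: Trajectory, config: ProtocolConfig = ProtocolConfig()
) -> list[InteractionPair]:
    """All ligand-heavy x protein-heavy pairs whose fraction of frames below
    ``d_interact`` strictly exceeds ``occ_threshold``."""
    top = traj.topology
    top.require_pipeline_atoms()
    if traj.n_frames < 2:
        raise ConfigurationError(
            "pair detection needs a trajectory segment of >= 2 frames"
        )
    lig = top.ligand_heavy
    prot = top.protein_heavy
    diff = (
        traj.coordinates[:, lig, None, :] - traj.coordinates[:, None, prot, :]
    )
    d = np.sqrt((diff * diff).sum(axis=-1))  # (F, L, P)
    occ = (d < config.d_interact).mean(axis=0)  # (L, P)
    found = []
    for i, j in np.argwhere(occ > config.occ_threshold):
        found.append(
            InteractionPair(
                ligand_atom_id=int(lig[i]),
                protein_atom_id=int(prot[j]),
                occupancy=float(occ[i, j]),
                iteration_added=0,
            )
        )
    found.sort(key=lambda p: p.key)
    return found


def cv_value(frame: np.ndarray, cv: UnbindingCV) -> float:
    """CV value on one coordinate frame: sum of member pair distances (Å)."""
    if cv.n_pairs == 0:
        return 0.0
    frame = np.asarray(frame, float)
    pairs = np.asarray(cv.pairs, dtype=int)
    diff = frame[pairs[:, 0]] - frame[pairs[:, 1]]
    return float(np.sqrt((diff * diff).sum(axis=1)).sum())


def cv_series(traj: Trajectory, cv: UnbindingCV) -> np.ndarray:
    """CV value on every frame of a trajectory."""
    if cv.n_pairs == 0:
        return np.zeros(traj.n_frames)
    return interatomic_distances(traj, cv.pairs).sum(axis=1)


# ---------------------------------------------------------------------------
# protocol bookkeeping
# ---------------------------------------------------------------------------

def update_cv_pairs(
    state: ProtocolState, segment: Trajectory, config: ProtocolConfig
) -> ProtocolState:
    """Ledger update after a biased segment: add newly interacting pairs,
    discard active pairs with segment-mean distance above ``d_discard``,
    re-admit previously discarded pairs that qualify again."""
    if segment.n_frames < 2:
        raise ProtocolError("cannot update the pair ledger on an empty segment")
    detected = {p.key: p for p in detect_interacting_pairs(segment, config)}
    for key, det in detected.items():
        existing = state.ledger.get(key)
        if existing is None:
            pair = InteractionPair(
                ligand_atom_id=key[0],
                protein_atom_id=key[1],
                occupancy=det.occupancy,
                iteration_added=state.iteration,
            )
            state.ledger[key] = pair
            state._log("pair_added", pair)
        elif existing.status == "discarded":
            existing.status = "active"
            existing.discard_iteration = None
            existing.occupancy = det.occupancy
            state._log("pair_readmitted", existing)
    active = state.active_pairs()
    if active:
        means = interatomic_distances(
            segment, [p.key for p in active]
        ).mean(axis=0)
        for pair, mean_d in zip(active, means):
            if mean_d > config.d_discard:
                pair.status = "discarded"
                pair.discard_iteration = state.iteration
                state._log("pair_discarded", pair, mean_distance=float(mean_d))
    return state


def next_center(
    state: ProtocolState, current_frame: np.ndarray, config: ProtocolConfig
) -> float:
    """Schedule the next restraint center.

    candidate = CV(current frame) + delta_per_pair * n_active_pairs;
    the returned center is clamped to be >= the previous one.
    """
    cv = state.cv()
    if cv.n_pairs == 0:
        raise ProtocolError("cannot schedule a center for an empty CV")
    candidate = cv_value(current_frame, cv) + config.delta_per_pair * cv.n_pairs
    if state.center_history:
        candidate = max(candidate, state.center_history[-1])
    state.center_history.append(candidate)
    state._log("center_scheduled", center=candidate, n_pairs=cv.n_pairs)
    return candidate


class Propagator(Protocol):
    """Contract for the dynamics backend used by the protocol loop."""

    def __call__(
        self,
        coordinates: np.ndarray,
        restraint: RestraintSpec | None,
        n_frames: int,
        seed: int,
    ) -> Trajectory: ...


def ligand_centroid_displacement(
    topology: Topology, frame: np.ndarray, reference_frame: np.ndarray
) -> float:
    lig = topology.ligand_heavy
    return float(
        np.linalg.norm(frame[lig].mean(axis=0) - reference_frame[lig].mean(axis=0))
    )


def run_unbinding_protocol(
    initial: Trajectory,
    propagator: Propagator,
    config: ProtocolConfig = ProtocolConfig(),
) -> tuple[ProtocolState, Trajectory]:
    """Iterate {update pairs -> schedule center -> restrain -> propagate}.

    Pair detection is seeded from the ``initial`` (unrestrained) trajectory;
    the loop then runs for at most ``max_iterations`` biased segments or
    until the ligand centroid is displaced by more than
    ``stop_displacement`` Å from its starting position.

    Returns the final state and the concatenation of all biased segments.
    """
    state = ProtocolState()
    start_frame = initial.frame(0)
    for pair in detect_interacting_pairs(initial, config):
        state.ledger[pair.key] = pair
        state._log("pair_added", pair)
    if not state.active_pairs():
        raise ConfigurationError(
            "no interacting pairs detected in the initial trajectory"
        )
    segments = []
    current = initial.frame(initial.n_frames - 1)
    for iteration in range(1, config.max_iterations + 1):
        state.iteration = iteration
        center = next_center(state, current, config)
        restraint = RestraintSpec(
            pairs=state.cv().pairs,
            center=center,
            force_constant=config.force_constant,
        )
        try:
            segment = propagator(
                current, restraint, config.iteration_frames,
                seed=config.seed + iteration,
            )
        except Exception as exc:
            raise ProtocolError(
                f"propagator failed at iteration {iteration}: {exc}"
            ) from exc
        segments.append(segment)
        state.segments.append(segment)
        update_cv_pairs(state, segment, config)
        current = segment.frame(segment.n_frames - 1)
        displacement = ligand_centroid_displacement(
            initial.topology, current, start_frame
        )
        state._log("iteration_done", displacement=float(displacement))
        if displacement > config.stop_displacement:
            state.stop_reason = "displacement"
            state._log("stopped", reason="displacement")
            break
        if not state.active_pairs():
            state.stop_reason = "no_active_pairs"
            state._log("stopped", reason="no_active_pairs")
            break
    else:
        state.stop_reason = "max_iterations"
        state._log("stopped", reason="max_iterations")
    coords = np.concatenate([s.coordinates for s in segments], axis=0)
    dt = segments[0].frame_spacing or 1e-3
    path = Trajectory(
        topology=initial.topology,
        coordinates=coords,
        times=np.arange(len(coords)) * dt,
    )
    return state, path


# ---------------------------------------------------------------------------
# colvars export (NAMD colvars dialect)
# ---------------------------------------------------------------------------

def export_colvars(spec: RestraintSpec, path):
    """Write a colvars configuration: one distance component per pair (the
    colvar sums its components) plus a harmonic bias.

    Atom ids are written 1-based (`atomNumbers`), matching the convention of
    MD engines; parsing the file back yields an equal RestraintSpec.
    """
    lines = ["colvar {", "    name unbinding_cv"]
    for lig, prot in spec.pairs:
        lines += [
            "    distance {",
            f"        group1 {{ atomNumbers {lig + 1} }}",
            f"        group2 {{ atomNumbers {prot + 1} }}",
            "    }",
        ]
    lines += [
        "}",
        "harmonic {",
        "    colvars unbinding_cv",
        f"    centers {spec.center!r}",
        f"    forceConstant {spec.force_constant!r}",
        "}",
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_colvars(path) -> RestraintSpec:
    """Parse a colvars file written by :func:`export_colvars`."""
    pairs = []
    center = None
    force_constant = None
    group: list[int] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if "atomNumbers" in line:
                tokens = line.replace("}", " ").split()
                try:
                    value = tokens[tokens.index("atomNumbers") + 1]
                    group.append(int(value) - 1)
                except (IndexError, ValueError) as exc:
                    raise ParseError(f"bad atomNumbers: {line!r}", lineno) from exc
                if len(group) == 2:
                    pairs.append((group[0], group[1]))
                    group = []
            elif line.startswith("centers"):
                center = float(line.split()[1])
            elif line.startswith("forceConstant"):
                force_constant = float(line.split()[1])
    if center is None or force_constant is None or not pairs:
        raise ParseError(f"incomplete colvars restraint file {path}")
    return RestraintSpec(
        pairs=tuple(pairs), center=center, force_constant=force_constant
    )
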