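"""Shared fixtures: all test data is generated programmatically."""

import numpy as np
import pytest

from unbindml import (
    PairDynamics,
    ReceptorSpec,
    ToySystemSpec,
    Topology,
    Trajectory,
    WaterDynamics,
    build_toy_topology,
    make_downhill_ensemble,
    make_toy_receptor_trajectory,
)

# desk-scale study conditions for the planted-signal ensemble: 8 kT saddle,
# 2 Å basin separation, D = 1 Å²/ns, frames every 5 ps
DESK_SPEC = dict(barrier_height=8.0, n_frames=45, frame_spacing=0.005, dt=0.001)


def desk_spec(seed=0, **overrides) -> ToySystemSpec:
    return ToySystemSpec(seed=seed, **{**DESK_SPEC, **overrides})


@pytest.fixture(scope="session")
def planted_ensemble():
    """150-trajectory planted-signal ensemble (3 informative / 50 features)."""
    fm, labels, truth = make_downhill_ensemble(desk_spec(seed=11), n_traj=150)
    return fm, labels, truth


def small_receptor_spec(seed=0, n_pairs=6) -> ReceptorSpec:
    """Receptor with controlled pairs straddling the 3.5 Å cutoff."""
    rng = np.random.default_rng(seed)
    pairs = tuple(
        PairDynamics(
            ligand_atom=j,
            protein_atom=int(rng.integers(0, 12)),
            mean=float(rng.uniform(2.8, 4.5)),
            sigma=0.4,
            tau=0.05,
        )
        for j in range(n_pairs)
    )
    return ReceptorSpec(
        n_protein_atoms=12,
        n_ligand_atoms=n_pairs,
        n_waters=10,
        pairs=pairs,
        waters=(
            WaterDynamics(water_index=0, anchor_role="ligand", mean=3.0),
            WaterDynamics(water_index=1, anchor_role="ligand", mean=4.5),
        ),
        seed=seed,
    )


@pytest.fixture()
def receptor_traj():
    return make_toy_receptor_trajectory(small_receptor_spec(seed=3), n_frames=80)


def manual_trajectory(coords_per_frame, topology=None, spacing=0.01):
    """Trajectory from an explicit (F, N, 3) array, default 1-ligand topology."""
    coords = np.asarray(coords_per_frame, float)
    if topology is None:
        n = coords.shape[1]
        topology = build_toy_topology(
            n_protein=n - 1, n_ligand=1, n_waters=1
        )
        # append a parked water column to match the topology
        water = np.full((coords.shape[0], 1, 3), 500.0)
        coords = np.concatenate([coords, water], axis=1)
    times = np.arange(coords.shape[0]) * spacing
    return Trajectory(topology=topology, coordinates=coords, times=times)
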