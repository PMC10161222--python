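import numpy as np
import pytest

from fcscreen import (
    DiffusionComponent,
    FcsModelParams,
    SimulationConfig,
    SpeciesSpec,
)


@pytest.fixture()
def one_component_params():
    return FcsModelParams(
        n_particles=2.0,
        components=(DiffusionComponent(1.0, 2e-4),),
        triplet_fraction=0.1,
        triplet_time=4e-6,
        structure_parameter=5.0,
    )


@pytest.fixture()
def two_component_params():
    return FcsModelParams(
        n_particles=5.0,
        components=(
            DiffusionComponent(0.6, 1e-4),
            DiffusionComponent(0.4, 3e-3),
        ),
        triplet_fraction=0.0,
        structure_parameter=5.0,
    )


@pytest.fixture()
def lag_grid():
    return np.geomspace(1e-6, 1.0, 73)


@pytest.fixture()
def fast_sim_config():
    """Small single-species recording that simulates in ~1 s."""
    species = SpeciesSpec(
        label="monomer",
        diffusion_coefficient=15.0,  # um^2/s -> tau_D ~ 1 ms at w0 = 0.25 um
        mean_copies=3.0,
        brightness=(4e4,),
    )
    return SimulationConfig(
        species=(species,),
        bin_time=1e-4,
        duration=8.0,
        lateral_radius=0.25,
        axial_radius=1.25,
    )


def random_valid_params(rng: np.random.Generator) -> FcsModelParams:
    """Draw a random valid model parameter set (shared property-test helper)."""
    n_comp = rng.integers(1, 3)
    taus = np.sort(10 ** rng.uniform(-5, -1.5, n_comp))
    if n_comp == 1:
        comps = (DiffusionComponent(1.0, float(taus[0])),)
    else:
        f1 = float(rng.uniform(0.05, 0.95))
        comps = (
            DiffusionComponent(f1, float(taus[0])),
            DiffusionComponent(1.0 - f1, float(taus[1])),
        )
    return FcsModelParams(
        n_particles=float(10 ** rng.uniform(-1, 2)),
        components=comps,
        triplet_fraction=float(rng.uniform(0.0, 0.4)),
        triplet_time=float(10 ** rng.uniform(-6.5, -5.8)),
        structure_parameter=float(rng.uniform(3.0, 8.0)),
    )
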