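import numpy as np
import pandas as pd
import pytest

from carboxysome.config import PoseSimConfig, QuantSimConfig
from carboxysome.simulate import (simulate_carboxysome,
                                  simulate_peptide_quant,
                                  simulate_population)
from carboxysome.spatial import summarize_population
from carboxysome.stoichiometry import reference_composition

POPULATION_SEED = 7
POPULATION_N = 200


@pytest.fixture(scope="session")
def noiseless_config() -> PoseSimConfig:
    return PoseSimConfig(diameter_sd_nm=0.0, position_jitter_sd_A=0.0,
                         orientation_noise_sd_deg=0.0, seed=2)


@pytest.fixture(scope="session")
def noiseless_carboxysome(noiseless_config):
    return simulate_carboxysome(noiseless_config, 169.0, seed=2)


@pytest.fixture(scope="session")
def population():
    """200 carboxysomes at the default study conditions, fixed seed."""
    return simulate_population(POPULATION_N, PoseSimConfig(seed=POPULATION_SEED))


@pytest.fixture(scope="session")
def population_summary(population):
    poses, _ = population
    return summarize_population(poses)


@pytest.fixture(scope="session")
def reference() -> pd.DataFrame:
    return reference_composition().set_index("protein")


@pytest.fixture(scope="session")
def true_copies(reference) -> dict[str, float]:
    return dict(reference["monomer_copies"].astype(float))


@pytest.fixture(scope="session")
def quant_noiseless(true_copies) -> pd.DataFrame:
    return simulate_peptide_quant(
        QuantSimConfig(true_monomer_copies=true_copies, noise_cv=0.0,
                       seed=11))


@pytest.fixture(scope="session")
def quant_noisy(true_copies) -> pd.DataFrame:
    return simulate_peptide_quant(
        QuantSimConfig(true_monomer_copies=true_copies, noise_cv=0.2,
                       n_replicates=4, seed=11))


def rigid_transform(poses: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Apply one random rotation + translation to a whole pose table."""
    from scipy.spatial.transform import Rotation

    rng = np.random.default_rng(seed)
    rot = Rotation.random(rng=rng)
    shift = rng.uniform(-1e4, 1e4, 3)
    out = poses.copy()
    xyz = poses[["x_A", "y_A", "z_A"]].to_numpy()
    out[["x_A", "y_A", "z_A"]] = rot.apply(xyz) + shift
    part = Rotation.from_euler(
        "ZYZ", poses[["rot_deg", "tilt_deg", "psi_deg"]].to_numpy(),
        degrees=True)
    out[["rot_deg", "tilt_deg", "psi_deg"]] = \
        (rot * part).as_euler("ZYZ", degrees=True)
    return out
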