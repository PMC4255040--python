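import numpy as np
import pytest

from npbilayer.model import Box, Frame, SiteRecord, Topology, Trajectory
from npbilayer.synth import GeneratorConfig, generate_trajectory


def point_trajectory(points, box=(10.0, 10.0, 10.0), molecule_type="SOL",
                     site_name="OW", mass=18.015, times=(0.0,)):
    """Trajectory of independent single-site molecules at fixed positions."""
    points = np.asarray(points, dtype=float)
    sites = [SiteRecord(i, molecule_type, site_name, mass) for i in range(len(points))]
    topo = Topology(sites)
    frames = [Frame(t, points.copy(), Box(*box)) for t in times]
    return Trajectory(topo, frames)


@pytest.fixture(scope="session")
def flat_bilayer():
    """Small reference bilayer: no nanoparticle, no noise, chains upright."""
    cfg = GeneratorConfig(
        n_lipids_per_leaflet=16,
        n_frames=3,
        dt=0.5,
        seed=11,
        np_radius=None,
        tilt_mean_cos2={"SR": 1.0, "BUFFER": 1.0, "LR": 1.0},
        z_fluctuation_sigma=0.0,
        d_lateral={"SR": 0.0, "BUFFER": 0.0, "LR": 0.0},
        water_number_density=0.0,
    )
    traj, truth = generate_trajectory(cfg)
    return traj, truth, cfg


@pytest.fixture(scope="session")
def np_system():
    """Bilayer with an embedded 1-nm gold particle and waters."""
    cfg = GeneratorConfig(
        n_lipids_per_leaflet=64,
        n_frames=21,
        dt=0.5,
        seed=4,
        np_radius=1.0,
        np_z_start=0.5,  # particle penetrated into the upper leaflet
        water_number_density=3.0,
        cluster_waters_near_np=15,
    )
    traj, truth = generate_trajectory(cfg)
    return traj, truth, cfg
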