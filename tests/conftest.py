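import numpy as np
import pytest

from polysite import resources
from polysite.rigid_geometry import Pose, matrix_to_euler
from polysite.star_io import ParticleRecord, ParticleSet
from polysite.synthetic_fields import Scenario, simulate_field

APIX = 2.17


@pytest.fixture(scope="session")
def sites():
    return resources.default_sites()


@pytest.fixture(scope="session")
def envelope():
    return resources.default_envelope()

@pytest.fixture(scope="session")
def pstalk_envelope():
    return resources.default_envelope("ribosome_80s_pstalk")


@pytest.fixture(scope="session")
def pose_library():
    return resources.default_pose_library()


def particle_set_from_poses(poses, tomo_ids=None, labels=None, apix=APIX):
    """Build a ParticleSet directly from world-frame poses."""
    n = len(poses)
    tomo_ids = tomo_ids if tomo_ids is not None else ["tomo_001"] * n
    records = []
    for i, pose in enumerate(poses):
        rot, tilt, psi = matrix_to_euler(pose.R.T)
        records.append(
            ParticleRecord(
                particle_id=f"p{i:05d}",
                tomogram_id=tomo_ids[i],
                coord_vox=pose.position / apix,
                origin_shift=np.zeros(3),
                euler_deg=(rot, tilt, psi),
                pixel_size=apix,
                class_label=None if labels is None else labels[i],
            )
        )
    return ParticleSet(records, metadata={"pixel_size": apix, "tomogram_column": "rlnTomoName"})


def random_poses(rng, n, box=4000.0):
    from scipy.spatial.transform import Rotation

    pos = rng.uniform(0, box, size=(n, 3))
    rots = Rotation.random(n, rng=rng).as_matrix()
    return [Pose(p, R) for p, R in zip(pos, rots)]


@pytest.fixture(scope="session")
def mixed_field_noise_free():
    """Mixed monosome/loose/collided/helical field without pose noise."""
    sc = Scenario(
        fractions={"loose": 0.3, "collided": 0.3, "helical": 0.2},
        pose_noise=(0.0, 0.0),
        n_tomograms=3,
        particles_per_tomogram=250,
        seed=5,
    )
    return simulate_field(sc)


@pytest.fixture(scope="session")
def mixed_field_noisy():
    """Same composition with the reference noise setting (10 Å, 5 deg)."""
    sc = Scenario(
        fractions={"loose": 0.3, "collided": 0.3, "helical": 0.2},
        pose_noise=(10.0, 5.0),
        n_tomograms=3,
        particles_per_tomogram=250,
        seed=6,
    )
    return simulate_field(sc)
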