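import numpy as np
import pytest

from arustrain import (AtlasGrid, CameraIntrinsics, SessionConfig,
                       build_dictionary)
from arustrain.synthetic import (MarkerTrack, SceneScript, make_pose,
                                 render_scene)


@pytest.fixture(scope="session")
def dictionary():
    return build_dictionary(n_ids=50, grid_size=4, min_hamming=3, seed=0)


@pytest.fixture(scope="session")
def small_dictionary():
    # small enough for exhaustive pairwise / bit-flip enumeration
    return build_dictionary(n_ids=8, grid_size=4, min_hamming=3, seed=7)


@pytest.fixture(scope="session")
def intrinsics():
    return CameraIntrinsics(fx=600.0, fy=600.0, cx=320.0, cy=240.0,
                            image_size=(640, 480))


@pytest.fixture(scope="session")
def session_config():
    return SessionConfig()


@pytest.fixture(scope="session")
def tilt_corpus(dictionary, intrinsics):
    """30 single-marker frames, tilt <= 45 deg, marker >= 80 px, flat bg."""
    rng = np.random.default_rng(11)
    frames, truths, ids = [], [], []
    for k in range(30):
        marker_id = int(rng.integers(0, 50))
        pose = make_pose(tilt_deg=float(rng.uniform(0, 45)),
                         spin_deg=float(rng.uniform(0, 360)),
                         azimuth_deg=float(rng.uniform(0, 360)),
                         position=(float(rng.uniform(-0.05, 0.05)),
                                   float(rng.uniform(-0.04, 0.04)),
                                   float(rng.uniform(0.30, 0.42))))
        script = SceneScript(intrinsics=intrinsics, image_size=(640, 480),
                             tracks=(MarkerTrack(marker_id, 0.05, (pose,)),),
                             n_frames=1, background="flat", seed=k)
        fs, ts = render_scene(script, dictionary)
        frames.append(fs[0])
        truths.append(ts[0])
        ids.append(marker_id)
    return frames, truths, ids


@pytest.fixture(scope="session")
def default_grid():
    return AtlasGrid()
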