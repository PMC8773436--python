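import warnings

import numpy as np
import pytest

from fireflash.behavior import classify_behavior, link_tracks
from fireflash.spot_detect import DetectionParams, detect_sequence
from fireflash.synth import (
    IndividualSpec,
    SceneSpec,
    flying_profile,
    perching_profile,
    simulate_scene,
)

# detection settings used for per-frame scene analysis (no decimation, with
# duplicate merging): each ~0.2 s flash spans several frames at 30 fps
PER_FRAME_DETECTION = dict(decimation_factor=1, merge_duplicates=True,
                           merge_radius_px=8.0)


@pytest.fixture(scope="session")
def mixed_scene():
    """A rendered 20 s scene: 3 flying A. cerata + 5 perching males, seed 1."""
    spec = SceneSpec(
        duration=20.0, fps=30.0, width=640, height=480, seed=1,
        individuals=[
            IndividualSpec(profile=flying_profile("A. cerata"), behavior="flying")
            for _ in range(3)
        ] + [
            IndividualSpec(profile=perching_profile(), behavior="perching")
            for _ in range(5)
        ],
    )
    seq, truth = simulate_scene(spec)
    return seq, truth


@pytest.fixture(scope="session")
def mixed_scene_tracks(mixed_scene):
    """Spots and classified tracks of the mixed scene."""
    seq, truth = mixed_scene
    spots = detect_sequence(seq, DetectionParams(**PER_FRAME_DETECTION))
    tracks = link_tracks(spots)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for tr in tracks:
            classify_behavior(tr)
    return spots, tracks


def truth_owner_of(spot_row, truth, max_dt=0.3):
    """Ground-truth individual whose nearest flash explains a detected spot."""
    best = (np.inf, None)
    for i, ind in enumerate(truth.individuals):
        for k, t in enumerate(ind.flash_times):
            if abs(t - spot_row.t_s) < max_dt:
                d = np.hypot(ind.flash_centers[k, 0] - spot_row.x_px,
                             ind.flash_centers[k, 1] - spot_row.y_px)
                if d < best[0]:
                    best = (d, i)
    return best[1]
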