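import numpy as np
import pytest

from fociquant.io import Channel, SemanticMask
from fociquant.synth import SceneSpec, generate_scene
from fociquant.zstack import select_focus_plane


@pytest.fixture(scope="session")
def default_scene():
    """One irradiated desk-scale scene shared by read-only tests."""
    return generate_scene(SceneSpec(seed=7, dose_Gy=5))


@pytest.fixture(scope="session")
def small_scene_pairs():
    """(dapi plane, gt nuclei mask) pairs from tiny 64×64 scenes for fast training tests."""
    pairs = []
    for seed in range(8):
        scene = generate_scene(
            SceneSpec(seed=seed, height_px=64, width_px=64, n_nuclei=1, dose_Gy=5,
                      extranuclear_speckle_rate=2.0)
        )
        _, plane = select_focus_plane(scene.dapi)
        mask = SemanticMask((scene.gt_nuclei.raster > 0).astype(np.uint8), scene.gt_nuclei.pixel_size_um)
        pairs.append((plane, mask))
    return pairs


def gt_nuclei_mask(scene) -> SemanticMask:
    return SemanticMask((scene.gt_nuclei.raster > 0).astype(np.uint8), scene.gt_nuclei.pixel_size_um)
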