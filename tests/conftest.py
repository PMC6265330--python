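import numpy as np
import pytest

import dropletlab as dl


@pytest.fixture()
def shell_droplet_scene():
    """One noiseless droplet with a channel-1-enriched shell (factor 1.3)."""
    scene = dl.SceneSpec(
        image_shape=(101, 101),
        droplets=(
            dl.DropletSpec(
                center_xy=(50.0, 50.0),
                radius=20.0,
                channel_amplitudes=(800.0, 600.0),
                shell_factor_per_channel=(1.3, 1.0),
                shell_width_fraction=0.15,
            ),
        ),
    )
    img, truth = dl.make_droplet_image(scene)
    return scene, img, truth


@pytest.fixture()
def three_disk_scene():
    """Three well-separated plain disks above the detection threshold."""
    droplets = tuple(
        dl.DropletSpec(center_xy=c, radius=r, channel_amplitudes=(a, a / 2))
        for c, r, a in [
            ((35.0, 40.0), 14.0, 1000.0),
            ((110.0, 38.0), 11.0, 950.0),
            ((70.0, 105.0), 16.0, 900.0),
        ]
    )
    scene = dl.SceneSpec(image_shape=(150, 150), droplets=droplets, background_level=20.0)
    img, truth = dl.make_droplet_image(scene)
    return scene, img, truth


@pytest.fixture()
def bead_image():
    return dl.make_bead_image((101, 101), bead_radius=20.0, amplitudes=(2.0, 1.0))
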