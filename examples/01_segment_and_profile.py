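"""Segment a two-channel droplet scene and profile its core-shell architecture.

Builds a synthetic droplet whose channel-1 protein is enriched 1.3x in an
outer shell, detects it, and measures the radial ratio profile.  The shell
enrichment statistic near 1.3 confirms the analyzer recovers the generator's
architecture; a uniform bead run through the same chain stays at 1.0.
"""

import numpy as np

import dropletlab as dl

scene = dl.SceneSpec(
    image_shape=(101, 101),
    droplets=(
        dl.DropletSpec(
            center_xy=(50.0, 50.0), radius=20.0,
            channel_amplitudes=(800.0, 600.0),
            shell_factor_per_channel=(1.3, 1.0),
            shell_width_fraction=0.15,
        ),
    ),
    pixel_size_um=0.1,
)
img, truth = dl.make_droplet_image(scene)

regions = dl.segment_scene(img)
r = regions[0]
print(f"detected {len(regions)} droplet(s)")
print(f"  center = ({r.center_xy[0]:.1f}, {r.center_xy[1]:.1f}) px "
      f"(truth: {truth['center_x'][0]:.0f}, {truth['center_y'][0]:.0f})")
print(f"  radius = {r.radius_px:.2f} px (truth: {truth['radius_px'][0]:.0f}), "
      f"circularity = {r.circularity:.3f}")

profile = dl.radial_profile(img, r, n_radii=30)
enrichment = dl.shell_enrichment(profile)
print(f"  shell enrichment = {enrichment:.3f} (generator truth: 1.3)")

bead = dl.make_bead_image((101, 101), bead_radius=20.0, amplitudes=(2.0, 1.0))
bead_region = dl.segment_scene(bead)[0]
bead_enrichment = dl.shell_enrichment(dl.radial_profile(bead, bead_region))
print(f"  bead control enrichment = {bead_enrichment:.3f} (flat ratio => 1.0)")
print("values > 1 flag a channel-1-rich boundary layer; the bead rules out "
      "chromatic artifacts")
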