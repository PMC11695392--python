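"""Fourier first-harmonic parametric images of a scarred phantom.

Fits f(t) = A0 + A1*sin(wt + P1) to every pixel's intensity series and
compares the amplitude map FA inside and outside the scar sector: reduced
wall motion means reduced videointensity modulation, hence lower FA.
"""

import math

import numpy as np

from cinescar import PhantomConfig, fourier_images, generate_loop
from cinescar.io import myocardium_mask

cfg = PhantomConfig(
    grid_size=64, n_frames=30, center=(32.0, 32.0), r_endo_ed=12.0,
    wall_thickness_ed=6.0, contraction_fraction=0.25,
    scar_present=True, scar_sector=(0.0, math.pi / 2), scar_motion_ratio=0.1,
)
loop, contours, label = generate_loop(cfg)
fa, fp = fourier_images(loop)

myo = myocardium_mask(contours, 0, loop.shape)
rows, cols = np.mgrid[0:64, 0:64]
theta = np.mod(np.arctan2(rows - 32.0, cols - 32.0), 2 * math.pi)
in_sector = theta < math.pi / 2

scar_fa = fa.data[myo & in_sector].mean()
remote_fa = fa.data[myo & ~in_sector].mean()
print(f"slice label:            {label}")
print(f"mean FA, scar sector:   {scar_fa:8.3f}")
print(f"mean FA, remote wall:   {remote_fa:8.3f}")
print(f"scar / remote ratio:    {scar_fa / remote_fa:8.3f}")
# The ratio is well below 1: the first-harmonic amplitude image separates
# the hypokinetic sector from normally contracting myocardium.
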