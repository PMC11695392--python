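"""Monogenic ED-ES difference images of a scarred phantom.

Band-passes the end-diastolic and end-systolic frames with a log-Gabor
filter, builds the Riesz quadrature pair, and prints sector statistics of
the amplitude-difference map MA = A_ED - A_ES: myocardium that barely
deforms between ED and ES changes its local structure less.
"""

import math

import numpy as np

from cinescar import (
    PhantomConfig,
    build_filters,
    generate_loop,
    monogenic_diff,
    select_ed_frame,
    select_es_frame,
)
from cinescar.io import myocardium_mask

cfg = PhantomConfig(
    grid_size=64, n_frames=30, center=(32.0, 32.0), r_endo_ed=12.0,
    wall_thickness_ed=6.0, contraction_fraction=0.25,
    scar_present=True, scar_sector=(0.0, math.pi / 2), scar_motion_ratio=0.1,
)
loop, contours, _ = generate_loop(cfg)
ed = select_ed_frame(loop, contours)
es = select_es_frame(loop, contours)
filters = build_filters(loop.shape, wavelength=8.0, sigma_on_f=0.5)
diff = monogenic_diff(loop.frames[ed], loop.frames[es], filters)

myo = myocardium_mask(contours, ed, loop.shape)
rows, cols = np.mgrid[0:64, 0:64]
theta = np.mod(np.arctan2(rows - 32.0, cols - 32.0), 2 * math.pi)
in_sector = theta < math.pi / 2

print(f"ED frame {ed}, ES frame {es}")
print(f"mean |MA|, scar sector: {np.abs(diff.ma.data)[myo & in_sector].mean():8.3f}")
print(f"mean |MA|, remote wall: {np.abs(diff.ma.data)[myo & ~in_sector].mean():8.3f}")
print(f"MP range: [{diff.mp.data.min():.3f}, {diff.mp.data.max():.3f}] rad")
# |MA| is smaller over the scar sector: less deformation between the two
# cardiac phases leaves the local band-pass structure nearly unchanged.
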