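"""Depth refocusing and extended depth of field from one acquisition.

Two beads sit at -4 um and +4 um.  A single view-partitioned acquisition
is refocused through a depth sweep using the linear shear-to-depth
calibration; the all-in-focus composite picks each pixel's sharpest depth.
The printed depth map readings at the bead centers should recover the
true depths.
"""

import numpy as np

import lifttomo as lt

N = 48
geom = lt.build_view_plan(K=5, Ntheta=N, image_size_N=N)
cal = lt.ShearCalibration(slope=0.8, intercept=0.0, valid_range=(-20, 20))

yy, xx = np.meshgrid(np.arange(N), np.arange(N), indexing="ij")
bead_a = (((yy - 14) ** 2 + (xx - 14) ** 2) <= 4).astype(float)
bead_b = (((yy - 34) ** 2 + (xx - 32) ** 2) <= 4).astype(float)
sino = lt.forward_sinogram([(bead_a, cal.shear_of(-4.0)),
                            (bead_b, cal.shear_of(+4.0))], geom)

depths = np.arange(-8.0, 8.1, 2.0)
stack = lt.depth_sweep(sino, geom, cal, depths)
edof, depth_map = lt.all_in_focus(stack)

print(f"swept {len(depths)} depths from {depths[0]} to {depths[-1]} um")
print(f"depth map at bead A center (true -4 um): {depth_map[14, 14]:+.1f} um")
print(f"depth map at bead B center (true +4 um): {depth_map[34, 32]:+.1f} um")
print("The EDOF image keeps both beads sharp even though no single "
      "refocus depth can; the depth map is the per-pixel argmax of the "
      "sum-of-modified-Laplacian focus measure.")
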