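"""Calibrate the four-camera rig from a bead field and triangulate a point.

The DLT maps tunnel coordinates to pixels with 11 linear parameters per
camera; triangulation inverts it across cameras by least squares.
"""

import numpy as np

from escapeflight import (default_rig, fit_dlt, generate_calibration_field,
                          project, triangulate)

rig = default_rig()
field = generate_calibration_field(rig, n_beads=30, seed=0, pixel_noise_sd=0.5)

dlts = []
for ci in range(len(rig.cameras)):
    dlt = fit_dlt(field.positions, field.pixels[ci], camera_id=f"cam{ci}")
    dlts.append(dlt)
    print(f"cam{ci}: reprojection RMSE {dlt.reprojection_rmse:.3f} px "
          f"from {dlt.n_points_used} beads")

rng = np.random.default_rng(1)
point = np.array([0.05, -0.03, 0.55])   # metres, tunnel frame
pixels = [project(d, point) + rng.normal(0, 0.5, 2) for d in dlts]
recovered, residuals = triangulate(dlts, pixels)

print(f"\ntrue point      : {point}")
print(f"triangulated    : {np.round(recovered, 5)}")
print(f"3D error        : {1000 * np.linalg.norm(recovered - point):.2f} mm")
print(f"pixel residuals : {np.round(residuals, 2)} px")
print("\nWith 0.5 px tracking noise the four-camera solution is good to "
      "well under a millimetre.")
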