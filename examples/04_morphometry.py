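"""The four morphometric measures on correspondences with known answers.

det J is the local areal ratio, logS the log deformation tensor (zero for any
rigid motion), and R the distance to the medial axis of iso-parameter slice
centroids ("thickness").
"""

import numpy as np

from surfmorph import compute_morphometry, parameterize, tube_mesh

tube = tube_mesh(radius=3.0, length=12.0, n_axial=30, n_circ=24)
param = parameterize(tube)

vm = compute_morphometry(param, tube.vertices.copy())
print("identity correspondence:"
      f"  detJ = {vm.detJ.mean():.6f}, |logS| = {np.abs(vm.logS).max():.2e},"
      f" R = {vm.R.mean():.3f} mm (tube radius 3)")

vm2 = compute_morphometry(param, 2.0 * tube.vertices)
print("doubled in size:        "
      f"  detJ = {vm2.detJ.mean():.6f} (area x4), R = {vm2.R.mean():.3f} mm")

th = 0.7
rot = np.array([[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0],
                [0, 0, 1.0]])
vm3 = compute_morphometry(param, tube.vertices @ rot.T)
print("rigidly rotated copy:   "
      f"  detJ = {vm3.detJ.mean():.6f}, |logS| = {np.abs(vm3.logS).max():.2e}"
      " (rigid motion leaves the deformation tensor at zero)")
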