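"""Recover a whisker's hidden pivot point from its (rho, theta) trace.

A whisker rotating about a fixed point R behind the snout line obeys
rho = L_f * cot(theta) + rho_f, so an ordinary least-squares line in
(cot(theta), rho) space yields the pivot depth L_f and foot rho_f.
"""

import numpy as np

from whiskertrack import estimate_pivot
from whiskertrack.synthetic import benchmark_scene, generate_scene

_, truth = generate_scene(benchmark_scene(n_frames=500))

for k in (0, 5, 9):
    rho = truth.params[:, k, 0]
    theta = truth.params[:, k, 1]
    est = estimate_pivot(rho, theta)
    rho_f, L_f = truth.pivots[k]
    print(
        f"whisker {k}: pivot foot rho_f={est.rho_f:7.2f} (true {rho_f:5.1f}), "
        f"depth L_f={est.L_f:6.2f} (true {L_f:4.1f}), r^2={est.r2:.4f}"
    )
print("the pivot sits below the snout line and is never imaged; recovering")
print("it from the angle sweep is what lets the recogniser use cot(theta)")
print("as a stable per-whisker signature.")
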