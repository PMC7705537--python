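"""Fit the four-parameter whisker description {rho, theta, b, L}.

Samples a known quadratic whisker, jitters the points, and recovers the
parameters with the nonlinear least-squares fit.
"""

import numpy as np

from whiskertrack import SnoutLine, WhiskerParams, fit_whisker, whisker_curve

snout = SnoutLine((0.0, 300.0), (400.0, 300.0))
true = WhiskerParams(rho=80.0, theta=1.2, b=0.004, length=120.0)

rng = np.random.default_rng(0)
points = whisker_curve(true, snout, 60) + rng.normal(0, 0.2, (60, 2))
fit = fit_whisker(points, snout)

print("true  : rho=80.00  theta=1.2000  b=0.00400  L=120.00")
print(
    f"fitted: rho={fit.rho:.2f}  theta={fit.theta:.4f}  "
    f"b={fit.b:.5f}  L={fit.length:.2f}  (rss={fit.rss:.2f} px^2)"
)
print("rho is the base position along the snout line, theta the angle of")
print("emergence, b the quadratic bending (d = b x^2 off the chord) and L")
print("the straight base-to-tip span; 0.2 px of point jitter moves the")
print("recovered angle by well under a hundredth of a radian.")
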