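"""Classify Y/T antibody shapes from Fab latitude angles.

Builds a toy hinge-linked antibody whose two Fab arms follow a known
(T, Y, asym) = (0.3, 0.5, 0.2) mixture, recomputes the per-frame (theta,
phi) angles in the Fc-anchored frame, and classifies each frame with the
85-degree latitude threshold.
"""

import numpy as np

from mabshape import SyntheticSpec, classify_shape, compute_fab_angles, generate_toy_mab

toy = generate_toy_mab(SyntheticSpec(seed=42, n_frames=5000))
angles = compute_fab_angles(toy.xyz, toy.groups)
call = classify_shape(angles, threshold=85.0)

print(f"frames analyzed:        {len(angles)}")
print(f"both Fabs theta >= 85 (T): {call.fraction_t:6.1%}   planted 30.0%")
print(f"both Fabs theta <  85 (Y): {call.fraction_y:6.1%}   planted 50.0%")
print(f"mixed (asym):              {call.fraction_asym:6.1%}   planted 20.0%")
print(f"per-Fab T fraction:        {call.per_fab_fraction_t[0]:.1%} / "
      f"{call.per_fab_fraction_t[1]:.1%}")
err = np.max(np.abs(angles.theta1 - toy.truth.theta1.values))
print(f"max theta recovery error:  {err:.2e} deg")
# The fractions recover the planted mixture to binomial accuracy, and the
# angle error shows the Fc-frame construction is exact on rigid toys.
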