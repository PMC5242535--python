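"""Design-based stereology on a synthetic section stack.

Applies the Cavalieri point-counting estimator to an analytic ellipsoid
and the optical fractionator to a stack with a known number of planted
neurons; both should land near the ground truth, with the Gundersen CE
describing the sampling precision.
"""
import math

import numpy as np

from neuropheno.stereology import (
    STRIATUM_DESIGN,
    CavalieriDesign,
    cavalieri_volume,
    dissector_height,
    gundersen_ce,
    optical_fractionator,
    sample_cavalieri_ellipsoid,
    sample_fractionator_counts,
)
from neuropheno.synthetic import random_histo_truth

rng = np.random.default_rng(0)

semi = (400.0, 600.0, 500.0)  # um
true_v = 4 / 3 * math.pi * semi[0] * semi[1] * semi[2] * 1e-9
design = CavalieriDesign(area_per_point_um2=60.0**2, section_period_um=150.0)
sampled = sample_cavalieri_ellipsoid(semi, design, rng)
ce = gundersen_ce([c for c in sampled.point_counts if c > 0])
print(f"Cavalieri: estimate {cavalieri_volume(sampled):.3f} mm^3, "
      f"truth {true_v:.3f} mm^3, CE {ce:.3f}")

print(f"\noptical fractionator: frame 65x35 um, dissector "
      f"{dissector_height(18.0, 0.5):.0f} um")
truth = random_histo_truth(40, 250, (1500.0, 1500.0), seed=8,
                           non_overlapping=False)
q, per_section = sample_fractionator_counts(truth, STRIATUM_DESIGN, rng)
print(f"sparse striatal design (grid 400x400 um, ssf 1/10): Q- = {q}, "
      f"N = {optical_fractionator(STRIATUM_DESIGN, q):.0f} "
      f"(planted {len(truth.neuron_coords)}; a single sparse draw is noisy)")

from neuropheno.stereology import FractionatorDesign

dense = FractionatorDesign(0.2, (65.0, 35.0), (100.0, 100.0), 18.0, 0.5)
est, ces = [], []
for _ in range(25):
    q, per_sec = sample_fractionator_counts(truth, dense, rng)
    est.append(optical_fractionator(dense, q))
    ces.append(gundersen_ce(per_sec))
print(f"dense design (grid 100x100 um, ssf 1/5): mean N over 25 draws = "
      f"{np.mean(est):.0f}, mean CE = {np.mean(ces):.3f}")
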