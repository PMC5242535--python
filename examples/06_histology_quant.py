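"""Two-level immunoreactivity quantification and cortical thickness.

Renders an aggregate-stained section with nuclear (dense) and diffuse
inclusion classes, thresholds it at the two darkness levels (90 nuclear /
130 total under the transmitted-light orientation), and measures a wedge
cortex with the vertical-line ruler.
"""
import numpy as np

from neuropheno.histo_quant import (
    ThicknessRuler,
    ThresholdPair,
    cortical_thickness,
    two_level_quantification,
)
from neuropheno.synthetic import generate_sections, random_histo_truth

truth = random_histo_truth(1, 0, (800.0, 800.0), inclusions_per_section=40,
                           nuclear_fraction=0.5, seed=7)
section = generate_sections(truth, pixel_size_um=2.0)[0]
res = two_level_quantification(section, ThresholdPair(nuclear=90, total=130))
nuc_true = 100.0 * section.annotations["nuclear_mask"].mean()
tot_true = 100.0 * (section.annotations["nuclear_mask"]
                    | section.annotations["diffuse_mask"]).mean()
print(f"nuclear immunoreactive area {res['nuclear_pct']:.2f}% "
      f"(ground truth {nuc_true:.2f}%)")
print(f"total   immunoreactive area {res['total_pct']:.2f}% "
      f"(ground truth {tot_true:.2f}%)")

# cortical thickness: 10 vertical lines between two boundary polylines
xs = np.linspace(0, 1000, 200)
callosal = np.column_stack([xs, np.zeros_like(xs)])        # inner boundary
pial = np.column_stack([xs, 800 + 0.4 * xs])               # outer boundary
mean_um, excluded = cortical_thickness(callosal, pial, ThicknessRuler(n_lines=10))
print(f"\nwedge cortex mean thickness {mean_um:.0f} um "
      f"(analytic mid-thickness 1000 um, {excluded} lines excluded)")
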