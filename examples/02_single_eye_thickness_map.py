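"""Map choroidal thickness for one synthetic eye, end to end.

Generates a low-myopia eye, renders its OCT volume (speckle + motion),
runs motion correction, boundary segmentation, fovea localisation and
normal-distance thickness mapping, then prints the nine-sector summary
and the 1-mm nasal-temporal ring profile next to the ground truth.
"""

import numpy as np

import choroidmap as cm
from choroidmap.pipeline import analyze_volume

spec = cm.default_cohort_spec()
truth = cm.make_eye_truth(spec.groups["low"], "OD", seed=123)
volume, _ = cm.render_volume(truth, cm.RenderParams(), seed=5)

analysis = analyze_volume(volume, qc_dual_operator=False)

print(f"fovea (estimated) : ({analysis.ctmap.fovea_xy_mm[0]:+.2f}, "
      f"{analysis.ctmap.fovea_xy_mm[1]:+.2f}) mm")
print(f"fovea (truth)     : ({truth.fovea_xy_mm[0]:+.2f}, "
      f"{truth.fovea_xy_mm[1]:+.2f}) mm")
print()
print(f"{'sector':<7}{'measured um':>12}{'truth um':>10}")
for s in ("Fovea", "NIM", "SIM", "TIM", "IIM", "NOM", "SOM", "TOM", "IOM"):
    print(f"{s:<7}{analysis.sectors.mean_um[s]:>12.1f}"
          f"{truth.sector_ct_um[s]:>10.1f}")
print()
print("ring profile (nasal -5 mm ... temporal +5 mm), um:")
print(np.round(analysis.profile.mean_um, 1))
print()
print("Measured sector means track the drawn ground truth to a few um;")
print("superior/inferior outer sectors are truncated by the 10 x 5 mm scan.")
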