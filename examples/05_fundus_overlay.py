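"""Render the geographic CT map onto an en-face fundus projection.

The fundus image is the per-(x, y) maximum intensity over depth; the
nine sectors are coloured on a fixed CT scale with a scale-bar strip.
Writes out/fundus_overlay.png.
"""

from pathlib import Path

import choroidmap as cm
from choroidmap.cohort_stats import render_ct_map
from choroidmap.pipeline import analyze_volume

spec = cm.default_cohort_spec()
truth = cm.make_eye_truth(spec.groups["moderate"], "OD", seed=9)
volume, _ = cm.render_volume(truth, cm.RenderParams(), seed=3)
analysis = analyze_volume(volume, qc_dual_operator=False)

out = Path("out")
out.mkdir(exist_ok=True)
img = render_ct_map(volume, analysis.ctmap, analysis.sectors,
                    path=out / "fundus_overlay.png")
print(f"wrote {out / 'fundus_overlay.png'} ({img.shape[0]}x{img.shape[1]} px)")
print("Warm colours = thicker choroid; the scale strip spans 0-400 um.")
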