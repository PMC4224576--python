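"""Bilayer thickness by leaflet-surface interpolation.

The ordered (Lo) phase packs thicker than the disordered (Ld) phase.  This
example plants a striped bilayer with phosphate-to-phosphate separations of
45 Å (Lo) and 36 Å (Ld), reconstructs both leaflet surfaces by cubic
interpolation of the phosphate z-coordinates, and reports the per-phase
thickness means — plus a PNG thickness map if you want to look at it.
"""

from pathlib import Path

import phasemap as pm
from phasemap import viz

frame, truth = pm.striped_frame(box=(300.0, 300.0), stripe_width=90.0,
                                seed=2, x0=75.0)
analysis = pm.analyze_frame(frame)
stats = analysis.thickness_stats

print(f"planted Lo / Ld separations : {truth.lo_separation} / "
      f"{truth.ld_separation} Å")
for cat in ("both_lo", "both_ld", "mismatch", "global"):
    if cat in stats:
        s = stats[cat]
        print(f"{cat:>8}: mean {s['mean']:.2f} Å over {s['fraction']:.1%} "
              "of the bilayer")
print("The global mean hides the ~9 Å Lo-Ld difference; the per-category")
print("means recover the planted separations to a few tenths of an Å.")

out = Path("example_output")
out.mkdir(exist_ok=True)
viz.save_thickness_png(analysis.thickness, out / "thickness.png")
print(f"thickness map written to {out / 'thickness.png'}")
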