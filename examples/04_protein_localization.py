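"""Classifying proteins as Lo, Ld or interfacial from their footprints.

Each protein is a 20 Å Gaussian footprint on the phase mask of its own
leaflet: >80% of the footprint in one phase assigns that phase, anything
else is interfacial.  Proteins are planted at known positions (3 deep in
Lo, 1 deep in Ld, 6 on the interface, per leaflet) and the classifier's
counts are compared with the plant.
"""

from collections import Counter

import phasemap as pm

frame, truth = pm.striped_frame(box=(300.0, 300.0), stripe_width=100.0,
                                seed=3, x0=60.0)
frame, truth = pm.place_proteins(
    frame, truth, placement={"Lo": 3, "Ld": 1, "interface": 6}, seed=3)
analysis = pm.analyze_frame(frame, with_thickness=False)

for leaflet in ("upper", "lower"):
    records = [r for r in analysis.protein_records if r.leaflet == leaflet]
    counts = Counter(r.label for r in records)
    print(f"{leaflet:>5} leaflet: {dict(counts)}")
    for r in records:
        planted = truth.protein_labels[r.protein_id]
        print(f"   protein {r.protein_id}: f_Lo = {r.f_lo:.2f} -> {r.label:<12}"
              f" (planted {planted})")
print("Footprints straddling an interface keep 20-80% of each phase and are")
print("interfacial; recovery of the planted labels is exact by construction.")
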