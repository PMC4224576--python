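"""Interface detection and length measurement on a striped bilayer.

Generates a phase-separated frame with one 120 Å-wide Ld stripe (known
interface length: two box-spanning edges, 800 Å), runs the pipeline and
compares the measured interface length and Ld area fraction against the
planted geometry.
"""

import phasemap as pm

frame, truth = pm.striped_frame(box=(400.0, 400.0), stripe_width=120.0,
                                seed=1, x0=100.0)
analysis = pm.analyze_frame(frame, with_thickness=False, with_proteins=False)

print(f"true interface length   : {truth.interface_length:.0f} Å")
print(f"true Ld area fraction   : {truth.ld_area_fraction:.3f}")
for _, row in analysis.rows.iterrows():
    print(f"{row.leaflet:>5} leaflet: measured length "
          f"{row.interface_length:.0f} Å, Ld fraction "
          f"{row.ld_area_fraction:.3f}, {row.n_domains} domains")
print("The edge-pixel sum measures axis-aligned interfaces essentially")
print("exactly; density shot noise and the interfacial mixing band add a")
print("few percent of boundary wiggle.")
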