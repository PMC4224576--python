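"""Inter-leaflet phase mismatch of a freshly mixed bilayer.

Builds a randomly mixed 400 Å bilayer (3000 lipids per leaflet, 5:3:2
DPPC:DUPC:CHOL), runs the density -> mean-threshold mask pipeline on both
leaflets and reports how much of the bilayer area is in different phases on
the two sides.  Because the two leaflets are statistically independent and
each is ~half Ld by construction of the mean threshold, the expected
mismatch is 2 p (1 - p) ~ 50% — the starting point any phase-separating
trajectory decays from as the leaflets couple.
"""

import phasemap as pm

frame, _ = pm.random_mixed_frame(box=(400.0, 400.0), seed=0)
analysis = pm.analyze_frame(frame, with_thickness=False, with_proteins=False)

row = analysis.rows.iloc[0]
print(f"lipids per leaflet   : {row.n_lipids}")
print(f"kernel width         : {row.lipid_sigma:.2f} Å (derived from box/count)")
print(f"Ld area fraction     : {row.ld_area_fraction:.3f} per leaflet")
print(f"leaflet mismatch     : {100 * row.mismatch_fraction:.1f} % of the bilayer area")
print("A fully mixed bilayer sits near 50 %: the leaflets' apparent domains")
print("are uncorrelated noise. Coupled, phase-separated bilayers fall well below.")
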