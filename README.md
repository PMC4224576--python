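# phasemap

Image-processing analysis of phase-separating coarse-grained lipid bilayers.

Ternary lipid mixtures such as DPPC : DUPC : cholesterol (5 : 3 : 2) undergo
spinodal decomposition into liquid-ordered (Lo, saturated-lipid- and
cholesterol-rich, thick) and liquid-disordered (Ld, unsaturated-lipid-rich,
thin) phases. Quantifying that process from coarse-grained molecular-dynamics
trajectories — how long the Lo/Ld interface is, how big the domains are, how
strongly the two leaflets couple, how thick each phase is, and where
lipid-anchored proteins such as NRas sit — is awkward in Cartesian
coordinates but straightforward once the bilayer is treated as an image.
`phasemap` is a library (plus a thin CLI) for exactly that, aimed at people
analysing MARTINI-scale bilayer simulations.

## Method

Per frame and leaflet, working on a grid of 1 × 1 Å pixels:

1. **Rasterize** one marker per molecule — the PO4 bead (DPPC, DUPC), the ROH
   bead (cholesterol), or the centre of mass (protein) — into a count grid.
2. **Smooth** with a periodic, unit-integral Gaussian. The lipid width comes
   from an equal-area argument: σ = √(A/(nπ)), the radius of a circle holding
   one lipid's share of the leaflet area A (σ = 4.1 Å for n = 3000 in a
   400 Å box). Proteins use σ = 20 Å.
3. **Mask** the phases: Ld is every pixel where ρ(DUPC) − ρ(DPPC) exceeds the
   mean of that difference field, strictly; the rest is Lo.
4. **Detect the interface** with a periodic Canny edge detector (smoothing
   σ = 2 Å); the interface length is the edge-pixel count × 1 Å. Domains are
   8-connected components merged across the periodic seams, each with
   equivalent radius √(area/π).
5. **Couple the leaflets**: pixels are both-Lo, both-Ld or mismatched; the
   mismatch fraction tracks inter-leaflet domain registration over time.
6. **Thickness**: cubic (Clough–Tocher) interpolation of the phosphate
   z-coordinates gives each leaflet surface; their difference is the
   phosphate-to-phosphate thickness, reported per match category.
7. **Proteins**: a protein belongs to a phase if its 20 Å Gaussian footprint
   holds > 80 % of that phase; otherwise it is interfacial.
8. **Kinetics**: interface length and mean domain radius form time series;
   coarsening follows L(t) ∼ t^α, fitted by least squares in log–log space.

A ground-truthed synthetic generator (`phasemap.synthetic`) builds marker-bead
bilayers — randomly mixed, striped, circular-domain, or coarsening series with
an imposed exponent — with planted interface lengths, area fractions,
per-phase thicknesses (45 / 36 Å defaults) and protein labels, so every stage
is testable without running MD.

## Worked example

```python
import phasemap as pm

frame, truth = pm.striped_frame(box=(400, 400), stripe_width=120, seed=1, x0=100)
fa = pm.analyze_frame(frame)
print(fa.rows[["leaflet", "ld_area_fraction", "interface_length"]])
print({k: round(v["mean"], 2) for k, v in fa.thickness_stats.items()})
```

prints (seed 1):

```
  leaflet  ld_area_fraction  interface_length
0   upper          0.312             818.0
1   lower          0.313             831.0
{'both_lo': 44.96, 'both_ld': 36.13, 'mismatch': 43.66, 'global': 42.21}
```

The planted stripe covers 0.30 of the box with an 800 Å interface; the
measured Ld fraction (≈ 0.31) and length (≈ 820 Å) carry the mean-threshold
boundary shift and a few percent of noise wiggle. The per-category thickness
means recover the planted 45 / 36 Å separations to ≈ 0.1 Å while the global
mean (≈ 42 Å) hides the difference — which is why the per-phase numbers
matter. The `examples/` directory has one short script per capability
(mismatch of a mixed bilayer, interface length, thickness maps, protein
classification, coarsening fits), each printing the numbers it computes and
what they mean.

A command-line front-end covers the same pipeline for shell use:

```bash
phasemap synth stripe -o stripe.gro --box 400 400 --seed 1
phasemap analyze stripe.gro -o out/          # frames.csv, config.json, PNGs
phasemap kinetics out/frames.csv -o fits.csv
phasemap report --condition-a a.csv --condition-b b.csv -o summary.csv
```

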