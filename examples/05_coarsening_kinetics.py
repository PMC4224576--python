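"""Measuring a domain-growth exponent from a synthetic coarsening series.

Spinodal decomposition grows domains as L(t) ~ t^alpha.  This example
generates a series whose true characteristic length follows alpha = 0.5,
measures the mean Ld domain radius per frame through the full pipeline, and
fits the exponent back in log-log space.
"""

import numpy as np

import phasemap as pm

frames, truths = pm.coarsening_series(alpha=0.5, n_frames=10, seed=4)

times, radii = [], []
for frame, truth in zip(frames, truths):
    fa = pm.analyze_frame(frame, with_thickness=False, with_proteins=False)
    r = []
    for leaflet in ("upper", "lower"):
        try:
            r.append(pm.mean_domain_radius(fa.domains[leaflet],
                                           phases=("Ld",)))
        except ValueError:
            pass
    times.append(truth.time_us)
    radii.append(np.mean(r))
    print(f"t = {truth.time_us:5.2f} µs: true radius "
          f"{truth.characteristic_length:5.1f} Å, measured {np.mean(r):5.1f} Å")

series = pm.MetricSeries(times=np.array(times), values=np.array(radii),
                         metric="mean_domain_radius")
fit = pm.fit_power_law(series)
print(f"\nfitted exponent alpha = {fit.alpha:.3f} (imposed 0.5), "
      f"r² = {fit.r_squared:.3f}")
print("Pixelation and the mean-threshold bias add ~2 Å to every radius,")
print("flattening the fit slightly; the imposed exponent is recovered to")
print("within a few hundredths.")
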