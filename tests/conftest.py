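"""Shared fixtures: generated reference frames analysed once per session."""

from __future__ import annotations

import numpy as np
import pytest

import phasemap as pm


@pytest.fixture(scope="session")
def stripe_frame_and_truth():
    """A 400 Å box with a straight 120 Å Ld stripe (Lo 45 / Ld 36 Å)."""
    return pm.striped_frame(box=(400.0, 400.0), stripe_width=120.0,
                            seed=20, x0=100.0)


@pytest.fixture(scope="session")
def stripe_analysis(stripe_frame_and_truth):
    frame, _ = stripe_frame_and_truth
    return pm.analyze_frame(frame)


@pytest.fixture(scope="session")
def stripe_proteins_analysis():
    """Stripe frame with planted proteins: 3 Lo, 1 Ld, 6 interfacial/leaflet."""
    frame, truth = pm.striped_frame(box=(300.0, 300.0), stripe_width=100.0,
                                    seed=21, x0=60.0)
    frame, truth = pm.place_proteins(
        frame, truth, placement={"Lo": 3, "Ld": 1, "interface": 6}, seed=21)
    return pm.analyze_frame(frame, with_thickness=False), truth


@pytest.fixture(scope="session")
def mixed_frame_and_truth():
    """A small randomly mixed bilayer (no phases)."""
    return pm.random_mixed_frame(box=(200.0, 200.0), seed=22)


def measure_coarsening(alpha: float, seed: int, **kwargs):
    """Pipeline-measured radius and interface-length series (µs, Å) for one
    synthetic coarsening run; phases-only analysis, leaflet-averaged."""
    frames, truths = pm.coarsening_series(alpha=alpha, seed=seed, **kwargs)
    times, radii, lengths = [], [], []
    for frame, truth in zip(frames, truths):
        fa = pm.analyze_frame(frame, with_thickness=False, with_proteins=False)
        r_leaflets = []
        for leaflet in ("upper", "lower"):
            try:
                r_leaflets.append(pm.mean_domain_radius(fa.domains[leaflet],
                                                        phases=("Ld",)))
            except ValueError:
                pass
        if not r_leaflets:
            continue
        times.append(truth.time_us)
        radii.append(float(np.mean(r_leaflets)))
        lengths.append(float(fa.rows["interface_length"].mean()))
    t = np.asarray(times)
    return (pm.MetricSeries(times=t, values=np.asarray(radii), metric="radius"),
            pm.MetricSeries(times=t, values=np.asarray(lengths),
                            metric="interface_length"))


@pytest.fixture(scope="session")
def coarsening_measured():
    """Measured series for three seeds at the default growth exponent 0.5."""
    return [measure_coarsening(0.5, seed) for seed in (1, 2, 3)]
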