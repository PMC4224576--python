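"""Synthetic bilayer generators and their ground truth."""

import math

import numpy as np
import pytest

import phasemap as pm
from phasemap.synthetic import stripe_arc_length


class TestComposition:
    def test_reference_scaling_is_exact_at_3000(self):
        comp = pm.CompositionSpec.from_total(3000)
        assert (comp.n_dppc, comp.n_dupc, comp.n_chol) == (1502, 900, 598)

    def test_largest_remainder_preserves_total(self):
        for total in (10, 757, 1500, 2999):
            counts = pm.largest_remainder([751, 450, 299], total)
            assert sum(counts) == total

    def test_dppc_fraction_of_phospholipids_is_five_eighths(self):
        comp = pm.CompositionSpec()
        assert comp.dppc_fraction_of_phospholipids == pytest.approx(
            751 / 1201)
        assert abs(comp.dppc_fraction_of_phospholipids - 5 / 8) < 1e-3

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            pm.CompositionSpec(n_dppc=-1)


class TestSystemBeads:
    def test_solvated_reference_system_total(self):
        assert pm.count_system_beads(3004, 1800, 1196,
                                     n_water=65984, n_na=2016,
                                     n_cl=2016) == 137232

    def test_waters_only(self):
        assert pm.count_system_beads(0, 0, 0, n_water=10) == 10

    def test_linearity(self):
        one = pm.count_system_beads(10, 20, 30, n_water=40, n_na=5, n_cl=5)
        two = pm.count_system_beads(20, 40, 60, n_water=80, n_na=10, n_cl=10)
        assert two == 2 * one


class TestPoissonDisk:
    def test_minimum_distance_respected_under_periodicity(self):
        rng = np.random.default_rng(0)
        pts = pm.poisson_disk_sample(300, (100.0, 100.0), 4.0, rng)
        d = np.abs(pts[:, None, :] - pts[None, :, :])
        d = np.minimum(d, 100.0 - d)
        dist = np.hypot(d[..., 0], d[..., 1])
        np.fill_diagonal(dist, np.inf)
        assert dist.min() >= 4.0

    def test_infeasible_density_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="infeasibly dense"):
            pm.poisson_disk_sample(10000, (100.0, 100.0), 5.0, rng)


class TestDeterminism:
    def test_same_seed_reproduces_frame(self):
        a, _ = pm.random_mixed_frame(box=(120.0, 120.0), seed=5)
        b, _ = pm.random_mixed_frame(box=(120.0, 120.0), seed=5)
        np.testing.assert_array_equal(a.positions, b.positions)
        assert list(a.resnames) == list(b.resnames)

    def test_different_seeds_decorrelate(self):
        a, _ = pm.random_mixed_frame(box=(120.0, 120.0), seed=5)
        b, _ = pm.random_mixed_frame(box=(120.0, 120.0), seed=6)
        assert not np.allclose(a.positions, b.positions)

    def test_protein_placement_reproducible(self):
        f, t = pm.striped_frame(box=(200.0, 200.0), stripe_width=60.0,
                                seed=7, x0=50.0)
        a, ta = pm.place_proteins(f, t, n_per_leaflet=4, seed=9)
        b, tb = pm.place_proteins(f, t, n_per_leaflet=4, seed=9)
        np.testing.assert_array_equal(a.positions, b.positions)
        assert ta.protein_leaflets == tb.protein_leaflets


class TestStripeTruth:
    def test_straight_stripe_geometry(self):
        _, truth = pm.striped_frame(box=(400.0, 400.0), stripe_width=120.0,
                                    seed=0, x0=10.0)
        assert truth.interface_length == pytest.approx(800.0)
        assert truth.ld_area_fraction == pytest.approx(0.3)

    def test_sinusoidal_arc_length_matches_polyline_oracle(self):
        amp, lam, ly = 15.0, 100.0, 400.0
        # dense polyline integration as an independent oracle
        y = np.linspace(0, ly, 200001)
        x = amp * np.sin(2 * np.pi * y / lam)
        oracle = np.sum(np.hypot(np.diff(x), np.diff(y)))
        assert stripe_arc_length(amp, lam, ly) == pytest.approx(oracle,
                                                                rel=1e-6)

    def test_roughness_beyond_half_width_rejected(self):
        with pytest.raises(ValueError, match="amplitude"):
            pm.striped_frame(box=(400.0, 400.0), stripe_width=50.0,
                             roughness_amplitude=30.0, seed=0)

    def test_stripe_width_outside_box_rejected(self):
        with pytest.raises(ValueError, match="stripe width"):
            pm.striped_frame(box=(400.0, 400.0), stripe_width=400.0, seed=0)

    def test_truth_mask_area_matches_geometry(self):
        _, truth = pm.striped_frame(box=(400.0, 400.0), stripe_width=120.0,
                                    seed=1, x0=33.0)
        mask = pm.truth_mask(truth)
        assert mask.ld_fraction == pytest.approx(0.3, abs=0.005)

    def test_phase_labels_match_species(self):
        frame, truth = pm.striped_frame(box=(200.0, 200.0), stripe_width=60.0,
                                        seed=2, x0=20.0)
        for rid, resname in zip(frame.resids, frame.resnames):
            expected = "Ld" if resname == "DUPC" else "Lo"
            assert truth.phase_by_resid[int(rid)] == expected


class TestCircularDomains:
    def test_truth_records_radii_and_rim_length(self):
        _, truth = pm.circular_domain_frame(box=(300.0, 300.0),
                                            radii=(30.0, 50.0), seed=3)
        assert truth.domain_radii == (30.0, 50.0)
        assert truth.interface_length == pytest.approx(2 * math.pi * 80.0)
        assert truth.characteristic_length == pytest.approx(40.0)

    def test_overlapping_circles_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            pm.circular_domain_frame(box=(300.0, 300.0), radii=(50.0, 50.0),
                                     centers=np.array([[100.0, 100.0],
                                                       [140.0, 100.0]]),
                                     seed=0)

    def test_circle_too_large_for_box_rejected(self):
        with pytest.raises(ValueError, match="image"):
            pm.circular_domain_frame(box=(150.0, 150.0), radii=(80.0,),
                                     seed=0)

    def test_corner_circle_is_one_domain_in_truth_mask(self):
        _, truth = pm.circular_domain_frame(
            box=(200.0, 200.0), radii=(40.0,),
            centers=np.array([[0.0, 0.0]]), seed=0)
        domains = pm.label_domains(pm.truth_mask(truth))
        ld = domains[domains.phase == "Ld"]
        assert len(ld) == 1
        assert ld.iloc[0].equivalent_radius == pytest.approx(40.0, abs=1.0)


class TestCoarseningSeries:
    def test_frame_count_and_monotone_truth(self):
        frames, truths = pm.coarsening_series(box=(150.0, 150.0), alpha=0.4,
                                              n_frames=5, r_start=10.0,
                                              seed=4)
        assert len(frames) == 5
        lengths = [t.characteristic_length for t in truths]
        assert all(b > a for a, b in zip(lengths, lengths[1:]))
        times = [t.time_us for t in truths]
        assert all(b > a for a, b in zip(times, times[1:]))

    def test_truth_series_follows_power_law_exactly(self):
        _, truths = pm.coarsening_series(box=(150.0, 150.0), alpha=0.45,
                                         n_frames=6, r_start=10.0, seed=5)
        df = pm.truth_series(truths)
        fit = pm.fit_power_law(pm.MetricSeries(
            times=df["time"].to_numpy(),
            values=df["characteristic_length"].to_numpy(), metric="L"))
        assert fit.alpha == pytest.approx(0.45, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_non_positive_exponent_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            pm.coarsening_series(alpha=0.0, seed=0)


class TestPlaceProteins:
    def test_hexagonal_adds_ten_per_leaflet(self):
        frame, truth = pm.random_mixed_frame(box=(150.0, 150.0), seed=8)
        out, truth2 = pm.place_proteins(frame, truth, n_per_leaflet=10,
                                        placement="hexagonal", seed=8)
        assert out.n_beads == frame.n_beads + 20
        assert len(truth2.protein_leaflets) == 20
        assert truth2.protein_labels == {}  # hexagonal plants no labels

    def test_phase_placement_requires_geometry(self):
        frame, truth = pm.random_mixed_frame(box=(150.0, 150.0), seed=8)
        with pytest.raises(ValueError, match="geometry"):
            pm.place_proteins(frame, truth, placement="Lo", seed=0)

    def test_planted_labels_sit_in_their_regions(self):
        frame, truth = pm.striped_frame(box=(300.0, 300.0), stripe_width=100.0,
                                        seed=9, x0=60.0)
        out, truth2 = pm.place_proteins(
            frame, truth, placement={"Lo": 2, "Ld": 2}, seed=9)
        mask = pm.truth_mask(truth2)
        prot = pm.select_markers(out, "PROTEIN")
        for rid, com in zip(prot.resids, prot.positions):
            in_ld = mask.values[int(com[0]) % 300, int(com[1]) % 300]
            expected = truth2.protein_labels[int(rid)]
            assert in_ld == (expected == "Ld")
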