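"""Phase masks, interface detection, domains and leaflet coupling."""

import math

import numpy as np
import pytest

import phasemap as pm
from phasemap.density import DensityField, PixelGrid
from phasemap.phases import MATCH_MISMATCH, PhaseMask, label_periodic


def field(values, **meta):
    values = np.asarray(values, dtype=float)
    return DensityField(grid=PixelGrid(*values.shape), values=values, **meta)


def stripe_mask(nx=400, ny=400, x0=100.0, width=120.0):
    x = np.arange(nx) + 0.5
    values = (np.mod(x - x0, nx) < width)[:, None] & np.ones((1, ny), bool)
    return PhaseMask(grid=PixelGrid(nx, ny), values=values)


def circle_mask(nx=400, ny=400, cx=200.0, cy=200.0, r=50.0):
    x = np.arange(nx) + 0.5
    xx, yy = np.meshgrid(x, np.arange(ny) + 0.5, indexing="ij")
    dx = np.minimum(np.abs(xx - cx), nx - np.abs(xx - cx))
    dy = np.minimum(np.abs(yy - cy), ny - np.abs(yy - cy))
    return PhaseMask(grid=PixelGrid(nx, ny), values=dx ** 2 + dy ** 2 < r ** 2)


class TestPhaseMask:
    def test_identical_constant_fields_all_lo(self):
        a = field(np.full((50, 50), 3.0))
        mask = pm.phase_mask(a, field(np.full((50, 50), 3.0)))
        assert mask.ld_fraction == 0.0  # strict > on a constant difference

    def test_step_fields_recover_the_dupc_half(self):
        dupc = field(np.where(np.arange(60)[:, None] < 30,
                              np.ones((60, 60)), 0.0))
        dppc = field(np.where(np.arange(60)[:, None] >= 30,
                              np.ones((60, 60)), 0.0))
        mask = pm.phase_mask(dupc, dppc)
        assert np.all(mask.values[:30])
        assert not np.any(mask.values[30:])
        assert mask.threshold_used == pytest.approx(0.0)

    def test_swapping_species_complements_mask_and_keeps_length(
            self, stripe_analysis):
        dupc = stripe_analysis.densities[("upper", "DUPC")]
        dppc = stripe_analysis.densities[("upper", "DPPC")]
        mask = pm.phase_mask(dupc, dppc)
        swapped = pm.phase_mask(dppc, dupc)
        assert np.array_equal(swapped.values, ~mask.values)
        la = pm.interface_length(pm.detect_interface(mask))
        lb = pm.interface_length(pm.detect_interface(swapped))
        assert la == lb

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="grid mismatch"):
            pm.phase_mask(field(np.zeros((10, 10))), field(np.zeros((12, 10))))


class TestDetectInterface:
    def test_uniform_mask_gives_empty_edges(self):
        mask = PhaseMask(grid=PixelGrid(50, 50),
                         values=np.zeros((50, 50), bool))
        assert pm.detect_interface(mask).n_edge_pixels == 0

    def test_straight_stripe_gives_two_single_pixel_chains(self):
        edges = pm.detect_interface(stripe_mask())
        labels, n = label_periodic(edges.values)
        assert n == 2
        assert pm.interface_length(edges) == pytest.approx(800.0, rel=0.02)

    def test_edges_continuous_across_periodic_seam(self):
        edges = pm.detect_interface(stripe_mask(x0=350.0))
        labels, n = label_periodic(edges.values)
        assert n == 2
        assert pm.interface_length(edges) == pytest.approx(800.0, rel=0.02)
        # no spurious border edges: every row crossed exactly twice
        assert np.all(edges.values.sum(axis=0) == 2)

    def test_every_edge_pixel_near_a_mask_transition(self):
        mask = circle_mask()
        edges = pm.detect_interface(mask)
        # dilate the mask boundary by 2 pixels
        from scipy import ndimage
        boundary = mask.values ^ ndimage.binary_erosion(mask.values)
        near = ndimage.binary_dilation(boundary, np.ones((5, 5)))
        assert np.all(near[edges.values])

    def test_agrees_with_reference_detector_on_clean_mask(self):
        # independent cross-check: scikit-image's Canny on the same stripe
        from skimage import feature
        from scipy import ndimage as ndi
        mask = stripe_mask()
        ours = pm.detect_interface(mask).values
        padded = np.pad(mask.values.astype(float), 16, mode="wrap")
        gmax = ndi.gaussian_gradient_magnitude(padded, 2.0).max()
        ref = feature.canny(padded, sigma=2.0, low_threshold=0.1 * gmax,
                            high_threshold=0.2 * gmax)[16:-16, 16:-16]
        # every edge pixel we report lies on (or next to) a reference edge
        near_ref = ndi.binary_dilation(ref, np.ones((3, 3)))
        assert np.all(near_ref[ours])


class TestInterfaceLength:
    def test_empty_edge_map_is_zero(self):
        edges = pm.EdgeMap(grid=PixelGrid(10, 10),
                           values=np.zeros((10, 10), bool))
        assert pm.interface_length(edges) == 0.0

    def test_circle_perimeter_within_pixelation_bias(self):
        edges = pm.detect_interface(circle_mask(r=50.0))
        assert pm.interface_length(edges) == pytest.approx(2 * math.pi * 50,
                                                           rel=0.10)

    def test_chain_estimator_weights_diagonals(self):
        # a single diagonal chain: pixel count underestimates, chain ~ sqrt(2)
        n = 64
        values = np.zeros((n, n), bool)
        idx = np.arange(1, n - 1)
        values[idx, idx] = True
        edges = pm.EdgeMap(grid=PixelGrid(n, n), values=values)
        pixel = pm.interface_length(edges, method="pixel")
        chain = pm.interface_length(edges, method="chain")
        assert chain == pytest.approx(math.sqrt(2) * (n - 3), rel=0.01)
        assert pixel == n - 2


class TestLabelDomains:
    def test_single_circle_one_ld_domain_with_true_radius(self):
        domains = pm.label_domains(circle_mask(r=50.0))
        ld = domains[domains.phase == "Ld"]
        assert len(ld) == 1
        assert ld.iloc[0].equivalent_radius == pytest.approx(50.0, abs=1.0)
        assert ld.iloc[0].centroid_x == pytest.approx(200.0, abs=1.0)

    def test_domain_straddling_seam_is_single_with_wrapped_centroid(self):
        domains = pm.label_domains(circle_mask(cx=0.0, cy=200.0, r=40.0))
        ld = domains[domains.phase == "Ld"]
        assert len(ld) == 1
        assert min(ld.iloc[0].centroid_x, 400 - ld.iloc[0].centroid_x) < 1.5

    def test_checkerboard_squares_merge_through_corners(self):
        values = np.zeros((40, 40), bool)
        values[10:20, 10:20] = True
        values[20:30, 20:30] = True
        values[0:10, 20:30] = True
        values[20:30, 0:10] = True
        mask = PhaseMask(grid=PixelGrid(40, 40), values=values)
        domains = pm.label_domains(mask)
        ld = domains[domains.phase == "Ld"]
        assert len(ld) == 1  # 8-connectivity joins diagonal corners
        assert ld.iloc[0].area == 400.0

    def test_phase_areas_partition_the_grid(self, stripe_analysis):
        domains = stripe_analysis.domains["upper"]
        total = domains.groupby("phase")["area"].sum()
        grid = stripe_analysis.grid
        assert total.sum() == grid.nx * grid.ny


class TestMeanDomainRadius:
    def test_single_circle(self):
        domains = pm.label_domains(circle_mask(r=50.0))
        assert pm.mean_domain_radius(domains, phases=("Ld",)) == pytest.approx(
            50.0, abs=1.0)

    def test_two_circles_unweighted_mean(self):
        values = circle_mask(cx=100, cy=100, r=30.0).values | \
            circle_mask(cx=280, cy=280, r=50.0).values
        domains = pm.label_domains(PhaseMask(grid=PixelGrid(400, 400),
                                             values=values))
        assert pm.mean_domain_radius(domains, phases=("Ld",)) == pytest.approx(
            40.0, abs=1.0)

    def test_small_islands_below_min_area_ignored(self):
        values = circle_mask(r=50.0).values.copy()
        for k in range(5):
            values[5 + k * 3, 5] = True  # single-pixel specks
        with_specks = pm.label_domains(PhaseMask(grid=PixelGrid(400, 400),
                                                 values=values))
        clean = pm.label_domains(circle_mask(r=50.0))
        assert pm.mean_domain_radius(with_specks, phases=("Ld",)) == \
            pm.mean_domain_radius(clean, phases=("Ld",))

    def test_no_surviving_domain_raises(self):
        domains = pm.label_domains(circle_mask(r=50.0))
        with pytest.raises(ValueError, match="undefined"):
            pm.mean_domain_radius(domains, min_area=1e9)


class TestLeafletMatch:
    def test_identical_masks_no_mismatch(self):
        mask = stripe_mask()
        match = pm.leaflet_match(mask, mask)
        assert match.mismatch_fraction == 0.0
        assert sum(match.fractions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_complementary_masks_full_mismatch(self):
        mask = stripe_mask()
        comp = PhaseMask(grid=mask.grid, values=~mask.values)
        assert pm.leaflet_match(mask, comp).mismatch_fraction == 1.0

    def test_independent_random_masks_mismatch_half(self):
        # two Bernoulli(1/2) masks disagree on 2 p (1-p) = 50% of pixels
        vals = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            a = PhaseMask(grid=PixelGrid(100, 100),
                          values=rng.random((100, 100)) < 0.5)
            b = PhaseMask(grid=PixelGrid(100, 100),
                          values=rng.random((100, 100)) < 0.5)
            vals.append(pm.leaflet_match(a, b).mismatch_fraction)
        assert np.mean(vals) == pytest.approx(0.5, abs=0.02)

    def test_match_codes_cover_grid(self, stripe_analysis):
        match = stripe_analysis.match
        counts = np.bincount(match.values.ravel(), minlength=3)
        assert counts.sum() == match.values.size
        assert match.fractions["mismatch"] == pytest.approx(
            counts[MATCH_MISMATCH] / match.values.size)


class TestSpeciesPartition:
    def test_uniform_density_partitions_like_area(self):
        mask = stripe_mask()
        uniform = field(np.full(mask.grid.shape, 0.37))
        assert pm.species_partition(uniform, mask) == pytest.approx(
            mask.ld_fraction, abs=1e-3)

    def test_cholesterol_partitions_into_ordered_phase(self, stripe_analysis):
        # generated frames put cholesterol only in the Lo region
        chol_ld = stripe_analysis.rows["chol_ld_fraction"]
        assert (chol_ld < 0.1).all()

    def test_zero_density_rejected(self):
        mask = stripe_mask()
        with pytest.raises(ValueError, match="undefined"):
            pm.species_partition(field(np.zeros(mask.grid.shape)), mask)


class TestPipelineStripeRecovery:
    """End-to-end mask metrics on a generated straight-stripe frame."""

    def test_ld_area_fraction_matches_stripe_width(self, stripe_analysis,
                                                   stripe_frame_and_truth):
        _, truth = stripe_frame_and_truth
        for frac in stripe_analysis.rows["ld_area_fraction"]:
            assert frac == pytest.approx(truth.ld_area_fraction, abs=0.02)

    def test_interface_length_recovers_geometry(self, stripe_analysis,
                                                stripe_frame_and_truth):
        # density noise and the mixing band wiggle the measured boundary;
        # the residual inflation stays within a few percent
        _, truth = stripe_frame_and_truth
        for length in stripe_analysis.rows["interface_length"]:
            assert length == pytest.approx(truth.interface_length, rel=0.06)

    def test_interface_length_invariant_under_translation(
            self, stripe_frame_and_truth):
        frame, _ = stripe_frame_and_truth
        shifted = pm.Frame(names=frame.names, resnames=frame.resnames,
                           resids=frame.resids,
                           positions=frame.positions + [57.0, 83.0, 0.0],
                           box=frame.box, time=frame.time)
        fa = pm.analyze_frame(pm.wrap_frame(shifted), with_thickness=False,
                              with_proteins=False)
        base = pm.analyze_frame(frame, with_thickness=False,
                                with_proteins=False)
        for a, b in zip(base.rows["interface_length"],
                        fa.rows["interface_length"]):
            assert b == pytest.approx(a, rel=0.02)

    def test_truth_mask_route_is_exact(self, stripe_frame_and_truth):
        _, truth = stripe_frame_and_truth
        edges = pm.detect_interface(pm.truth_mask(truth))
        assert pm.interface_length(edges) == pytest.approx(
            truth.interface_length, rel=0.02)


class TestCoarseningConsistency:
    def test_radius_and_interface_move_oppositely(self, coarsening_measured):
        from scipy.stats import spearmanr
        for radius, length in coarsening_measured:
            rho, _ = spearmanr(radius.values, length.values)
            assert rho < 0
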