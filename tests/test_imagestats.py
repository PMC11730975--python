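"""Image statistics: slope, fractal dimension, contrast, edge entropy."""

import numpy as np
import pytest
from oracles import naive_box_count, naive_pair_entropy
from scipy.optimize import minimize_scalar

from viscomfort import imagestats as ist
from viscomfort import stimuli
from viscomfort.imagestats import EdgeExtractionConfig, EdgeSet
from viscomfort.stimuli import GratingSpec, ImageStimulus


class TestSpectralSlope:
    @pytest.mark.parametrize("k", [-1.5, -0.5])
    def test_constructed_exponent_recovered(self, k):
        slopes = [
            ist.spectral_slope(stimuli.make_onef_noise(k, 256, s, 40))[0]
            for s in range(5)
        ]
        assert abs(np.mean(slopes) - k) < 0.1

    def test_grating_flagged_invalid(self, grating3):
        k, valid = ist.spectral_slope(grating3)
        assert not valid and np.isnan(k)

    def test_windowed_grating_flagged_invalid(self, grating3):
        win = stimuli.apply_gaussian_window(grating3, 32, 10.0)
        assert not ist.spectral_slope(win)[1]

    def test_constant_image_invalid(self):
        img = ImageStimulus(np.full((64, 64), 0.5), 16.0, "external")
        assert not ist.spectral_slope(img)[1]

    def test_bump_noise_remains_valid(self):
        img = stimuli.make_bump_noise(stimuli.BumpSpec(f0=1.5, size=128, seed=0), 16)
        assert ist.spectral_slope(img)[1]


class TestFractalDimension:
    def test_filled_plane(self):
        img = ImageStimulus(np.full((512, 512), 0.6), 40.0, "external")
        d, _, valid = ist.fractal_dimension(img)
        assert valid and d == pytest.approx(2.0, abs=0.05)

    def test_straight_line(self):
        pix = np.zeros((512, 512))
        pix[256, :] = 1.0
        d, _, valid = ist.fractal_dimension(ImageStimulus(pix, 40.0, "external"))
        assert valid and d == pytest.approx(1.0, abs=0.1)

    def test_sierpinski_triangle(self):
        x, y = np.meshgrid(np.arange(512), np.arange(512))
        pix = ((x & y) == 0).astype(float)
        d, _, valid = ist.fractal_dimension(ImageStimulus(pix, 40.0, "external"))
        assert valid and d == pytest.approx(np.log(3) / np.log(2), abs=0.05)

    def test_monotone_ordering_of_dimensions(self):
        x, y = np.meshgrid(np.arange(512), np.arange(512))
        plane = ImageStimulus(np.full((512, 512), 0.9), 40.0, "external")
        sier = ImageStimulus(((x & y) == 0).astype(float), 40.0, "external")
        line = np.zeros((512, 512))
        line[100, :] = 1.0
        d_plane = ist.fractal_dimension(plane)[0]
        d_sier = ist.fractal_dimension(sier)[0]
        d_line = ist.fractal_dimension(ImageStimulus(line, 40.0, "external"))[0]
        assert d_plane > d_sier > d_line

    def test_padding_rule_300px_to_512(self):
        assert ist.padded_size(300) == 512
        img = ImageStimulus(
            np.random.default_rng(0).uniform(0, 1, (300, 300)), 40.0, "external"
        )
        _, curve, _ = ist.fractal_dimension(img)
        assert curve.box_sizes_r.max() == 512

    def test_counts_nonincreasing_in_box_size(self):
        img = stimuli.make_onef_noise(-1, 128, 3, 16)
        _, curve, _ = ist.fractal_dimension(img)
        assert (np.diff(curve.counts_n) <= 0).all()

    def test_box_count_matches_naive_iteration(self):
        mask = np.random.default_rng(1).uniform(size=(64, 64)) > 0.7
        curve = ist.box_count(mask)
        for size, count in zip(curve.box_sizes_r, curve.counts_n):
            assert count == naive_box_count(mask, int(size))

    def test_empty_foreground_invalid(self):
        img = ImageStimulus(np.zeros((64, 64)), 16.0, "external")
        d, _, valid = ist.fractal_dimension(img)
        assert not valid and np.isnan(d)


class TestContrast:
    def test_uniform_image_zero_contrast(self):
        img = ImageStimulus(np.full((64, 64), 0.5), 16.0, "external")
        assert ist.rms_contrast(img) == 0.0
        assert ist.csf_filter_contrast(img) == 0.0

    def test_full_contrast_sinusoid_rms(self):
        img = stimuli.make_grating(GratingSpec(frequency=3, size=300, contrast=1.0), 30)
        assert ist.rms_contrast(img) == pytest.approx(1 / np.sqrt(2), abs=0.01)

    def test_csf_peak_near_eight_cpd(self):
        res = minimize_scalar(
            lambda f: -ist.mannos_sakrison_csf(f), bounds=(0.1, 60), method="bounded"
        )
        assert res.x == pytest.approx(8.0, abs=0.5)

    def test_components_above_limit_contribute_nothing(self):
        # grating on the FFT grid at 65.625 c/deg (ppd 140): entirely beyond
        # the 60 c/deg cut-off, so the filtered contrast is exactly zero
        freq = 140.0 / 128 * 60
        img = stimuli.make_grating(GratingSpec(frequency=freq, size=128), 140.0)
        assert ist.csf_filter_contrast(img) == pytest.approx(0.0, abs=1e-9)

    def test_csf_bounded_by_peak_sensitivity_times_rms(self):
        img = stimuli.make_onef_noise(-1, 128, 2, 16)
        bound = ist.mannos_sakrison_csf(8.0) * ist.rms_contrast(img) * 1.05
        assert ist.csf_filter_contrast(img) <= bound


class TestEdgeExtraction:
    def test_grating_edges_concentrate_in_one_orientation(self, ppd16):
        img = stimuli.make_grating(GratingSpec(frequency=3, size=256), 40.636)
        edges = ist.extract_edges(img)
        modal = np.bincount(edges.theta_idx).argmax()
        assert np.mean(edges.theta_idx == modal) > 0.95
        assert modal == 0  # vertical grating -> 0 rad filter

    def test_top_k_rule_retains_exactly_ten_thousand(self):
        rng = np.random.default_rng(0)
        h = w = 140
        intensity = np.zeros((h, w))
        interior = np.zeros((h, w), dtype=bool)
        interior[15:-15, 15:-15] = True
        flat = np.flatnonzero(interior.ravel())
        chosen = rng.choice(flat, size=12000, replace=False)
        intensity.ravel()[chosen] = rng.uniform(0.1, 1.0, 12000)
        theta = rng.integers(0, 24, (h, w))
        pol = np.ones((h, w), dtype=int)
        edges = ist.select_top_edges(intensity, theta, pol, 15, 10000)
        assert len(edges) == 10000

    def test_border_responses_discarded(self):
        h = w = 100
        intensity = np.zeros((h, w))
        intensity[:15, :] = 1.0  # energy only in the border strip
        intensity[:, :15] = 1.0
        intensity[-15:, :] = 1.0
        intensity[:, -15:] = 1.0
        theta = np.zeros((h, w), dtype=int)
        pol = np.ones((h, w), dtype=int)
        edges = ist.select_top_edges(intensity, theta, pol, 15, 10000)
        assert len(edges) == 0

    def test_large_image_resized_to_max_side(self):
        img = ImageStimulus(
            np.random.default_rng(2).uniform(0, 1, (400, 200)), 40.0, "external"
        )
        edges = ist.extract_edges(img, EdgeExtractionConfig(top_edges=500))
        assert edges.y.max() < 340 and edges.x.max() < 170

    def test_too_small_image_rejected(self):
        img = ImageStimulus(np.random.default_rng(0).uniform(0, 1, (20, 20)), 16.0, "external")
        with pytest.raises(ValueError):
            ist.extract_edges(img)


def _random_edges(rng, n):
    return EdgeSet(
        x=rng.uniform(0, 300, n),
        y=rng.uniform(0, 300, n),
        theta_idx=rng.integers(0, 24, n),
        polarity=rng.choice([-1, 1], n),
        intensity=rng.uniform(0.1, 2.0, n),
    )


class TestEdgeEntropy:
    def test_single_orientation_zero_entropy(self):
        edges = EdgeSet(
            np.arange(10.0), np.zeros(10), np.zeros(10, int),
            np.ones(10, int), np.ones(10),
        )
        h1, h2, _ = ist.edge_orientation_entropy(edges)
        assert h1 == 0.0 and h2 == 0.0

    def test_uniform_orientations_reach_maximum(self):
        # every position hosts all 48 directed orientations at equal
        # intensity, so every occupied (d, alpha) cell is exactly uniform
        positions = [(0, 0), (50, 10), (120, 200), (300, 40)]
        xs, ys, th, pol = [], [], [], []
        for px, py in positions:
            for o in range(48):
                xs.append(px)
                ys.append(py)
                th.append(o % 24)
                pol.append(1 if o < 24 else -1)
        edges = EdgeSet(
            np.array(xs, float), np.array(ys, float), np.array(th),
            np.array(pol), np.ones(len(xs)),
        )
        h1, h2, hist = ist.edge_orientation_entropy(edges)
        occupied = ~np.isnan(hist.probabilities[..., 0])
        assert np.allclose(hist.probabilities[occupied], 1 / 24, rtol=0, atol=1e-12)
        assert h1 == pytest.approx(ist.LOG2_24, abs=1e-12)
        assert h2 == pytest.approx(ist.LOG2_24, abs=1e-12)

    @pytest.mark.parametrize("n", [50, 200, 500])
    def test_matches_naive_pairwise_oracle(self, rng, n):
        edges = _random_edges(rng, n)
        _, h2, _ = ist.edge_orientation_entropy(edges)
        expected = naive_pair_entropy(
            edges.x, edges.y, edges.theta_idx, edges.polarity, edges.intensity
        )
        assert h2 == pytest.approx(expected, abs=1e-9)

    def test_entropies_bounded(self, rng):
        edges = _random_edges(rng, 300)
        h1, h2, _ = ist.edge_orientation_entropy(edges)
        assert 0 <= h1 <= ist.LOG2_24 and 0 <= h2 <= ist.LOG2_24

    def test_first_order_entropy_invariant_to_quarter_rotation(self):
        img = stimuli.make_bump_noise(stimuli.BumpSpec(f0=1.5, size=128, seed=6), 16)
        rot = ImageStimulus(np.rot90(img.pixels).copy(), 16.0, "bump")
        cfg = EdgeExtractionConfig(top_edges=2000)
        h1a = ist.first_order_entropy(ist.extract_edges(img, cfg))
        h1b = ist.first_order_entropy(ist.extract_edges(rot, cfg))
        assert h1a == pytest.approx(h1b, abs=0.05)

    def test_fewer_than_two_edges_rejected(self):
        edges = EdgeSet(np.zeros(1), np.zeros(1), np.zeros(1, int), np.ones(1, int), np.ones(1))
        with pytest.raises(ValueError):
            ist.edge_orientation_entropy(edges)


class TestAggregation:
    def test_bump_record_fully_valid(self):
        img = stimuli.make_bump_noise(stimuli.BumpSpec(f0=1.5, size=128, seed=0), 16)
        rec = ist.compute_all(img, "bump01", EdgeExtractionConfig(top_edges=1000),
                              {"n_d_bins": 100})
        assert "slope_invalid" not in rec.flags
        assert np.isfinite(rec.entropy_first) and np.isfinite(rec.entropy_second)

    def test_grating_record_flags_slope_only(self, grating3):
        rec = ist.compute_all(grating3, "g3", EdgeExtractionConfig(top_edges=1000),
                              {"n_d_bins": 100})
        assert "slope_invalid" in rec.flags
        assert np.isfinite(rec.rms_contrast) and np.isfinite(rec.entropy_first)

    def test_csv_round_trip_identity(self, tmp_path, grating3):
        img2 = stimuli.make_onef_noise(-1, 128, 4, 16)
        recs = [
            ist.compute_all(grating3, "g", EdgeExtractionConfig(top_edges=500),
                            {"n_d_bins": 50}),
            ist.compute_all(img2, "n", EdgeExtractionConfig(top_edges=500),
                            {"n_d_bins": 50}),
        ]
        path = tmp_path / "stats.csv"
        ist.write_stats_csv(recs, path)
        loaded = ist.read_stats_csv(path)
        for a, b in zip(recs, loaded):
            assert a.flags == b.flags and a.image_id == b.image_id
            for f in ("slope_k", "fractal_D", "rms_contrast", "csf_contrast",
                      "entropy_first", "entropy_second"):
                va, vb = getattr(a, f), getattr(b, f)
                assert (np.isnan(va) and np.isnan(vb)) or va == pytest.approx(vb, rel=1e-12)
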