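"""STA estimation, peak-frame and pixel tests, yoking, SVD, and PC1."""

import numpy as np
import pytest

from v1iso import receptive_field as rf
from v1iso.display import gaussian_phosphor_display
from v1iso.neurons import make_neuron, simulate_white_noise
from v1iso.stimulus import HyperpixelMap, hyperpixel_white_noise, pixel_white_noise


class TestComputeSTA:
    def test_single_spike_recovers_segment(self, display):
        movie = pixel_white_noise(40, display, seed=1)
        spikes = np.zeros(40, dtype=int)
        spikes[25] = 1
        sta = rf.compute_sta(movie, spikes, display)
        expected = movie.data[11:26] - display.background_rgb
        assert np.allclose(sta.frames, expected)
        assert sta.n_spikes == 1

    def test_no_usable_spikes_raises(self, display):
        movie = pixel_white_noise(40, display, seed=2)
        spikes = np.zeros(40, dtype=int)
        spikes[5] = 1  # before the first full segment
        with pytest.raises(rf.EmptySTAError):
            rf.compute_sta(movie, spikes, display)

    def test_linear_in_spike_vector(self, display):
        """STA weighted by (a + b) equals the weighted mix of the two STAs."""
        movie = pixel_white_noise(200, display, seed=3)
        rng = np.random.default_rng(4)
        a = rng.poisson(0.3, 200)
        b = rng.poisson(0.3, 200)
        a[:14] = b[:14] = 0
        a[20] += 1  # ensure both have spikes
        b[30] += 1
        sta_a = rf.compute_sta(movie, a, display)
        sta_b = rf.compute_sta(movie, b, display)
        sta_ab = rf.compute_sta(movie, a + b, display)
        na, nb = a.sum(), b.sum()
        mix = (na * sta_a.frames + nb * sta_b.frames) / (na + nb)
        assert np.allclose(sta_ab.frames, mix)

    def test_null_sta_is_small(self, display):
        """Spikes independent of the stimulus: every STA element stays below
        4 noise SDs of its standard error (CLT bound)."""
        movie = pixel_white_noise(12_000, display, seed=5)
        rng = np.random.default_rng(6)
        spikes = (rng.random(12_000) < 0.85).astype(int)  # ~1e4 spikes
        spikes[:14] = 0
        sta = rf.compute_sta(movie, spikes, display)
        bound = 4.0 * sta.stimulus_sd.max() / np.sqrt(sta.n_spikes)
        assert np.abs(sta.frames).max() < bound

    def test_linear_neuron_sta_matches_filter(self, display):
        """For a linear-logistic neuron the STA is proportional to the
        filter: cosine similarity > 0.9 at ~5e3 spikes (5x5 grid keeps the
        noise floor low enough for this bound)."""
        hmap = HyperpixelMap((6, 7), (11, 12))
        neuron = make_neuron(
            "do_linear", {"grid": (5, 5), "hmap": hmap, "gain": 12.0, "c": -4.5}
        )
        movie = pixel_white_noise(80_000, display, seed=7, grid=(5, 5))
        spikes = simulate_white_noise(neuron, movie, seed=8)
        assert spikes.sum() >= 5000
        sta = rf.compute_sta(movie, spikes, display)
        truth = neuron.filters.sum(axis=0).ravel()
        cos = float(
            sta.frames.ravel() @ truth
            / (np.linalg.norm(sta.frames) * np.linalg.norm(truth))
        )
        assert cos > 0.9


class TestPeakFrame:
    def _sta(self, frames, n_spikes=1000):
        return rf.STA(frames=frames, n_spikes=n_spikes, stimulus_sd=np.full(3, 0.15))

    def test_picks_the_loaded_frame(self):
        frames = np.zeros((15, 100, 3))
        frames[5, 40, 0] = 0.05
        peak, _ = rf.select_peak_frame(self._sta(frames))
        assert peak == 5

    def test_statistic_scales_quadratically(self):
        frames = np.zeros((15, 100, 3))
        frames[5, 40, 0] = 0.05
        s1 = rf.peak_frame_statistics(self._sta(frames))
        s2 = rf.peak_frame_statistics(self._sta(2 * frames))
        assert s2[5] == pytest.approx(4 * s1[5])

    def test_null_type_one_error_rate(self, display):
        """Pure-noise STAs: the chi-square peak test at alpha = 1e-4 flags at
        most ~1% of 200 replicates (max-over-frames inflation included)."""
        n_sig = 0
        for rep in range(200):
            rng = np.random.default_rng(1000 + rep)
            n_spk = 400
            # direct simulation of a null STA: elements ~ N(0, sd^2 / n)
            frames = rng.normal(0.0, 0.15 / np.sqrt(n_spk), size=(15, 25, 3))
            sta = rf.STA(
                frames=frames, n_spikes=n_spk, stimulus_sd=np.full(3, 0.15),
                grid=(5, 5),
            )
            _, sig = rf.select_peak_frame(sta, alpha=1e-4)
            n_sig += sig
        assert n_sig <= 2  # <= 1% of 200


class TestYoking:
    def _sta_from_mask(self, color_map, n_spikes=4000):
        """Build an STA whose peak frame holds the given per-pixel colors."""
        rows = len(color_map)
        cols = len(color_map[0])
        frames = np.zeros((15, rows * cols, 3))
        for r, row in enumerate(color_map):
            for c, col in enumerate(row):
                frames[7, r * cols + c, :] = col
        return rf.STA(
            frames=frames, n_spikes=n_spikes, stimulus_sd=np.full(3, 0.15),
            grid=(rows, cols),
        )

    RED = (0.05, -0.02, 0.0)
    GREEN = (-0.05, 0.02, 0.0)
    ZERO = (0.0, 0.0, 0.0)

    def test_two_opposite_blobs(self):
        R, G, Z = self.RED, self.GREEN, self.ZERO
        sta = self._sta_from_mask(
            [
                [R, R, Z, G, G],
                [R, R, Z, G, G],
                [Z, Z, Z, Z, Z],
                [Z, Z, Z, Z, Z],
                [Z, Z, Z, Z, Z],
            ]
        )
        hmap = rf.yoke_hyperpixels(sta, peak=7)
        sizes = sorted([len(hmap.subfield1), len(hmap.subfield2)])
        assert sizes == [4, 4]

    def test_single_blob_raises(self):
        R, Z = self.RED, self.ZERO
        sta = self._sta_from_mask(
            [
                [R, R, Z, Z, Z],
                [R, R, Z, Z, Z],
                [Z, Z, Z, Z, Z],
                [Z, Z, Z, Z, Z],
                [Z, Z, Z, Z, Z],
            ]
        )
        with pytest.raises(rf.InsufficientSubfieldsError):
            rf.yoke_hyperpixels(sta, peak=7)

    def test_three_blobs_picks_two_largest_color_distinct(self):
        """Blobs of sizes 6, 4, 2: the first two are color-distinct and win."""
        R, G, Z = self.RED, self.GREEN, self.ZERO
        sta = self._sta_from_mask(
            [
                [R, R, R, Z, G],
                [R, R, R, Z, G],
                [Z, Z, Z, Z, G],
                [G, G, Z, Z, G],
                [Z, Z, Z, Z, Z],
            ]
        )
        hmap = rf.yoke_hyperpixels(sta, peak=7)
        sizes = sorted([len(hmap.subfield1), len(hmap.subfield2)])
        assert sizes == [4, 6]

    def test_same_color_second_blob_rejected(self):
        R, Z = self.RED, self.ZERO
        sta = self._sta_from_mask(
            [
                [R, R, Z, Z, R],
                [R, R, Z, Z, R],
                [Z, Z, Z, Z, Z],
                [Z, Z, Z, Z, Z],
                [Z, Z, Z, Z, Z],
            ]
        )
        with pytest.raises(rf.InsufficientSubfieldsError):
            rf.yoke_hyperpixels(sta, peak=7)


class TestDecomposition:
    def _hsta(self, frames, n_spikes=2000):
        hmap = HyperpixelMap((0,), (1,))
        return rf.HyperpixelSTA(
            frames=frames, hmap=hmap, n_spikes=n_spikes,
            stimulus_sd=np.full(3, 0.15),
        )

    def test_rank_one_fully_explained(self):
        color = np.array([0.8, -0.6, 0.0])
        spatial = np.array([1.0, -1.0]) / np.sqrt(2)
        frames = np.zeros((15, 2, 3))
        frames[7] = np.outer(spatial, color)
        d = rf.weighted_sta_decompose(self._hsta(frames))
        assert d.variance_explained == pytest.approx(1.0)
        assert abs(d.color_weighting @ (color / np.linalg.norm(color))) == pytest.approx(1.0)
        # sign convention: largest-|entry| of the color vector is positive
        assert d.color_weighting[np.argmax(np.abs(d.color_weighting))] > 0

    def test_equal_singular_values_split(self):
        frames = np.zeros((15, 2, 3))
        frames[7, 0, 0] = 0.05  # orthogonal color/space pairs, equal energy
        frames[7, 1, 1] = 0.05
        d = rf.weighted_sta_decompose(self._hsta(frames))
        assert d.variance_explained == pytest.approx(0.5)

    def test_variance_explained_at_least_half(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            frames = np.zeros((15, 2, 3))
            frames[6:9] = rng.normal(0, 0.05, (3, 2, 3))
            d = rf.weighted_sta_decompose(self._hsta(frames))
            assert 0.5 <= d.variance_explained <= 1.0

    def test_do_linear_color_vector_recovered(self, phase2_session, display):
        """Parameter recovery through simulation at ~5e3 spikes."""
        hsta = phase2_session["hsta"]
        neuron = phase2_session["neuron"]
        d = rf.weighted_sta_decompose(hsta)
        k = neuron.peak_lag_index
        true_color = neuron.filters[0, k, list(neuron.hmap.subfield1)[0], :]
        true_color = true_color / np.linalg.norm(true_color)
        assert abs(d.color_weighting @ true_color) > 0.95


class TestPC1:
    def test_energy_neuron_detected(self, display):
        """Squaring subunits put excess variance along a non-STA axis: the
        permutation test detects it in >= 9 of 10 small replicates (scaled
        down from the 50-replicate design for runtime)."""
        n_sig = 0
        for rep in range(10):
            neuron = make_neuron("energy")
            movie = hyperpixel_white_noise(8000, display, neuron.hmap, seed=30 + rep)
            spikes = simulate_white_noise(neuron, movie, seed=60 + rep)
            hsta = rf.compute_hyperpixel_sta(movie, spikes, neuron.hmap, display)
            res = rf.pc1_test(
                movie, spikes, hsta, n_perm=400, seed=rep,
                background=display.background_rgb,
            )
            n_sig += res.significant
        assert n_sig >= 9

    def test_shuffled_spikes_not_systematically_significant(self, phase2_session, display):
        """A spike train shuffled against the stimulus satisfies the null:
        across 12 shuffles the rejection count stays near alpha."""
        movie = phase2_session["movie"]
        spikes = phase2_session["spikes"].copy()
        hmap = phase2_session["hsta"].hmap
        n_sig = 0
        for rep in range(12):
            rng = np.random.default_rng(rep)
            shuffled = spikes.copy()
            rng.shuffle(shuffled)
            hsta = rf.compute_hyperpixel_sta(movie, shuffled, hmap, display)
            res = rf.pc1_test(
                movie, shuffled, hsta, n_perm=200, seed=rep,
                background=display.background_rgb,
            )
            n_sig += res.significant
        assert n_sig <= 3  # P(>3 | p=0.05) < 0.003

    def test_insufficient_spikes_rejected(self, display, phase2_session):
        movie = phase2_session["movie"]
        hsta = phase2_session["hsta"]
        sparse = np.zeros(movie.n_frames, dtype=int)
        sparse[100:110] = 1
        with pytest.raises(ValueError):
            rf.pc1_test(movie, sparse, hsta, n_perm=50, seed=0)
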