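"""Projection datasets, GLM/GQM fits, ROC errors, and nonlinearity indices."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy.special import expit

from v1iso import nli, receptive_field as rf
from v1iso.nli import (
    ModelFit,
    ProjectionDataset,
    SubfieldRGBDataset,
    _design,
    _nli_from_errors,
    classification_error,
    fit_subfield_model,
    jackknife_se,
    white_noise_nli,
    within_subfield_nli,
)
from v1iso.neurons import simulate_white_noise
from v1iso.stimulus import hyperpixel_white_noise, hyperpixel_values


def _simulate_projection_ds(w1, w2, c, n, seed):
    """Rows drawn exactly from the across-subfield GLM."""
    rng = np.random.default_rng(seed)
    p1 = rng.normal(0, 1, n)
    p2 = rng.normal(0, 1, n)
    y = rng.random(n) < expit(w1 * p1 + w2 * p2 + c)
    return ProjectionDataset(p1=p1, p2=p2, spike=y.astype(int))


class TestProjectionDataset:
    def test_zero_sta_half_gives_zero_projection(self, phase2_session, display):
        hsta = phase2_session["hsta"]
        frames = hsta.frames.copy()
        frames[:, 1, :] = 0.0
        hsta0 = rf.HyperpixelSTA(
            frames=frames, hmap=hsta.hmap, n_spikes=hsta.n_spikes,
            stimulus_sd=hsta.stimulus_sd,
        )
        ds = nli.build_projection_dataset(
            phase2_session["movie"], phase2_session["spikes"], hsta0,
            background=display.background_rgb,
        )
        assert np.all(ds.p2 == 0.0)
        assert np.any(ds.p1 != 0.0)

    def test_projections_uncorrelated_across_subfields(self, phase2_session, display):
        """Disjoint supports + independent hyperpixels leave P1 and P2
        uncorrelated.  Overlapping 15-frame segments autocorrelate
        consecutive rows, so the check decimates to independent rows and
        uses a 3-SE bound."""
        ds = nli.build_projection_dataset(
            phase2_session["movie"], phase2_session["spikes"],
            phase2_session["hsta"], background=display.background_rgb,
        )
        p1, p2 = ds.p1[::15], ds.p2[::15]
        r = np.corrcoef(p1, p2)[0, 1]
        assert abs(r) < 3.0 / np.sqrt(p1.size)

    def test_aligned_segment_maximizes_projection(self, phase2_session, display):
        """A movie holding the STA itself as one segment projects maximally
        at the aligned lag."""
        hsta = phase2_session["hsta"]
        movie = phase2_session["movie"]
        data = np.tile(display.background_rgb, (60, movie.n_pixels, 1))
        scale = 1.0 / np.abs(hsta.frames).max() * 0.1
        for k in range(15):
            for h, pixels in enumerate(hsta.hmap.subfields):
                data[20 + k, list(pixels), :] = (
                    display.background_rgb + scale * hsta.frames[k, h, :]
                )
        probe = type(movie)(data=data, grid=movie.grid)
        ds = nli.build_projection_dataset(
            probe, np.zeros(60, dtype=int) + 1, hsta,
            background=display.background_rgb,
        )
        assert np.argmax(ds.p1) == 34 - 14  # segment ending at frame 34
        assert np.argmax(ds.p2) == 34 - 14

    def test_row_count(self, phase2_session, display):
        ds = nli.build_projection_dataset(
            phase2_session["movie"], phase2_session["spikes"],
            phase2_session["hsta"], background=display.background_rgb,
        )
        assert ds.p1.size == phase2_session["movie"].n_frames - 14


class TestFiringRateMap:
    def test_all_silent(self):
        ds = ProjectionDataset(
            p1=np.random.default_rng(0).normal(size=100),
            p2=np.random.default_rng(1).normal(size=100),
            spike=np.zeros(100, dtype=int),
        )
        prob, *_ = nli.firing_rate_map(ds, n_bins=5)
        occupied = ~np.isnan(prob)
        assert np.all(prob[occupied] == 0.0)

    def test_half_plane_rule(self):
        rng = np.random.default_rng(2)
        p1 = rng.normal(size=5000)
        p2 = rng.normal(size=5000)
        ds = ProjectionDataset(p1=p1, p2=p2, spike=(p1 > 0).astype(int))
        prob, xe, ye = nli.firing_rate_map(ds, n_bins=6)
        # bins lying wholly on one side of the P1 = 0 boundary are pure
        right = prob[xe[:-1] > 0, :]
        left = prob[xe[1:] < 0, :]
        assert np.nanmin(right) == 1.0
        assert np.nanmax(left) == 0.0

    def test_monotone_along_preferred_direction(self, phase2_session, display):
        from scipy.stats import spearmanr

        ds = nli.build_projection_dataset(
            phase2_session["movie"], phase2_session["spikes"],
            phase2_session["hsta"], background=display.background_rgb,
        )
        prob, xe, ye = nli.firing_rate_map(ds, n_bins=10)
        # drive grows along (P1 + P2); rank-correlate across occupied bins
        xc = (xe[:-1] + xe[1:]) / 2
        yc = (ye[:-1] + ye[1:]) / 2
        drive = xc[:, None] + yc[None, :]
        m = ~np.isnan(prob)
        rho, _ = spearmanr(drive[m].ravel(), prob[m].ravel())
        assert rho > 0.9


class TestModelFits:
    def test_glm_recovers_generating_weights(self):
        """Weights recovered within 3 SEs (statsmodels as the oracle for
        both the point estimate and its standard error)."""
        ds = _simulate_projection_ds(2.0, 1.0, -1.0, 20_000, seed=3)
        fit = fit_subfield_model(ds, "GLM_across")
        ref = sm.Logit(ds.spike, sm.add_constant(ds.features)).fit(disp=0)
        # agreement with the independent implementation
        assert np.allclose(fit.weights, ref.params[1:], atol=1e-4)
        assert fit.intercept == pytest.approx(ref.params[0], abs=1e-4)
        # consistency with the generating values
        for est, se, truth in zip(ref.params, ref.bse, [-1.0, 2.0, 1.0]):
            assert abs(est - truth) < 3 * se

    def test_gqm_quadratic_terms_vanish_on_glm_data(self):
        ds = _simulate_projection_ds(2.0, 1.0, -1.0, 20_000, seed=4)
        fit = fit_subfield_model(ds, "GQM_across")
        ref = sm.Logit(
            ds.spike, sm.add_constant(_design(ds.features, "GQM_across"))
        ).fit(disp=0)
        for est, se in zip(ref.params[1:4], ref.bse[1:4]):
            assert abs(est) < 3 * se
        assert np.allclose(fit.weights, ref.params[1:], atol=1e-3)

    def test_null_data_gives_null_slopes(self):
        rng = np.random.default_rng(5)
        ds = ProjectionDataset(
            p1=rng.normal(size=10_000), p2=rng.normal(size=10_000),
            spike=(rng.random(10_000) < 0.2).astype(int),
        )
        ref = sm.Logit(ds.spike, sm.add_constant(ds.features)).fit(disp=0)
        for est, se in zip(ref.params[1:], ref.bse[1:]):
            assert abs(est) < 3 * se

    def test_one_class_data_rejected(self):
        ds = ProjectionDataset(
            p1=np.ones(50), p2=np.ones(50), spike=np.zeros(50, dtype=int)
        )
        with pytest.raises(ValueError):
            fit_subfield_model(ds, "GLM_across")

    def test_separation_falls_back_to_ridge(self):
        p1 = np.concatenate([np.full(30, -2.0), np.full(30, 2.0)])
        ds = ProjectionDataset(
            p1=p1, p2=np.zeros(60), spike=(p1 > 0).astype(int)
        )
        fit = fit_subfield_model(ds, "GLM_across")
        assert fit.converged
        assert fit.ridged

    def test_nesting_likelihood(self):
        """On training data the GQM's Bernoulli likelihood is never below
        the GLM's (the GLM is the GQM with quadratic weights zeroed)."""
        for seed in range(3):
            ds = _simulate_projection_ds(1.0, -0.5, -1.5, 4000, seed=seed)
            glm = fit_subfield_model(ds, "GLM_across")
            gqm = fit_subfield_model(ds, "GQM_across")

            def loglik(fit):
                p = np.clip(fit.predict_proba(ds), 1e-12, 1 - 1e-12)
                y = ds.spike
                return np.sum(y * np.log(p) + (1 - y) * np.log(1 - p))

            assert loglik(gqm) >= loglik(glm) - 1e-6


class TestClassificationError:
    def test_perfect_separation_zero_error(self):
        ds = ProjectionDataset(
            p1=np.linspace(-1, 1, 100), p2=np.zeros(100),
            spike=(np.linspace(-1, 1, 100) > 0).astype(int),
        )
        fit = ModelFit(kind="GLM_across", weights=np.array([5.0, 0.0]),
                       intercept=0.0, converged=True)
        assert classification_error(fit, ds) == 0.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(6)
        ds = ProjectionDataset(
            p1=rng.normal(size=10_000), p2=rng.normal(size=10_000),
            spike=(rng.random(10_000) < 0.5).astype(int),
        )
        fit = ModelFit(kind="GLM_across", weights=np.array([1.0, 0.0]),
                       intercept=0.0, converged=True)
        assert classification_error(fit, ds) == pytest.approx(0.5, abs=0.02)

    def test_negating_scores_flips_error(self):
        ds = _simulate_projection_ds(2.0, 0.5, -1.0, 2000, seed=7)
        fit = fit_subfield_model(ds, "GLM_across")
        flipped = ModelFit(kind="GLM_across", weights=-fit.weights,
                           intercept=-fit.intercept, converged=True)
        e = classification_error(fit, ds)
        assert classification_error(flipped, ds) == pytest.approx(1.0 - e, abs=1e-12)


class TestNLI:
    def test_identical_errors_give_exact_zero(self):
        value, se = _nli_from_errors([(0.3, 0.3)] * 10)
        assert value == 0.0
        assert se == 0.0

    def test_white_noise_nli_near_zero_for_glm_data(self):
        """CV removes the GQM's in-sample advantage on GLM-generated data."""
        vals = [
            white_noise_nli(
                _simulate_projection_ds(1.5, 1.0, -1.5, 20_000, seed=s), seed=s
            ).value
            for s in range(5)
        ]
        assert abs(np.median(vals)) < 0.005

    def test_subfield_relabeling_invariance(self):
        ds = _simulate_projection_ds(1.5, 1.0, -1.5, 8000, seed=9)
        swapped = ProjectionDataset(p1=ds.p2, p2=ds.p1, spike=ds.spike)
        a = white_noise_nli(ds, seed=3)
        b = white_noise_nli(swapped, seed=3)
        assert a.value == pytest.approx(b.value, abs=1e-12)

    def test_requires_enough_spikes(self):
        ds = ProjectionDataset(
            p1=np.random.default_rng(0).normal(size=100),
            p2=np.zeros(100),
            spike=np.concatenate([[1, 1, 1], np.zeros(97)]).astype(int),
        )
        with pytest.raises(ValueError):
            white_noise_nli(ds, k=10)


class TestWithinSubfieldNLI:
    def test_squared_channel_drive_detected(self, display):
        """A neuron whose drive squares one phosphor channel within a
        subfield yields a positive within-subfield NLI."""
        from v1iso.neurons import default_hyperpixel_map

        hmap = default_hyperpixel_map()
        n_pos = 0
        for rep in range(5):
            movie = hyperpixel_white_noise(15_000, display, hmap, seed=40 + rep)
            hp = hyperpixel_values(movie, hmap) - display.background_rgb
            rng = np.random.default_rng(140 + rep)
            g = 40.0 * hp[:, 0, 0] ** 2 + 8.0 * hp[:, 1, 1] - 2.0
            spikes = (rng.random(hp.shape[0]) < expit(g)).astype(int)
            frames = np.zeros((15, 2, 3))
            frames[14, 0, 0] = frames[14, 1, 1] = 0.01  # latency-0 stand-in STA
            hsta = rf.HyperpixelSTA(
                frames=frames, hmap=hmap, n_spikes=int(spikes.sum()),
                stimulus_sd=np.full(3, 0.15),
            )
            res = within_subfield_nli(
                movie, spikes, hsta, latency=0, seed=rep,
                background=display.background_rgb,
            )
            n_pos += res.value > 0
        assert n_pos >= 4

    def test_linear_rgb_drive_near_zero(self, phase2_session, display):
        res = within_subfield_nli(
            phase2_session["movie"], phase2_session["spikes"],
            phase2_session["hsta"], seed=0, background=display.background_rgb,
        )
        assert abs(res.value) < 0.01
        assert res.jackknife_se >= 0.0


class TestJackknife:
    def test_non_negative_and_zero_for_constant(self):
        assert jackknife_se(np.full(10, 0.3)) == pytest.approx(0.0, abs=1e-12)
        assert jackknife_se(np.array([0.1, 0.2, 0.4])) > 0.0

    def test_shrinks_with_tighter_folds(self):
        rng = np.random.default_rng(11)
        ses = [
            jackknife_se(rng.normal(0, 1.0 / np.sqrt(n), size=10))
            for n in (1, 4, 16, 64)
        ]
        assert all(a > b for a, b in zip(ses, ses[1:]))
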