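"""Ground-truth generator: Brownian statistics, bleaching, event streams."""

import numpy as np
import pytest
from scipy import stats

from fabtirf.config import OpticsModel, SimConfig
from fabtirf.render import render_movie
from fabtirf.synthetic import (STATE_BLEACHED, sample_fluorophore_heights,
                               simulate_activation_population,
                               simulate_event_streams, simulate_trajectories)


def test_zero_diffusion_keeps_positions_constant():
    cfg = SimConfig(box_size=10.0, d_free=0.0, d_bound=0.0, n_frames=10)
    truth = simulate_trajectories(cfg, substeps_per_frame=2, frame_interval=0.5,
                                  n_molecules=4, rng=np.random.default_rng(0))
    assert np.allclose(truth.x, truth.x[:, :1])
    assert np.allclose(truth.y, truth.y[:, :1])


def test_mean_squared_displacement_matches_4d_dt(rng):
    d, dt = 2.49, 0.02
    cfg = SimConfig(box_size=300.0, d_free=d, d_bound=0.0, n_frames=101)
    truth = simulate_trajectories(cfg, substeps_per_frame=1, frame_interval=dt,
                                  n_molecules=100, rng=rng)
    r2 = (np.diff(truth.x, axis=1) ** 2 + np.diff(truth.y, axis=1) ** 2).ravel()
    expected = 4 * d * dt
    se = r2.std() / np.sqrt(r2.size)
    assert abs(r2.mean() - expected) < 3 * se


def test_invalid_parameters_rejected():
    with pytest.raises(ValueError):
        SimConfig(d_free=-1.0)
    with pytest.raises(ValueError):
        SimConfig(d_free=1.0, d_bound=2.0)
    with pytest.raises(ValueError):
        SimConfig(box_size=float("nan"))
    with pytest.raises(ValueError):
        OpticsModel(exposure=1.0, frame_interval=0.5)


def test_true_dwell_durations_exponential_with_requested_mean(rng):
    tau = 5.0
    cfg = SimConfig(box_size=20.0, d_free=2.5, d_bound=0.01, k_on_app=0.5,
                    tau_off_true=tau, n_frames=400)
    truth = simulate_trajectories(cfg, substeps_per_frame=5, frame_interval=0.5,
                                  n_molecules=40, rng=rng)
    dwells = np.array(truth.dwell_durations_s)
    assert dwells.size > 300
    se = dwells.std() / np.sqrt(dwells.size)
    assert abs(dwells.mean() - tau) < 3 * se
    # exponential shape (mean estimated from the sample; loose KS level)
    p = stats.kstest(dwells, "expon", args=(0, dwells.mean())).pvalue
    assert p > 0.005


def test_bleaching_is_absorbing(rng):
    cfg = SimConfig(box_size=10.0, d_free=1.0, d_bound=0.0,
                    tau_bleach_true=2.0, n_frames=60)
    truth = simulate_trajectories(cfg, substeps_per_frame=2, frame_interval=0.5,
                                  n_molecules=30, rng=rng)
    bleached = truth.state == STATE_BLEACHED
    assert bleached.any()
    # once bleached, always bleached
    started = np.maximum.accumulate(bleached, axis=1)
    assert np.array_equal(bleached, started)


def test_activation_probability_half_max_and_saturation(rng):
    ec50, h, m = 0.3, 2.0, 0.9
    at_ec50 = simulate_activation_population([ec50], ec50, h, m, 4000, rng)
    frac = at_ec50.activated.mean()
    assert abs(frac - m / 2) < 3 * np.sqrt(m / 2 * (1 - m / 2) / 4000)
    sat = simulate_activation_population([ec50 * 1e4], ec50, h, m, 4000, rng)
    assert abs(sat.activated.mean() - m) < 3 * np.sqrt(m * (1 - m) / 4000)
    with pytest.raises(ValueError):
        simulate_activation_population([0.3], ec50, -1.0, m, 10)
    with pytest.raises(ValueError):
        simulate_activation_population([-0.3], ec50, h, m, 10)


def test_event_stream_degenerate_probabilities():
    none = simulate_event_streams(10, 8.0, 0.0, 0.0, 3)
    assert all(len(c.condensates) == 0 for c in none)
    certain = simulate_event_streams(10, 8.0, 1.0, 0.0, 3)
    for c in certain:
        assert len(c.condensates) == len(c.binding_events)
    with pytest.raises(ValueError):
        simulate_event_streams(5, 8.0, 1.5, 0.0, 3)


def test_fluorophore_heights_truncated_and_ordered(rng):
    for hmax in (14.0, 25.0, 50.0):
        h = sample_fluorophore_heights(500, hmax, None, rng)
        assert h.min() >= 0 and h.max() <= hmax
    means = [sample_fluorophore_heights(500, hm, None, rng).mean()
             for hm in (14.0, 25.0, 50.0)]
    assert means[0] < means[1] < means[2]


class TestRendering:
    def _static_truth(self, height_nm=0.0):
        cfg = SimConfig(box_size=10.0, d_free=0.0, d_bound=0.0, n_frames=1)
        truth = simulate_trajectories(cfg, substeps_per_frame=10,
                                      frame_interval=0.5, n_molecules=1,
                                      rng=np.random.default_rng(0))
        truth.x[:] = 5.0
        truth.y[:] = 5.0
        truth.height_nm[:] = height_nm
        return truth

    def test_noiseless_total_counts_equal_photon_budget(self):
        opt = OpticsModel()
        img = render_movie(self._static_truth(), opt, noise=False)[0]
        assert img.sum() == pytest.approx(opt.photon_rate * opt.exposure * opt.gain,
                                          rel=1e-3)

    def test_height_at_evanescent_depth_attenuates_by_e(self):
        opt = OpticsModel()
        img0 = render_movie(self._static_truth(0.0), opt, noise=False)[0]
        imgd = render_movie(self._static_truth(opt.evanescent_depth), opt,
                            noise=False)[0]
        assert img0.sum() / imgd.sum() == pytest.approx(np.e, rel=1e-9)

    def test_motion_blur_suppresses_free_molecule_peak(self):
        opt = OpticsModel()
        bound = render_movie(self._static_truth(), opt, noise=False)[0]
        cfg = SimConfig(box_size=10.0, d_free=2.5, d_bound=0.0, n_frames=1,
                        rng_seed=2)
        free_truth = simulate_trajectories(cfg, substeps_per_frame=50,
                                           frame_interval=0.5, n_molecules=1,
                                           rng=np.random.default_rng(2))
        free = render_movie(free_truth, opt, noise=False)[0]
        assert bound.max() / free.max() >= 5.0

    def test_background_mean_matches_configured_baseline(self, rng):
        opt = OpticsModel(background_rate=100.0, offset=100.0)
        cfg = SimConfig(box_size=10.0, density=0.0, d_free=1.0, d_bound=0.0,
                        n_frames=3)
        truth = simulate_trajectories(cfg, substeps_per_frame=10,
                                      frame_interval=0.5, n_molecules=0, rng=rng)
        movie = render_movie(truth, opt, rng=rng)
        expected = opt.offset + opt.gain * opt.background_rate * opt.exposure \
            * opt.pixel_size ** 2
        assert abs(movie.mean() - expected) < opt.read_noise_sd

    def test_insufficient_substeps_rejected(self):
        truth = self._static_truth()
        with pytest.raises(ValueError):
            render_movie(truth, OpticsModel(exposure=0.05, frame_interval=0.5))
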