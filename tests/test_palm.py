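"""Tests of spot detection, trace building and the dwell-time estimator."""

import math

import numpy as np
import pytest
from scipy.special import ndtr

from clamptrace.core import ConfigError, DataError
from clamptrace.palm import (
    EstimationError,
    FittingError,
    OnTimeSet,
    UnloadingModel,
    bleach_time,
    build_traces,
    detect_spots,
    filter_single_step,
    fit_on_times,
    measure_on_times,
    unloading_time,
)
from clamptrace.synthgen import PalmConfig, generate_palm_movie, sample_on_times


def add_spot(img, r, c, flux, sigma=1.3):
    e_r = np.arange(img.shape[0] + 1.0)
    e_c = np.arange(img.shape[1] + 1.0)
    img += flux * np.outer(
        np.diff(ndtr((e_r - r) / sigma)), np.diff(ndtr((e_c - c) / sigma))
    )


def noisy(img, rng, gain=20.0, read=20.0):
    return gain * rng.poisson(np.maximum(img, 0) / gain) + rng.normal(0, read, img.shape)


class TestDetection:
    def test_blank_noise_false_positive_rate(self):
        rng = np.random.default_rng(31)
        n_fp = 0
        for _ in range(100):
            frame = noisy(np.full((128, 128), 100.0), rng)
            n_fp += len(detect_spots(frame))
        assert n_fp / 100 < 0.1

    def test_snr5_detection_rate(self):
        # peak SNR 5 relative to per-pixel noise
        rng = np.random.default_rng(32)
        noise_sd = math.sqrt(100 * 20 + 400)
        flux = 5 * noise_sd / 0.0935  # 0.0935 = peak pixel fraction of a sigma=1.3 PSF
        hits = 0
        trials = 200
        for _ in range(trials):
            img = np.full((64, 64), 100.0)
            add_spot(img, 32 + rng.uniform(-5, 5), 32 + rng.uniform(-5, 5), flux)
            hits += len(detect_spots(noisy(img, rng))) >= 1
        assert hits / trials > 0.95

    def test_two_separated_spots_resolved(self):
        img = np.full((64, 64), 100.0)
        add_spot(img, 30, 27, 5000.0)
        add_spot(img, 30, 37, 5000.0)
        det = detect_spots(img)
        assert len(det) == 2

    def test_nonfinite_pixels_rejected(self):
        img = np.full((32, 32), 100.0)
        img[3, 3] = np.nan
        with pytest.raises(DataError):
            detect_spots(img)


class TestTraces:
    def test_movie_on_times_match_truth(self):
        cfg = PalmConfig(n_frames=100, seed=41)
        stack, truth = generate_palm_movie(cfg, t_unload=195.0, n_spots=25,
                                           t_bleach_exposure_s=40.0)
        on_set = measure_on_times(stack, truth["cells"], exposure_s=0.4)
        rec = np.sort(on_set.on_times_s / 5.0)
        tru = np.sort(truth["visible_frames"])
        # nearly all on-times recovered exactly; allow one lost/extra trace
        assert abs(len(rec) - len(tru)) <= 2
        common = min(len(rec), len(tru))
        matches = sum(
            int(r) in truth["visible_frames"].tolist() for r in rec
        )
        assert matches >= common - 2

    def test_persistent_spot_is_censored(self):
        cfg = PalmConfig(n_frames=30, seed=42, noise=False)
        stack, truth = generate_palm_movie(cfg, t_unload=np.inf, n_spots=4)
        traces = build_traces(stack, truth["cells"])
        assert len(traces) == 4
        assert all(t.censored for t in traces)
        assert all(t.n_frames_on == 29 for t in traces)

    def test_out_of_cell_spot_rejected(self):
        cfg = PalmConfig(n_frames=12, seed=43, noise=False)
        stack, truth = generate_palm_movie(cfg, t_unload=np.inf, n_spots=2)
        px = stack.pixels.copy()
        for f in range(1, 12):
            add_spot(px[f], 2.0, 2.0, 3000.0)  # in the margin, not in a cell
        stack.pixels = px
        traces = build_traces(stack, truth["cells"])
        assert len(traces) == 2


class TestSingleStepFilter:
    def test_clean_one_step_accepted(self):
        trace = np.array([10.0] * 8 + [0.2] * 4)
        assert filter_single_step(trace)

    def test_two_equal_steps_rejected(self):
        trace = np.array([20.0] * 5 + [10.0] * 5 + [0.1] * 4)
        assert not filter_single_step(trace)

    def test_upward_step_rejected(self):
        trace = np.array([0.2] * 5 + [10.0] * 7)
        assert not filter_single_step(trace)

    def test_too_short_rejected(self):
        assert not filter_single_step(np.array([5.0, 0.0]))


def grid_mle_oracle(on_set):
    """Brute-force likelihood maximization over a fine tau grid."""
    dt = on_set.frame_interval_s
    k = np.round(on_set.on_times_s / dt)
    unc = ~on_set.censored
    taus = np.linspace(5.0, 2000.0, 40_000)
    a = dt / taus[:, None]
    ll = (
        np.log(np.exp(-(k[unc] - 1) * a) - np.exp(-k[unc] * a) + 1e-300).sum(axis=1)
        - (k[~unc] * a).sum(axis=1)
    )
    return taus[int(np.argmax(ll))]


class TestOnTimeFit:
    def test_degenerate_all_equal(self):
        s = OnTimeSet(np.full(20, 50.0), 1e-3, 0.4)
        assert fit_on_times(s) == pytest.approx(50.0, rel=1e-3)

    def test_consistency_at_large_n(self):
        on, cens, _ = sample_on_times(10_000, 140.0, np.inf, 5.0, 1e9, seed=44)
        s = OnTimeSet(on, 5.0, 0.4, cens, 1e9)
        assert 137.0 <= fit_on_times(s) <= 143.0

    def test_right_censoring_handled(self):
        on, cens, _ = sample_on_times(10_000, 140.0, np.inf, 5.0, 150.0, seed=45)
        s = OnTimeSet(on, 5.0, 0.4, cens, 150.0)
        assert cens.mean() > 0.3
        assert fit_on_times(s) == pytest.approx(140.0, rel=0.05)

    def test_matches_brute_force_grid_oracle(self):
        on, cens, _ = sample_on_times(300, 180.0, 600.0, 5.0, 900.0, seed=46)
        s = OnTimeSet(on, 5.0, 0.4, cens, 900.0)
        assert fit_on_times(s) == pytest.approx(grid_mle_oracle(s), rel=2e-3)

    def test_fine_frame_limit_equals_sample_mean(self):
        rng = np.random.default_rng(47)
        dt = 1e-9
        k = np.round(rng.exponential(1.0, 200) / dt)
        s = OnTimeSet(k * dt, dt, 0.4)
        assert fit_on_times(s) == pytest.approx((k * dt).mean(), rel=1e-9)

    def test_all_censored_is_an_error(self):
        s = OnTimeSet(np.full(20, 100.0), 5.0, 0.4, np.ones(20, bool), 100.0)
        with pytest.raises(FittingError):
            fit_on_times(s)


class TestBleachTime:
    def test_duty_one_is_identity(self):
        on, cens, _ = sample_on_times(5000, np.inf, 40.0, 0.4, 400.0, seed=48)
        s = OnTimeSet(on, 0.4, 0.4, cens, 400.0)
        t_wall = bleach_time(s, exposure_s=0.4, duty=1.0)
        assert t_wall == pytest.approx(40.0, rel=0.05)

    def test_duty_scaling(self):
        # 40 s of illumination at duty 0.08 -> 500 s wall clock
        on, cens, _ = sample_on_times(20_000, np.inf, 70.0, 0.7, 2000.0, seed=49)
        s = OnTimeSet(on, 0.7, 0.4, cens, 2000.0)
        # fast movie: 0.4 s exposure per 0.7 s frame -> 70 s wall = 40 s exposure
        t_wall = bleach_time(s, exposure_s=0.4, duty=0.4 / 5.0)
        assert t_wall == pytest.approx(500.0, rel=0.05)

    def test_bad_duty_rejected(self):
        s = OnTimeSet(np.array([5.0] * 20), 5.0, 0.4)
        with pytest.raises(ConfigError):
            bleach_time(s, 0.4, 0.0)


class TestUnloadingEstimate:
    def test_no_bleaching_limit(self):
        on, cens, _ = sample_on_times(500, 195.0, np.inf, 5.0, 1e9, seed=50)
        s = OnTimeSet(on, 5.0, 0.4, cens, 1e9)
        t_obs = fit_on_times(s)
        est = unloading_time(t_obs, 1e12, s, n_bootstrap=100, seed=0)
        assert est.t_unload == pytest.approx(t_obs, rel=1e-6)

    def test_rate_subtraction(self):
        s = OnTimeSet(np.array([140.0] * 20), 5.0, 0.4)
        est = unloading_time(140.3, 500.0, s, n_bootstrap=100, seed=0)
        assert est.t_unload == pytest.approx(195.1, abs=1.0)

    def test_bleaching_dominated_is_an_error(self):
        s = OnTimeSet(np.array([140.0] * 20), 5.0, 0.4)
        with pytest.raises(EstimationError):
            unloading_time(600.0, 500.0, s, n_bootstrap=10, seed=0)

    def test_rate_additivity_round_trip(self):
        # generate with (t_unload, t_bleach), estimate both, recover t_unload
        on, cens, _ = sample_on_times(10_000, 195.0, 500.0, 5.0, 3000.0, seed=51)
        slow = OnTimeSet(on, 5.0, 0.4, cens, 3000.0)
        fast_on, fast_cens, _ = sample_on_times(10_000, np.inf, 70.0, 0.7, 2000.0, seed=52)
        fast = OnTimeSet(fast_on, 0.7, 0.4, fast_cens, 2000.0)
        model = UnloadingModel(slow, fast_set=fast, duty=0.4 / 5.0)
        res = model.fit(n_bootstrap=200, seed=0)
        assert abs(res.t_unload - 195.0) / 195.0 < 0.05

    def test_bootstrap_ci_coverage(self):
        # nominal 95% percentile CI covers the truth within a few points
        n_rep, hits = 200, 0
        for i in range(n_rep):
            on, cens, _ = sample_on_times(84, 195.0, 500.0, 5.0, 1200.0, seed=600 + i)
            s = OnTimeSet(on, 5.0, 0.4, cens, 1200.0)
            try:
                est = unloading_time(fit_on_times(s), 500.0, s, n_bootstrap=500, seed=i)
            except (EstimationError, FittingError):
                continue
            hits += est.ci_low <= 195.0 <= est.ci_high
        assert hits / n_rep >= 0.89

    def test_summary_reports_estimate(self):
        on, cens, _ = sample_on_times(84, 195.0, 500.0, 5.0, 1200.0, seed=53)
        s = OnTimeSet(on, 5.0, 0.4, cens, 1200.0)
        res = UnloadingModel(s, t_bleach_wall=500.0).fit(n_bootstrap=200, seed=1)
        text = res.summary()
        assert "t_unload" in text and "bootstrap" in text
        lo, hi = res.conf_int()
        assert lo < res.t_unload < hi
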