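"""Tests of preprocessing, kymographs and the cell decomposition."""

import numpy as np
import pytest
from scipy.special import ndtr

from clamptrace.core import ConfigError, DataError, ImageStack
from clamptrace.timelapse import (
    CellCycleTrace,
    DecompositionSettings,
    TrackingError,
    build_kymograph,
    correct_drift,
    correct_illumination,
    decompose_cell,
    select_cells,
    subtract_background,
)


def gauss_profile(n, p, sigma=1.3):
    e = np.arange(n + 1.0)
    return np.diff(ndtr((e - p) / sigma))


def blurred_rect(n, a, b, sigma=1.3):
    e = np.arange(n + 1.0)

    def psi(u):
        return u * ndtr(u) + np.exp(-0.5 * u * u) / np.sqrt(2 * np.pi)

    return np.diff(sigma * (psi((e - a) / sigma) - psi((e - b) / sigma)) / (b - a))


class TestBackgroundSubtraction:
    def test_constant_image_maps_to_zero(self):
        out = subtract_background(np.full((40, 40), 137.0), 15.0)
        assert np.abs(out).max() < 1.0

    def test_spot_integral_preserved_on_plane(self):
        rng = np.random.default_rng(0)
        img = np.outer(np.linspace(100, 160, 48), np.ones(48))
        spot = 5000.0 * np.outer(gauss_profile(48, 24.0), gauss_profile(48, 24.0))
        out = subtract_background(img + spot, 15.0)
        from clamptrace.palm import _aperture_intensity
        measured = _aperture_intensity(out, 24.0, 24.0, a=6)
        assert measured == pytest.approx(5000.0, rel=0.05)

    def test_invalid_radius(self):
        with pytest.raises(ConfigError):
            subtract_background(np.zeros((10, 10)), 0.0)


class TestIlluminationCorrection:
    def test_flat_profile_is_identity(self):
        frame = np.random.default_rng(1).random((20, 20))
        out = correct_illumination(frame, np.ones((20, 20)))
        assert np.allclose(out, frame)

    def test_flat_field_property(self):
        rr, cc = np.meshgrid(np.arange(40) - 20.0, np.arange(40) - 20.0, indexing="ij")
        beam = np.exp(-(rr**2 + cc**2) / (2 * 30.0**2))
        flat = np.full((40, 40), 500.0)
        out = correct_illumination(flat * beam, beam)
        assert np.all(np.abs(out / 500.0 - 1.0) < 1e-9)
        # corner to centre ratio restored to ~1
        assert out[2, 2] / out[20, 20] == pytest.approx(1.0, abs=1e-9)

    def test_bad_profile_rejected(self):
        frame = np.ones((10, 10))
        with pytest.raises(DataError):
            correct_illumination(frame, np.zeros((10, 10)))
        with pytest.raises(DataError):
            correct_illumination(frame, np.ones((5, 5)))


def _drifting_stack(drift_per_frame, n_frames=100, fid=(24.3, 10.4), flux=20000.0):
    rng = np.random.default_rng(7)
    frames = []
    for f in range(n_frames):
        dy, dx = np.asarray(drift_per_frame, dtype=float) * f
        img = np.full((48, 48), 100.0)
        img += flux * np.outer(gauss_profile(48, fid[0] + dy), gauss_profile(48, fid[1] + dx))
        frames.append(img + rng.normal(0, 5, img.shape))
    return ImageStack(np.array(frames), 160.0, 150.0, 0.08)


class TestDriftCorrection:
    def test_zero_drift_zero_shifts(self):
        stack = _drifting_stack((0.0, 0.0))
        _, shifts = correct_drift(stack, (16, 34, 2, 20))
        assert np.all(shifts == 0)

    def test_linear_drift_recovered_within_one_pixel(self):
        stack = _drifting_stack((0.0, 0.2))
        _, shifts = correct_drift(stack, (16, 34, 2, 40))
        truth = -np.outer(np.arange(100), (0.0, 0.2))
        assert np.abs(shifts - truth).max() <= 1.0

    def test_sinusoidal_drift_residual_bounded(self):
        rng = np.random.default_rng(3)
        frames = []
        n = 60
        dy = 3.0 * np.sin(2 * np.pi * np.arange(n) / 40.0)
        for f in range(n):
            img = np.full((48, 48), 100.0)
            img += 20000.0 * np.outer(gauss_profile(48, 24 + dy[f]), gauss_profile(48, 24.0))
            frames.append(img + rng.normal(0, 5, img.shape))
        stack = ImageStack(np.array(frames), 160.0, 150.0, 0.08)
        _, shifts = correct_drift(stack, (14, 34, 14, 34))
        residual = dy + shifts[:, 0]
        assert np.abs(residual).max() <= 1.0

    def test_lost_fiducial_raises_with_frame(self):
        stack = _drifting_stack((0.0, 0.0))
        stack.pixels[17] = 100.0  # fiducial vanishes in frame 17
        with pytest.raises(TrackingError, match="17"):
            correct_drift(stack, (16, 34, 2, 20))


class TestKymograph:
    def test_single_pixel(self):
        px = np.zeros((3, 10, 8))
        px[1, 4, 3] = 7.0
        kymo = build_kymograph(ImageStack(px, 160, 150, 0.08), (0, 8))
        assert kymo.data[1, 4] == 7.0
        assert kymo.data.sum() == 7.0

    def test_mass_conservation_per_frame(self):
        rng = np.random.default_rng(5)
        px = rng.random((4, 12, 10))
        kymo = build_kymograph(ImageStack(px, 160, 150, 0.08), (2, 7))
        assert np.allclose(kymo.data.sum(axis=1), px[:, :, 2:7].sum(axis=(1, 2)))

    def test_empty_region_rejected(self):
        with pytest.raises(ConfigError):
            build_kymograph(ImageStack(np.zeros((2, 5, 5)), 160, 150, 0.08), (3, 3))


class TestDecomposition:
    def test_uniform_cell_has_no_foci(self):
        rng = np.random.default_rng(11)
        profile = 8000.0 + rng.normal(0, 100, 24)
        outside = rng.normal(100, 10, 60)
        bg, cyt, foc, cnt = decompose_cell(profile, outside, 8)
        assert cnt == 0
        assert foc < 3 * 100 * np.sqrt(24)

    def test_conservation_is_exact(self):
        rng = np.random.default_rng(13)
        profile = 8000.0 + 40000 * gauss_profile(24, 12.3) + rng.normal(0, 200, 24)
        outside = rng.normal(100, 10, 60)
        bg, cyt, foc, cnt = decompose_cell(profile, outside, 8)
        assert bg + cyt + foc == pytest.approx(profile.sum(), rel=1e-9)

    def test_offset_moves_background_not_foci(self):
        rng = np.random.default_rng(17)
        noise_prof = rng.normal(0, 150, 28)
        noise_out = rng.normal(0, 12, 60)
        base_prof = 9000.0 + 60000 * gauss_profile(28, 14.0) + noise_prof
        base_out = 100.0 + noise_out
        bg0, _, foc0, _ = decompose_cell(base_prof, base_out, 8)
        bg1, _, foc1, _ = decompose_cell(base_prof + 8 * 50.0, base_out + 50.0, 8)
        assert bg1 / (8 * 28) - bg0 / (8 * 28) == pytest.approx(50.0, abs=2.0)
        assert foc1 == pytest.approx(foc0, rel=0.05)

    @pytest.mark.parametrize("sep", [0.0, 2.0, 5.0, 8.0, 10.0])
    def test_two_focus_flux_recovery(self, sep):
        # cytoplasm floor + two sister foci: total focal flux within 10%
        n = 30
        prof = 250000 * blurred_rect(n, 3, 27)
        prof += 90000 * gauss_profile(n, 15 - sep / 2) + 94000 * gauss_profile(n, 15 + sep / 2)
        bg, cyt, foc, cnt = decompose_cell(prof, np.zeros(50), 8)
        assert foc == pytest.approx(184000, rel=0.10)
        if sep >= 5.0:
            assert cnt == 2

    def test_bound_fraction_recovery_with_noise(self):
        # half the content focal: recovered fraction in a generous band
        rng = np.random.default_rng(19)
        n = 26
        diffuse, focal = 200000.0, 200000.0
        prof = diffuse * blurred_rect(n, 3, 23) + focal * gauss_profile(n, 13.2)
        prof = 20.0 * rng.poisson(np.maximum(prof, 0) / 20.0)
        bg, cyt, foc, cnt = decompose_cell(prof, rng.normal(0, 5, 50), 8)
        assert 0.42 <= foc / (foc + cyt) <= 0.58

    def test_degenerate_inputs(self):
        with pytest.raises(DataError):
            decompose_cell(np.array([1.0]), np.ones(10), 8)
        with pytest.raises(DataError):
            decompose_cell(np.ones(10), np.array([]), 8)


def _mk_trace(foci_counts, foci=None, n=20, birth_len=14.0, growth=2.0, edge=False):
    frames = np.arange(n)
    foci_arr = np.asarray(foci, dtype=float) if foci is not None else (
        np.asarray(foci_counts, dtype=float) * 1e5
    )
    lengths = birth_len * growth ** (frames / (n - 1))
    tr = CellCycleTrace(
        cell_id="t", channel=0, frames=frames,
        row0=np.full(n, 2.0), row1=2.0 + lengths,
        background_per_px=np.zeros(n), cytoplasm=np.full(n, 1e5),
        foci=foci_arr, foci_count=np.asarray(foci_counts, dtype=int),
    )
    tr.flags["touches_movie_edge"] = edge
    return tr


class TestSelection:
    def test_truncated_trace_fails_completeness(self):
        tr = _mk_trace([0] * 20, edge=True)
        report = select_cells([tr], expected_birth_length_px=14.0)
        assert tr.flags["complete"] is False
        assert report["rejections"]["complete"] == 1

    def test_focus_in_first_frame_fails_diffuse_start(self):
        counts = [1] * 12 + [0] * 8
        tr = _mk_trace(counts)
        select_cells([tr], expected_birth_length_px=14.0)
        assert tr.flags["diffuse_ends"] is False

    def test_clean_cycle_selected(self):
        counts = [0, 0] + [1] * 14 + [0] * 4
        foci = [0, 0] + [1e5] * 14 + [0, 0, 0, 0]
        tr = _mk_trace(counts, foci=foci)
        report = select_cells([tr], expected_birth_length_px=14.0)
        assert tr.selected
        assert report["n_selected"] == 1

    def test_wrong_length_rejected(self):
        tr = _mk_trace([0] * 20, birth_len=40.0)
        select_cells([tr], expected_birth_length_px=14.0)
        assert tr.flags["length"] is False

    def test_poor_growth_rejected(self):
        tr = _mk_trace([0] * 20, growth=1.1)
        select_cells([tr], expected_birth_length_px=14.0)
        assert tr.flags["growth"] is False
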