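"""Quantification of long fluorescence time-lapse stacks.

The stages mirror the standard mother-machine workflow: rolling-ball
background subtraction, flat-field (beam-profile) correction, integer-pixel
drift correction against a fiducial marker, per-channel kymographs (the sum
of pixel intensities perpendicular to the channel per frame), cell-cycle
segmentation from the mother cell's pole positions, quality selection, and a
per-frame decomposition of each cell's fluorescence into background,
cytoplasm and focal (DNA-bound) components.

Decomposition convention: the background level is the robust per-pixel level
outside the cell.  Candidate focus runs are positions of the
background-subtracted summed line profile significantly above the cytoplasmic
floor (contiguous runs over a robust threshold); the focal intensity is then
measured by a non-negative least-squares fit of a flat cytoplasm floor plus
up to two fixed-width Gaussian components at the profile peaks, so the
cytoplasm under a focus stays with the cytoplasm and the PSF tails of the
focus are counted with the focus.  The three components sum exactly to the
raw in-cell total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import nnls
from scipy.signal import find_peaks
from scipy.special import ndtr
from skimage.filters import threshold_isodata
from skimage.restoration import rolling_ball

from .core import ConfigError, DataError, ImageStack

__all__ = [
    "Kymograph",
    "CellCycleTrace",
    "DecompositionSettings",
    "subtract_background",
    "correct_illumination",
    "correct_drift",
    "build_kymograph",
    "segment_channel_poles",
    "segment_cycles",
    "select_cells",
    "decompose_cell",
]


class TrackingError(RuntimeError):
    """Fiducial lost during drift correction."""


@dataclass
class Kymograph:
    """Summed intensity along a growth channel versus time.

    ``data[t, r]`` is the sum of frame ``t`` over the channel's column band at
    row ``r``.
    """

    data: np.ndarray
    channel_cols: tuple[int, int]
    band_width: int
    stack_id: str = ""


@dataclass
class CellCycleTrace:
    """Per-frame decomposition of one cell cycle (birth to division)."""

    cell_id: str
    channel: int
    frames: np.ndarray            # absolute frame indices, birth..division-1
    row0: np.ndarray
    row1: np.ndarray
    background_per_px: np.ndarray
    cytoplasm: np.ndarray         # counts
    foci: np.ndarray              # counts
    foci_count: np.ndarray        # 0/1/2 per frame
    init_frame: int | None = None
    term_frame: int | None = None
    flags: dict = field(default_factory=dict)
    selected: bool = False

    @property
    def length_px(self) -> np.ndarray:
        return self.row1 - self.row0

    @property
    def total(self) -> np.ndarray:
        """Background-subtracted in-cell intensity (cytoplasm + foci)."""
        return self.cytoplasm + self.foci


@dataclass(frozen=True)
class DecompositionSettings:
    """Thresholds of the foci/cytoplasm separation.

    ``k_mad``: a profile position opens a focus run when it exceeds the
    cytoplasmic median by more than ``k_mad`` robust standard deviations.
    ``dilate_px``: accepted runs are widened by this many pixels per side to
    capture the PSF tails below the significance threshold.
    ``min_run_px``: runs narrower than a PSF core are rejected as noise.
    ``edge_exclude_px``: pole rows excluded from the cytoplasm-level estimate
    (the PSF roll-off there underestimates the mid-cell floor).
    """

    k_mad: float = 3.0
    dilate_px: int = 2
    min_run_px: int = 2
    max_foci: int = 2
    edge_exclude_px: int = 5
    psf_sigma_px: float = 1.3


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


def subtract_background(frame: np.ndarray, ball_radius_px: float = 15.0) -> np.ndarray:
    """Remove smooth background with a rolling-ball filter; clip at zero.

    The radius must be large against the PSF (so compact spots are preserved)
    and small against the frame; 15 px ~ 11 PSF sigma at defaults.
    """
    if ball_radius_px <= 0:
        raise ConfigError(f"ball radius must be > 0, got {ball_radius_px}")
    frame = np.asarray(frame, dtype=float)
    bg = rolling_ball(frame, radius=ball_radius_px)
    return np.clip(frame - bg, 0.0, None)


def correct_illumination(frame: np.ndarray, beam_profile: np.ndarray) -> np.ndarray:
    """Flat-field a frame by the normalized (max 1) illumination profile."""
    beam = np.asarray(beam_profile, dtype=float)
    frame = np.asarray(frame, dtype=float)
    if beam.shape != frame.shape:
        raise DataError(f"beam profile shape {beam.shape} != frame shape {frame.shape}")
    if not np.all(np.isfinite(beam)) or np.any(beam <= 0):
        raise DataError("beam profile must be strictly positive and finite")
    return frame / (beam / beam.max())


def _fiducial_position(frame: np.ndarray, region: tuple[int, int, int, int]) -> tuple[float, float, float]:
    r0, r1, c0, c1 = region
    crop = ndimage.gaussian_filter(np.asarray(frame[r0:r1, c0:c1], dtype=float), 1.0)
    idx = np.unravel_index(int(np.argmax(crop)), crop.shape)
    peak = crop[idx]
    floor = np.median(crop)
    mad = np.median(np.abs(crop - floor)) * 1.4826
    # subpixel refinement: flux-weighted centroid of the significant excess
    # (a marker sitting on a pixel boundary would otherwise flip its argmax)
    w = np.clip(crop - (floor + 3.0 * mad), 0.0, None)
    if w.sum() > 0:
        rr, cc = np.mgrid[0: crop.shape[0], 0: crop.shape[1]]
        pos = (float((w * rr).sum() / w.sum()), float((w * cc).sum() / w.sum()))
    else:
        pos = (float(idx[0]), float(idx[1]))
    return pos[0] + r0, pos[1] + c0, (peak - floor) / max(mad, 1e-12)


def correct_drift(
    stack: ImageStack,
    fiducial_search_region: tuple[int, int, int, int],
    min_snr: float = 5.0,
    extra: list[ImageStack] | None = None,
) -> tuple[ImageStack, np.ndarray]:
    """Integer-pixel drift correction by tracking a fiducial marker.

    The fiducial is the brightest (smoothed) peak in the search region
    ``(r0, r1, c0, c1)``; every frame is shifted so the peak returns to its
    frame-0 position.  Stacks in ``extra`` (e.g. the brightfield channel,
    already aligned to the fluorescence) receive the same shifts.
    """
    px = np.asarray(stack.pixels, dtype=float)
    n = px.shape[0]
    shifts = np.zeros((n, 2), dtype=int)
    r_ref, c_ref, snr = _fiducial_position(px[0], fiducial_search_region)
    if snr < min_snr:
        raise TrackingError(f"fiducial not found in frame 0 (snr {snr:.1f})")
    out = np.empty_like(px)
    extra_out = [np.empty_like(np.asarray(e.pixels, dtype=float)) for e in (extra or [])]
    for f in range(n):
        r, c, snr = _fiducial_position(px[f], fiducial_search_region)
        if snr < min_snr:
            raise TrackingError(f"fiducial lost at frame {f} (snr {snr:.1f})")
        shift = (int(round(r_ref - r)), int(round(c_ref - c)))
        shifts[f] = shift
        out[f] = np.roll(px[f], shift, axis=(0, 1))
        for e_in, e_arr in zip(extra or [], extra_out):
            e_arr[f] = np.roll(np.asarray(e_in.pixels[f], dtype=float), shift, axis=(0, 1))
    corrected = ImageStack(out, stack.pixel_size_nm, stack.frame_interval_s, stack.exposure_s)
    for e_in, e_arr in zip(extra or [], extra_out):
        e_in.pixels = e_arr
    return corrected, shifts


def align_channels(reference: np.ndarray, other: np.ndarray, max_shift: int = 4) -> tuple[int, int]:
    """Integer-pixel alignment of two channels by cross-correlation."""
    best, best_shift = -np.inf, (0, 0)
    ref = reference - reference.mean()
    for dr in range(-max_shift, max_shift + 1):
        for dc in range(-max_shift, max_shift + 1):
            rolled = np.roll(other, (dr, dc), axis=(0, 1))
            score = float((ref * (rolled - rolled.mean())).sum())
            if score > best:
                best, best_shift = score, (dr, dc)
    return best_shift


# ---------------------------------------------------------------------------
# kymographs and cycle segmentation
# ---------------------------------------------------------------------------


def build_kymograph(
    stack: ImageStack,
    channel_cols: tuple[int, int],
    rows: tuple[int, int] | None = None,
) -> Kymograph:
    """Sum each frame over the channel-perpendicular axis (columns)."""
    c0, c1 = channel_cols
    if c1 <= c0 or c0 < 0 or c1 > stack.shape[2]:
        raise ConfigError(f"empty or out-of-range channel region {channel_cols}")
    px = stack.pixels
    if rows is not None:
        px = px[:, rows[0]: rows[1], :]
    data = px[:, :, c0:c1].sum(axis=2)
    return Kymograph(data=np.asarray(data, dtype=float), channel_cols=(c0, c1),
                     band_width=c1 - c0)


def segment_channel_poles(
    brightfield: ImageStack,
    channel_cols: tuple[int, int],
    channel_length_px: int,
    min_length_px: int = 4,
) -> np.ndarray:
    """Mother-cell pole positions per frame from the brightfield proxy.

    Cells are dark on a bright background; the row profiles are thresholded
    with isodata (one global threshold per channel, midway between the dark
    and bright class means) and the connected dark run nearest the
    channel's dead end (row 0) is the mother.  Returns an ``(n_frames, 2)``
    array of half-open ``[top, bottom)`` row intervals (NaN when no cell).
    """
    c0, c1 = channel_cols
    band = np.asarray(brightfield.pixels[:, :channel_length_px, c0:c1], dtype=float)
    profiles = band.mean(axis=2)  # (frame, row) mean over the channel width
    thresh = threshold_isodata(profiles.ravel())
    poles = np.full((band.shape[0], 2), np.nan)
    for f in range(band.shape[0]):
        dark = profiles[f] < thresh
        labels, n_lab = ndimage.label(dark)
        for lab in range(1, n_lab + 1):
            rows = np.flatnonzero(labels == lab)
            if len(rows) >= min_length_px and rows[0] <= 6:
                poles[f] = (rows[0], rows[-1] + 1)
                break
    return poles


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open index runs of True values."""
    out = []
    m = np.concatenate([[False], mask, [False]])
    starts = np.flatnonzero(~m[:-1] & m[1:])
    ends = np.flatnonzero(m[:-1] & ~m[1:])
    for s, e in zip(starts, ends):
        out.append((int(s), int(e)))
    return out


def decompose_cell(
    profile: np.ndarray,
    outside_pixels: np.ndarray,
    band_width: int,
    settings: DecompositionSettings = DecompositionSettings(),
) -> tuple[float, float, float, int]:
    """Split one cell-frame's summed line profile into its three components.

    Parameters
    ----------
    profile : array
        Summed line profile over the cell interval (one value per row along
        the channel, each the sum over ``band_width`` columns).
    outside_pixels : array
        Per-pixel intensities sampled outside the cell (same preprocessing).
    band_width : int
        Number of columns summed into each profile value.

    Returns
    -------
    (background_total, cytoplasm, foci, foci_count); the three intensity
    components sum exactly to ``profile.sum()``.
    """
    profile = np.asarray(profile, dtype=float)
    if profile.size < 2:
        raise DataError("cell narrower than 2 px")
    outside_pixels = np.asarray(outside_pixels, dtype=float)
    if outside_pixels.size == 0:
        raise DataError("empty outside-cell sample")

    bg_per_px = float(np.median(outside_pixels))
    corrected = profile - bg_per_px * band_width
    n = profile.size

    def find_runs(threshold: float) -> list[tuple[int, int]]:
        mask = corrected > threshold
        runs = [r for r in _runs(mask) if r[1] - r[0] >= settings.min_run_px]
        # widen to capture PSF tails, then merge overlaps
        widened = [
            (max(r[0] - settings.dilate_px, 0), min(r[1] + settings.dilate_px, n))
            for r in runs
        ]
        merged: list[tuple[int, int]] = []
        for r in sorted(widened):
            if merged and r[0] <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], r[1]))
            else:
                merged.append(r)
        return merged

    # interior rows: the PSF roll-off at the cell poles is not representative
    # of the mid-cell cytoplasm floor
    e = settings.edge_exclude_px if n > 2 * settings.edge_exclude_px + 6 else (
        2 if n > 10 else 0
    )
    interior = np.zeros(n, dtype=bool)
    interior[e: n - e if e else n] = True
    body = corrected[interior]

    # seed the cytoplasm level from the lower body of the profile: with two
    # separated sister foci the focal rows can be the majority, which would
    # wreck a plain median/MAD estimate
    level = float(np.percentile(body, 25))
    low = body[body <= np.percentile(body, 50)]
    noise = float(np.median(np.abs(low - level))) * 1.4826
    peak = float(body.max())

    def threshold(level: float, noise: float) -> float:
        # noise floor for empty cells; peak-relative for bright foci whose
        # wings would otherwise contaminate the noise estimate
        return level + max(settings.k_mad * noise, 0.2 * (peak - level))

    runs = find_runs(threshold(level, noise))

    foci = 0.0
    n_foci = 0
    if runs:
        # In a short cell the PSF tails of the foci reach every remaining
        # row, so no row set yields an uncontaminated cytoplasm level.
        # Decompose instead by non-negative least squares: a flat cytoplasm
        # floor plus up to ``max_foci`` fixed-width Gaussians at the profile
        # peaks; the fitted Gaussian fluxes (tails included) are the foci.
        env0, env1 = runs[0][0], runs[-1][1]
        centers = _peak_positions(
            corrected, env0, env1, settings.max_foci, settings.psf_sigma_px
        )
        basis = [np.ones(n)[interior]]
        edges = np.arange(n + 1, dtype=float)
        for c in centers:
            # pair each centre with a wider component: two sister foci merged
            # below the peak-splitting distance read as one broadened spot
            for sig in (settings.psf_sigma_px, 1.6 * settings.psf_sigma_px):
                g = np.diff(ndtr((edges - (c + 0.5)) / sig))
                basis.append(g[interior])
        a_mat = np.column_stack(basis)
        coef, _ = nnls(a_mat, corrected[interior])
        per_center = coef[1:].reshape(-1, 2).sum(axis=1)
        # significance gate: a fitted flux must exceed the noise of a few
        # profile rows, otherwise it is a noise excursion, not a focus
        significant = per_center >= 10.0 * max(noise, 1e-12)
        if significant.any():
            foci = float(per_center[significant].sum())
            foci = float(np.clip(foci, 0.0, max(corrected.sum(), 0.0)))
            n_foci = min(int(significant.sum()), settings.max_foci)
        else:
            foci, n_foci = 0.0, 0
    cytoplasm = float(corrected.sum()) - foci
    background_total = bg_per_px * band_width * profile.size
    return background_total, cytoplasm, foci, n_foci


def _peak_positions(
    corrected: np.ndarray, env0: int, env1: int, max_peaks: int, sigma: float
) -> list[float]:
    """Subpixel positions of up to ``max_peaks`` local maxima in [env0, env1).

    Peaks are located on a lightly smoothed profile so that the positions do
    not chase positive noise excursions (which would bias the fitted flux).
    """
    smooth = ndimage.gaussian_filter1d(corrected, 1.0)
    seg = smooth[env0:env1]
    peaks, props = find_peaks(seg, distance=max(int(2 * sigma), 2))
    if len(peaks) == 0:
        peaks = np.array([int(np.argmax(seg))])
    order = np.argsort(seg[peaks])[::-1]
    out = []
    for p in peaks[order][:max_peaks]:
        i = int(p) + env0
        # parabolic subpixel refinement
        if 0 < i < len(corrected) - 1:
            y0, y1, y2 = smooth[i - 1: i + 2]
            denom = y0 - 2 * y1 + y2
            delta = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
            out.append(i + float(np.clip(delta, -1.0, 1.0)))
        else:
            out.append(float(i))
    return out


def _detect_replication_window(
    foci_int: np.ndarray, foci_count: np.ndarray, persist: int = 2
) -> tuple[int | None, int | None]:
    """Initiation/termination frames from the foci-intensity trace.

    Frames with a detected focus define candidate replication; the window is
    then delimited by the half-maximum crossings of the foci intensity, which
    cancels the detection lag between the fast exponential rise after
    initiation and the slow decay after termination.  A crossing must persist
    ``persist`` consecutive frames.
    """
    detected = foci_count > 0
    if detected.sum() < persist:
        return None, None
    plateau = float(np.median(foci_int[detected]))
    if plateau <= 0:
        return None, None
    above = foci_int > 0.5 * plateau
    runs = [r for r in _runs(above) if r[1] - r[0] >= persist]
    if not runs:
        return None, None
    return runs[0][0], runs[-1][1] - 1


def segment_cycles(
    kymo: Kymograph,
    poles: np.ndarray,
    channel: int = 0,
    outside_margin_px: int = 4,
    pole_pad_px: int = 3,
    division_drop: float = 0.25,
    min_cycle_frames: int = 6,
    channel_length_px: int | None = None,
    settings: DecompositionSettings = DecompositionSettings(),
) -> list[CellCycleTrace]:
    """Cut the mother-cell record into cell cycles and decompose each frame.

    Division is a drop of more than ``division_drop`` in mother length between
    consecutive frames.  Frames of each cycle are decomposed with
    :func:`decompose_cell`; initiation/termination are the half-maximum
    crossings of the foci-intensity trace.  Cycles overlapping the movie ends
    are returned but flagged incomplete.  A movie with no foci yields cycles
    with undefined initiation/termination.
    """
    n_frames = kymo.data.shape[0]
    n_rows = kymo.data.shape[1] if channel_length_px is None else channel_length_px
    lengths = poles[:, 1] - poles[:, 0]
    valid = np.isfinite(lengths)
    if valid.sum() < min_cycle_frames:
        return []

    # division events: sharp relative drop in mother length
    div_frames = [0]
    for f in range(1, n_frames):
        if valid[f] and valid[f - 1] and lengths[f] < (1.0 - division_drop) * lengths[f - 1]:
            div_frames.append(f)
    div_frames.append(n_frames)

    traces: list[CellCycleTrace] = []
    for i in range(len(div_frames) - 1):
        f0, f1 = div_frames[i], div_frames[i + 1]
        frames = np.arange(f0, f1)
        frames = frames[valid[f0:f1]]
        if len(frames) < min_cycle_frames:
            continue
        bg_l, cyt_l, foc_l, cnt_l, r0_l, r1_l = [], [], [], [], [], []
        for f in frames:
            r0, r1 = int(poles[f, 0]), int(poles[f, 1])
            # pad past the detected poles so the PSF-blurred cell edge is
            # integrated with the cell rather than lost to the background
            p0 = max(r0 - pole_pad_px, 0)
            p1 = min(r1 + pole_pad_px, n_rows)
            profile = kymo.data[f, p0:p1]
            lo = max(p1 + outside_margin_px, 0)
            outside = kymo.data[f, lo:n_rows] / kymo.band_width
            if p0 > outside_margin_px:
                outside = np.concatenate([kymo.data[f, : p0 - outside_margin_px] / kymo.band_width, outside])
            bg, cyt, foc, cnt = decompose_cell(profile, outside, kymo.band_width, settings)
            bg_l.append(bg / (kymo.band_width * (p1 - p0)))
            cyt_l.append(cyt)
            foc_l.append(foc)
            cnt_l.append(cnt)
            r0_l.append(r0)
            r1_l.append(r1)
        foci_int = np.asarray(foc_l)
        init_f, term_f = _detect_replication_window(foci_int, np.asarray(cnt_l))
        trace = CellCycleTrace(
            cell_id=f"ch{channel:02d}_cyc{i:03d}",
            channel=channel,
            frames=frames,
            row0=np.asarray(r0_l, dtype=float),
            row1=np.asarray(r1_l, dtype=float),
            background_per_px=np.asarray(bg_l),
            cytoplasm=np.asarray(cyt_l),
            foci=foci_int,
            foci_count=np.asarray(cnt_l, dtype=int),
            init_frame=None if init_f is None else int(frames[init_f]),
            term_frame=None if term_f is None else int(frames[term_f]),
        )
        trace.flags["touches_movie_edge"] = (f0 == 0) or (f1 == n_frames)
        traces.append(trace)
    return traces


def select_cells(
    traces: list[CellCycleTrace],
    expected_birth_length_px: float,
    length_band: tuple[float, float] = (0.5, 2.0),
    min_elongation: float = 1.4,
    diffuse_end_frames: int = 2,
    diffuse_fraction: float = 0.2,
) -> dict:
    """Flag traces on the four quality criteria and mark all-pass traces.

    Criteria: birth length inside ``length_band`` times the expected birth
    length; relative elongation at least ``min_elongation``; a complete cycle
    (not clipped by the movie ends); and a fluorescence signal that is diffuse
    in the first and last ``diffuse_end_frames`` frames — focal intensity
    below ``diffuse_fraction`` of the cycle's plateau focal intensity (the
    few bound clamps that have not yet unloaded still read as diffuse).
    Returns a report with per-criterion rejection counts.
    """
    rejections = dict(length=0, growth=0, complete=0, diffuse_ends=0)
    for tr in traces:
        birth_len = float(tr.length_px[0])
        ok_len = (
            length_band[0] * expected_birth_length_px
            <= birth_len
            <= length_band[1] * expected_birth_length_px
        )
        ok_growth = float(tr.length_px[-1]) >= min_elongation * birth_len
        ok_complete = not tr.flags.get("touches_movie_edge", False)
        k = diffuse_end_frames
        detected = tr.foci_count > 0
        plateau = float(np.median(tr.foci[detected])) if detected.any() else 0.0
        lim = diffuse_fraction * plateau
        ok_diffuse = bool(np.all(tr.foci[:k] <= lim) and np.all(tr.foci[-k:] <= lim))
        if plateau == 0.0:
            ok_diffuse = True
        tr.flags.update(
            length=ok_len, growth=ok_growth, complete=ok_complete, diffuse_ends=ok_diffuse
        )
        tr.selected = ok_len and ok_growth and ok_complete and ok_diffuse
        for key, ok in zip(rejections, (ok_len, ok_growth, ok_complete, ok_diffuse)):
            if not ok:
                rejections[key] += 1
    return dict(
        n_traces=len(traces),
        n_selected=sum(t.selected for t in traces),
        rejections=rejections,
    )
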