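"""Single-molecule dwell-time analysis of PALM movies.

Sparse photoactivated molecules are detected per frame with an a-trous
(undecimated) B3-spline wavelet detector, linked into traces, filtered to
clean single-step disappearances, and the distribution of on-times (frames
from activation to disappearance) is fitted with an interval/right-censored
exponential.  Because a molecule vanishes either by unloading from DNA or by
photobleaching — independent exponential competing risks — the observed
disappearance rate is the sum of the two, and the unloading time follows by
subtracting the bleaching rate measured in a fast (bleaching-dominated)
movie, scaled from illumination time to wall-clock time by the duty cycle:

    1/t_obs = 1/t_unload + 1/t_bleach_wall,
    t_bleach_wall = t_bleach_exposure / (exposure / frame_interval).

Confidence intervals come from case-resampling the on-time set and repeating
the fit and correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import ConfigError, DataError, ImageStack

__all__ = [
    "SpotTrace",
    "OnTimeSet",
    "UnloadEstimate",
    "UnloadingModel",
    "detect_spots",
    "build_traces",
    "filter_single_step",
    "fit_on_times",
    "bleach_time",
    "unloading_time",
]


class FittingError(RuntimeError):
    """Dwell-time fit impossible on the given data."""


class EstimationError(RuntimeError):
    """Unloading unresolvable (bleaching-dominated observations)."""


# ---------------------------------------------------------------------------
# wavelet spot detection
# ---------------------------------------------------------------------------

_B3 = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0


def _atrous_planes(frame: np.ndarray, levels: int) -> list[np.ndarray]:
    """Detail planes W_1..W_levels of the a-trous B3-spline decomposition."""
    approx = np.asarray(frame, dtype=float)
    planes = []
    for j in range(levels):
        kernel = np.zeros(4 * 2**j + 1)
        kernel[:: 2**j] = _B3
        sm = ndimage.convolve1d(approx, kernel, axis=0, mode="reflect")
        sm = ndimage.convolve1d(sm, kernel, axis=1, mode="reflect")
        planes.append(approx - sm)
        approx = sm
    return planes


def detect_spots(
    frame: np.ndarray,
    levels: int = 3,
    threshold_k: float = 3.0,
    min_area_px: int = 5,
    aperture_radius_px: int | None = None,
    background: float | None = None,
) -> pd.DataFrame:
    """Detect diffraction-limited spots in one (preprocessed) frame.

    The detection mask is the product of the hard-thresholded detail planes
    (each plane thresholded at ``threshold_k`` robust standard deviations,
    estimated by the plane's MAD); the finest plane is excluded as pure
    noise.  Spot intensity is the sum of background-subtracted pixel values
    over the connected detection region, or over a square aperture of radius
    ``aperture_radius_px`` around the centroid when given (aperture
    photometry captures the PSF tails the mask misses).

    Returns a DataFrame with columns row, col, intensity, area.
    """
    frame = np.asarray(frame, dtype=float)
    if not np.all(np.isfinite(frame)):
        raise DataError("frame contains non-finite pixels")
    planes = _atrous_planes(frame, levels)
    mask = np.ones(frame.shape, dtype=bool)
    for plane in planes[1:]:
        sd = np.median(np.abs(plane - np.median(plane))) * 1.4826
        mask &= plane > threshold_k * max(sd, 1e-12)
    labels, n_lab = ndimage.label(mask)
    global_bg = float(np.median(frame)) if background is None else background
    rows = []
    for lab in range(1, n_lab + 1):
        region = labels == lab
        if region.sum() < min_area_px:
            continue
        rr, cc = np.nonzero(region)
        w = np.clip(frame[rr, cc] - global_bg, 0.0, None)
        if w.sum() <= 0:
            continue
        r_c = float(np.average(rr, weights=w))
        c_c = float(np.average(cc, weights=w))
        if aperture_radius_px is None:
            intensity = float((frame[region] - global_bg).sum())
        else:
            # aperture photometry with local background from the surrounding
            # annulus (unbiased when the global background is structured)
            a = aperture_radius_px
            ri, ci = int(round(r_c)), int(round(c_c))
            r0, r1 = max(ri - a, 0), min(ri + a + 1, frame.shape[0])
            c0, c1 = max(ci - a, 0), min(ci + a + 1, frame.shape[1])
            b = a + 3
            rb0, rb1 = max(ri - b, 0), min(ri + b + 1, frame.shape[0])
            cb0, cb1 = max(ci - b, 0), min(ci + b + 1, frame.shape[1])
            ring = frame[rb0:rb1, cb0:cb1].copy()
            ring[(r0 - rb0): (r1 - rb0), (c0 - cb0): (c1 - cb0)] = np.nan
            # ring mean, not median: shot noise is skewed, so the median of
            # the annulus underestimates the background level
            local_bg = float(np.nanmean(ring)) if np.isfinite(ring).any() else global_bg
            box = frame[r0:r1, c0:c1]
            intensity = float(box.sum() - local_bg * box.size)
        rows.append(dict(row=r_c, col=c_c, intensity=intensity, area=int(region.sum())))
    return pd.DataFrame(rows, columns=["row", "col", "intensity", "area"])


# ---------------------------------------------------------------------------
# traces
# ---------------------------------------------------------------------------


@dataclass
class SpotTrace:
    """One molecule's integrated-intensity time series."""

    cell_id: int
    row: float
    col: float
    first_frame: int
    last_frame: int
    intensities: np.ndarray
    frame_interval_s: float
    censored: bool = False
    in_cell: bool = True
    single_step: bool | None = None

    @property
    def on_time_s(self) -> float:
        return (self.last_frame - self.first_frame + 1) * self.frame_interval_s

    @property
    def n_frames_on(self) -> int:
        return self.last_frame - self.first_frame + 1


def _aperture_intensity(frame: np.ndarray, row: float, col: float, a: int = 4) -> float:
    """Background-subtracted aperture sum at a fixed position (annulus bg)."""
    frame = np.asarray(frame, dtype=float)
    ri, ci = int(round(row)), int(round(col))
    r0, r1 = max(ri - a, 0), min(ri + a + 1, frame.shape[0])
    c0, c1 = max(ci - a, 0), min(ci + a + 1, frame.shape[1])
    b = a + 3
    rb0, rb1 = max(ri - b, 0), min(ri + b + 1, frame.shape[0])
    cb0, cb1 = max(ci - b, 0), min(ci + b + 1, frame.shape[1])
    ring = frame[rb0:rb1, cb0:cb1].copy()
    ring[(r0 - rb0): (r1 - rb0), (c0 - cb0): (c1 - cb0)] = np.nan
    local_bg = float(np.nanmean(ring)) if np.isfinite(ring).any() else float(np.median(frame))
    box = frame[r0:r1, c0:c1]
    return float(box.sum() - local_bg * box.size)


def _inside_cell(row: float, col: float, cells: list[tuple[float, float, float, float]]) -> int:
    for i, (r0, r1, c0, c1) in enumerate(cells):
        if r0 <= row < r1 and c0 <= col < c1:
            return i
    return -1


def build_traces(
    stack: ImageStack,
    cells: list[tuple[float, float, float, float]],
    first_frame: int = 1,
    gate_radius_px: float = 3.0,
    gap_frames: int = 2,
    tail_frames: int = 4,
    aperture_radius_px: int = 4,
    detect_kwargs: dict | None = None,
) -> list[SpotTrace]:
    """Link per-frame detections into single-molecule traces.

    Detections are associated to open traces by nearest position within
    ``gate_radius_px``; a trace ends at the first of ``gap_frames``
    consecutive frames without a detection (blinking shorter than the gap is
    bridged).  Spots outside every cell rectangle are rejected.  Traces still
    visible in the last frame are right-censored.
    """
    detect_kwargs = dict(detect_kwargs or {})
    n = stack.n_frames
    open_traces: list[dict] = []
    done: list[SpotTrace] = []

    def close(tr: dict, censored: bool) -> None:
        done.append(
            SpotTrace(
                cell_id=tr["cell"],
                row=tr["row"],
                col=tr["col"],
                first_frame=tr["first"],
                last_frame=tr["last"],
                intensities=np.asarray(tr["ints"]),
                frame_interval_s=stack.frame_interval_s,
                censored=censored,
                in_cell=tr["cell"] >= 0,
            )
        )

    for f in range(first_frame, n):
        det = detect_spots(stack.pixels[f], **detect_kwargs)
        used = np.zeros(len(det), dtype=bool)
        for tr in open_traces:
            if len(det):
                d = np.hypot(det.row.values - tr["row"], det.col.values - tr["col"])
                d[used] = np.inf
                j = int(np.argmin(d))
                if d[j] <= gate_radius_px:
                    used[j] = True
                    tr["last"] = f
                    tr["miss"] = 0
                    tr["ints"].append(float(det.intensity.values[j]))
                    continue
            tr["miss"] += 1
        still_open = []
        for tr in open_traces:
            if tr["miss"] >= gap_frames:
                close(tr, censored=False)
            else:
                still_open.append(tr)
        open_traces = still_open
        for j in range(len(det)):
            if not used[j]:
                r, c = float(det.row.values[j]), float(det.col.values[j])
                open_traces.append(
                    dict(
                        cell=_inside_cell(r, c, cells), row=r, col=c, first=f, last=f,
                        miss=0, ints=[float(det.intensity.values[j])],
                    )
                )
    for tr in open_traces:
        close(tr, censored=tr["last"] >= n - 1)
    done = [t for t in done if t.in_cell]
    # photometry pass: fixed-position aperture intensity from first frame to
    # a few frames past disappearance, so the single-step filter sees the
    # drop to background
    for t in done:
        f_hi = min(t.last_frame + 1 + tail_frames, n)
        t.intensities = np.array(
            [
                _aperture_intensity(stack.pixels[f], t.row, t.col, aperture_radius_px)
                for f in range(t.first_frame, f_hi)
            ]
        )
    return done


def filter_single_step(
    trace: np.ndarray | SpotTrace,
    f_ratio_max: float = 3.0,
    residual_floor_fraction: float = 0.25,
) -> bool:
    """Accept traces that are flat then drop once to near background.

    Fits 1-step and 2-step piecewise-constant models by least squares; the
    trace passes when the extra step does not improve the residual variance
    beyond ``f_ratio_max`` and the single step is downward, to below
    ``residual_floor_fraction`` of the initial plateau.  Traces shorter than
    3 frames cannot be classified and are rejected.
    """
    y = np.asarray(trace.intensities if isinstance(trace, SpotTrace) else trace, dtype=float)
    n = len(y)
    if n < 3:
        return False
    cum = np.concatenate([[0.0], np.cumsum(y)])
    cum2 = np.concatenate([[0.0], np.cumsum(y * y)])

    def sse(i, j):  # residual sum of squares of a constant fit on y[i:j]
        if j <= i:
            return 0.0
        s, s2 = cum[j] - cum[i], cum2[j] - cum2[i]
        return s2 - s * s / (j - i)

    best1, best_cp = np.inf, None
    for cp in range(1, n):
        r = sse(0, cp) + sse(cp, n)
        if r < best1:
            best1, best_cp = r, cp
    best2 = np.inf
    for cp1 in range(1, n - 1):
        left = sse(0, cp1)
        for cp2 in range(cp1 + 1, n):
            r = left + sse(cp1, cp2) + sse(cp2, n)
            best2 = min(best2, r)

    plateau = float(np.mean(y[:best_cp]))
    floor = float(np.mean(y[best_cp:]))
    if plateau <= 0 or floor >= residual_floor_fraction * plateau:
        return False
    dof1, dof2 = max(n - 2, 1), max(n - 3, 1)
    if best2 < np.inf and best2 > 0:
        f_ratio = (best1 / dof1) / (best2 / dof2)
        if f_ratio > f_ratio_max:
            return False
    return True


def measure_on_times(
    stack: ImageStack,
    cells: list[tuple[float, float, float, float]],
    exposure_s: float,
    min_frames: int = 1,
    **trace_kwargs,
) -> "OnTimeSet":
    """Movie-to-on-times convenience: detect, link, filter, collect.

    The single-step filter is applied to uncensored traces only (a censored
    molecule never shows its disappearance step).
    """
    traces = build_traces(stack, cells, **trace_kwargs)
    for t in traces:
        if not t.censored:
            t.single_step = filter_single_step(t)
    kept = [
        t for t in traces
        if t.n_frames_on >= min_frames and (t.censored or t.single_step)
    ]
    movie_length = (stack.n_frames - 1) * stack.frame_interval_s
    return OnTimeSet(
        on_times_s=np.array([t.on_time_s for t in kept]),
        frame_interval_s=stack.frame_interval_s,
        exposure_s=exposure_s,
        censored=np.array([t.censored for t in kept], dtype=bool),
        movie_length_s=movie_length,
    )


# ---------------------------------------------------------------------------
# censored-exponential fitting
# ---------------------------------------------------------------------------


@dataclass
class OnTimeSet:
    """Observed single-molecule on-times.

    On-times are multiples of the frame interval (each event is known only to
    the frame); censored observations ran to the end of the movie.
    """

    on_times_s: np.ndarray
    frame_interval_s: float
    exposure_s: float
    censored: np.ndarray | None = None
    movie_length_s: float | None = None

    def __post_init__(self) -> None:
        self.on_times_s = np.asarray(self.on_times_s, dtype=float)
        if self.censored is None:
            self.censored = np.zeros(len(self.on_times_s), dtype=bool)
        self.censored = np.asarray(self.censored, dtype=bool)
        if len(self.censored) != len(self.on_times_s):
            raise DataError("censored flags must match on_times length")
        frames = self.on_times_s / self.frame_interval_s
        if not np.allclose(frames, np.round(frames), atol=1e-6):
            raise DataError("on-times must be multiples of the frame interval")

    @classmethod
    def from_traces(cls, traces: list[SpotTrace], exposure_s: float,
                    movie_length_s: float | None = None) -> "OnTimeSet":
        kept = [t for t in traces if t.single_step is not False]
        return cls(
            on_times_s=np.array([t.on_time_s for t in kept]),
            frame_interval_s=kept[0].frame_interval_s if kept else 1.0,
            exposure_s=exposure_s,
            censored=np.array([t.censored for t in kept], dtype=bool),
            movie_length_s=movie_length_s,
        )

    @property
    def n(self) -> int:
        return len(self.on_times_s)


def fit_on_times(on_set: OnTimeSet, min_uncensored: int = 10) -> float:
    """ML exponential time constant for interval/right-censored on-times.

    An uncensored on-time of ``k`` frames places the event in
    ``((k-1)*dt, k*dt]``; a censored one contributes the survival beyond its
    recorded time.  With a common frame interval the likelihood is geometric
    and the maximizer is closed-form::

        tau = dt / log(1 + n_u / S),
        S = sum(k_i - 1) over uncensored + sum(t_c / dt) over censored.

    In the fine-frame uncensored limit this reduces to the sample mean.
    """
    dt = on_set.frame_interval_s
    unc = ~on_set.censored
    n_u = int(unc.sum())
    if n_u == 0:
        raise FittingError("all observations are censored")
    if n_u < min_uncensored:
        raise FittingError(f"need >= {min_uncensored} uncensored on-times, got {n_u}")
    k = np.round(on_set.on_times_s[unc] / dt)
    if np.any(k < 1):
        raise FittingError("on-times must be at least one frame")
    s = float(np.sum(k - 1.0)) + float(np.sum(on_set.on_times_s[~unc] / dt))
    if s <= 0:
        # every event in the first frame: tau below resolution
        return dt / math.log1p(float(n_u) / 1e-12)
    return dt / math.log1p(n_u / s)


def bleach_time(
    fast_set: OnTimeSet,
    exposure_s: float,
    duty: float,
) -> float:
    """Wall-clock bleaching time constant of the slow acquisition.

    The fast movie (frames back-to-back, unloading negligible) gives the
    exposure-domain bleaching constant; dividing by the slow movie's duty
    cycle (exposure / frame interval) converts it to the wall-clock constant
    that competes with unloading.
    """
    if not (0.0 < duty <= 1.0):
        raise ConfigError(f"duty cycle must be in (0, 1], got {duty}")
    # refit on the illumination-time axis: k frames -> k * exposure of light
    exp_set = OnTimeSet(
        on_times_s=np.round(fast_set.on_times_s / fast_set.frame_interval_s) * exposure_s,
        frame_interval_s=exposure_s,
        exposure_s=exposure_s,
        censored=fast_set.censored,
        movie_length_s=fast_set.movie_length_s,
    )
    t_exposure = fit_on_times(exp_set)
    return t_exposure / duty


def unloading_time(
    t_obs: float,
    t_bleach_wall: float,
    on_set: OnTimeSet,
    n_bootstrap: int = 10_000,
    seed: int = 0,
) -> "UnloadEstimate":
    """Bleach-corrected unloading time with a bootstrap percentile CI.

    Subtracts the bleaching rate (``1/t_unload = 1/t_obs - 1/t_bleach_wall``)
    and case-resamples the on-time set ``n_bootstrap`` times, refitting and
    re-correcting each replicate.
    """
    if not (t_obs < t_bleach_wall):
        raise EstimationError(
            "bleaching-dominated: observed disappearance is not slower than "
            f"bleaching (t_obs={t_obs:.1f} s >= t_bleach_wall={t_bleach_wall:.1f} s)"
        )

    def correct(tobs: np.ndarray | float) -> np.ndarray | float:
        return 1.0 / (1.0 / tobs - 1.0 / t_bleach_wall)

    rng = np.random.default_rng(seed)
    dt = on_set.frame_interval_s
    n = on_set.n
    k = np.round(on_set.on_times_s / dt)
    unc = ~on_set.censored
    boot = np.empty(n_bootstrap)
    idx = rng.integers(0, n, size=(n_bootstrap, n))
    # vectorised closed-form refit per resample
    contrib_s = np.where(unc, k - 1.0, k)  # censored contribute full t/dt
    n_u_mat = unc[idx].sum(axis=1)
    s_mat = contrib_s[idx].sum(axis=1)
    valid = (n_u_mat > 0) & (s_mat > 0)
    tau_obs_b = np.full(n_bootstrap, np.nan)
    tau_obs_b[valid] = dt / np.log1p(n_u_mat[valid] / s_mat[valid])
    resolvable = valid & (tau_obs_b < t_bleach_wall)
    boot = np.full(n_bootstrap, np.nan)
    boot[resolvable] = correct(tau_obs_b[resolvable])
    boot_clean = boot[np.isfinite(boot)]
    ci = (
        tuple(np.percentile(boot_clean, [2.5, 97.5]))
        if len(boot_clean)
        else (np.nan, np.nan)
    )
    return UnloadEstimate(
        t_obs=t_obs,
        t_bleach_wall=t_bleach_wall,
        t_unload=float(correct(t_obs)),
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        n_obs=n,
        n_bootstrap=n_bootstrap,
        seed=seed,
        bootstrap_samples=boot_clean,
    )


@dataclass
class UnloadEstimate:
    """Bleach-corrected unloading-time estimate with bootstrap CI."""

    t_obs: float
    t_bleach_wall: float
    t_unload: float
    ci_low: float
    ci_high: float
    n_obs: int
    n_bootstrap: int
    seed: int
    bootstrap_samples: np.ndarray = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# model / results facade
# ---------------------------------------------------------------------------


class UnloadingModel:
    """Censored-exponential dwell-time model for single-molecule on-times.

    Parameters
    ----------
    on_set : OnTimeSet
        Observed on-times from the slow (unloading) movie.
    t_bleach_wall : float, optional
        Wall-clock bleaching time constant.  Either give it directly (e.g.
        known from the generator) or provide ``fast_set`` plus ``duty`` to
        estimate it from a fast bleaching movie.
    """

    def __init__(
        self,
        on_set: OnTimeSet,
        t_bleach_wall: float | None = None,
        fast_set: OnTimeSet | None = None,
        duty: float | None = None,
    ) -> None:
        if t_bleach_wall is None:
            if fast_set is None or duty is None:
                raise ConfigError("provide t_bleach_wall, or fast_set and duty")
            t_bleach_wall = bleach_time(fast_set, fast_set.exposure_s, duty)
        self.on_set = on_set
        self.t_bleach_wall = float(t_bleach_wall)

    def fit(self, n_bootstrap: int = 10_000, seed: int = 0) -> "UnloadingResults":
        t_obs = fit_on_times(self.on_set)
        est = unloading_time(t_obs, self.t_bleach_wall, self.on_set, n_bootstrap, seed)
        return UnloadingResults(model=self, estimate=est)


@dataclass
class UnloadingResults:
    """Fitted dwell-time results (statsmodels-style facade)."""

    model: UnloadingModel
    estimate: UnloadEstimate

    @property
    def t_unload(self) -> float:
        return self.estimate.t_unload

    @property
    def t_obs(self) -> float:
        return self.estimate.t_obs

    def conf_int(self) -> tuple[float, float]:
        return (self.estimate.ci_low, self.estimate.ci_high)

    def summary(self) -> str:
        e = self.estimate
        lines = [
            "Single-molecule unloading-time fit",
            "=" * 46,
            f"observations (on-times)        {e.n_obs:>10d}",
            f"censored                       {int(self.model.on_set.censored.sum()):>10d}",
            f"observed time constant t_obs   {e.t_obs:>10.1f} s",
            f"bleaching (wall-clock)         {e.t_bleach_wall:>10.1f} s",
            f"unloading time t_unload        {e.t_unload:>10.1f} s",
            f"95% bootstrap CI               [{e.ci_low:.1f}, {e.ci_high:.1f}] s",
            f"bootstrap replicates           {e.n_bootstrap:>10d}",
        ]
        return "\n".join(lines)
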