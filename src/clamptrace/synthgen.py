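"""Synthetic mother-machine microscopy with exact ground truth.

Generates the three kinds of raw data the analysis modules consume:

* long fluorescence + brightfield-proxy time-lapse stacks of rod-shaped cells
  growing and dividing in vertical dead-end channels, with DNA-bound clamp
  foci driven by the birth-death kinetics model, diffuse cytoplasmic signal
  that doubles over the cell cycle, uneven illumination, stage drift with a
  fiducial marker, photobleaching, and Poisson + read noise;
* PALM movies in which sparse single molecules are activated once and imaged
  until they disappear (unloading or bleaching, whichever comes first);
* single-fluorophore calibration fields of isolated PSF spots.

Every stochastic choice is recorded in a :class:`SceneTruth` so each analysis
stage can be tested against exact per-frame ground truth.

Photometry convention: ``unit_intensity`` is the integrated camera counts one
fluorophore contributes per frame; a clamp is a homodimer carrying two
fluorophore fusions, so a focus of ``n`` bound clamps has integrated intensity
``2 n * unit_intensity`` (before illumination shading and bleaching).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .core import ConfigError, ImageStack
from .kinetics import KineticParams, sample_at, simulate_exact

__all__ = [
    "SceneConfig",
    "SceneTruth",
    "TimelapseScene",
    "generate_timelapse",
    "generate_palm_movie",
    "generate_calibration_field",
    "sample_on_times",
    "default_kinetics",
]


def default_kinetics() -> KineticParams:
    """Measured kinetic parameters: one loading per 195/46 s, unloading 195 s."""
    return KineticParams(k_p=46.0 / 195.0, t_unload=195.0, t_rep=4080.0, dt=0.05)


@dataclass(frozen=True)
class SceneConfig:
    """Geometry, optics, cell model and noise of a synthetic time-lapse scene.

    Defaults emulate the slow-growth acquisition regime this pipeline targets:
    160 nm pixels, one frame every 2.5 min at 80 ms exposure, ~84 min doubling
    and ~68 min replication per cycle, per-cell totals growing from 60 to 120
    clamp dimers, and bound-clamp dynamics from :func:`default_kinetics`.
    """

    # image geometry
    n_frames: int = 140
    n_channels: int = 6
    channel_spacing_px: int = 12
    channel_width_px: int = 8
    cell_width_px: int = 6
    channel_length_px: int = 48
    pdms_margin_px: int = 16
    pixel_size_nm: float = 160.0
    # timing
    frame_interval_s: float = 150.0
    exposure_s: float = 0.08
    # cell-cycle model (seconds); t_double = t_rep + slack, slack = B + D period
    birth_length_px: float = 14.0
    t_rep_mean_s: float = 4080.0
    t_rep_sd_s: float = 600.0
    slack_mean_s: float = 960.0
    slack_sd_s: float = 300.0
    slack_min_s: float = 720.0
    b_period_fraction: float = 0.3
    # clamp content (dimer counts)
    kinetics: KineticParams = field(default_factory=default_kinetics)
    total_start: float = 60.0
    total_end: float = 120.0
    sister_separation_fraction: float = 0.4
    # optics & photometry
    psf_sigma_px: float = 1.3
    unit_intensity: float = 2000.0
    # background & illumination
    background_offset: float = 200.0
    background_gradient: float = 30.0
    beam_sigma_factor: float = 1.5
    flat_beam: bool = False
    # drift & fiducial
    drift_per_frame_px: tuple[float, float] = (0.012, 0.02)
    fiducial_flux: float = 20000.0
    # noise & bleaching
    noise: bool = True
    camera_gain: float = 20.0
    read_noise_sd: float = 30.0
    survival_per_exposure: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_frames, self.n_channels, self.channel_width_px) < 1:
            raise ConfigError("all dimensions must be >= 1")
        if self.cell_width_px > self.channel_width_px:
            raise ConfigError("cell wider than its growth channel")
        if self.channel_spacing_px < self.channel_width_px:
            raise ConfigError("channel spacing below channel width")
        if 2.0 * self.birth_length_px + 4 > self.channel_length_px:
            raise ConfigError("channel too short to hold one full cell cycle")
        if self.unit_intensity < 0:
            raise ConfigError("unit_intensity must be >= 0")
        if not (0.0 < self.survival_per_exposure <= 1.0):
            raise ConfigError("survival_per_exposure must be in (0, 1]")
        if self.psf_sigma_px <= 0:
            raise ConfigError("psf_sigma_px must be > 0")
        if self.frame_interval_s < self.exposure_s:
            raise ConfigError("frame interval must be >= exposure")

    # derived geometry -----------------------------------------------------
    @property
    def height(self) -> int:
        return self.channel_length_px + self.pdms_margin_px

    @property
    def width(self) -> int:
        return self.n_channels * self.channel_spacing_px

    def channel_cols(self, ch: int) -> tuple[int, int]:
        """Half-open column interval of growth channel ``ch``."""
        pad = (self.channel_spacing_px - self.channel_width_px) // 2
        c0 = ch * self.channel_spacing_px + pad
        return c0, c0 + self.channel_width_px

    def cell_cols(self, ch: int) -> tuple[float, float]:
        c0, c1 = self.channel_cols(ch)
        mid = 0.5 * (c0 + c1)
        return mid - self.cell_width_px / 2.0, mid + self.cell_width_px / 2.0

    @property
    def fiducial_pos(self) -> tuple[float, float]:
        r = self.channel_length_px + self.pdms_margin_px / 2.0
        c = self.width - 8.0 if self.width >= 16 else self.width / 2.0
        return (r, c)


@dataclass
class SceneTruth:
    """Exact per-frame ground truth of a generated scene.

    ``frames``: one row per (channel, cycle, frame) with the cell interval
    ``[row0, row1)`` along the channel, bound/total dimer counts, the intact
    (unbleached) fluorophore fraction, focus positions and per-focus splits,
    and the cycle phase (``pre`` / ``rep`` / ``post``).

    ``cycles``: one row per cell cycle with birth/initiation/termination/
    division times (s) and the drawn ``t_rep`` and ``t_double``.
    """

    frames: pd.DataFrame
    cycles: pd.DataFrame
    drift: np.ndarray
    beam: np.ndarray
    fiducial: np.ndarray
    config: SceneConfig


@dataclass
class TimelapseScene:
    """A generated time-lapse: fluorescence + brightfield proxy + truth."""

    fluorescence: ImageStack
    brightfield: ImageStack
    truth: SceneTruth


# ---------------------------------------------------------------------------
# rendering primitives (flux-exact, subpixel)
# ---------------------------------------------------------------------------


def _renormalize(profile: np.ndarray) -> np.ndarray:
    # all emitted flux is deposited on the detector: fold the small tail that
    # would fall off the image edge back in, so photometric bookkeeping is
    # exact; skip sources that are mostly outside the image
    s = profile.sum()
    return profile / s if s > 0.9 else profile


def _gauss_pixel_profile(n: int, mu: float, sigma: float) -> np.ndarray:
    """Fraction of unit Gaussian flux landing in each of ``n`` pixels."""
    edges = np.arange(n + 1, dtype=float)
    cdf = ndtr((edges - mu) / sigma)
    return _renormalize(np.diff(cdf))


def _rect_pixel_profile(n: int, a: float, b: float, sigma: float) -> np.ndarray:
    """Unit flux uniform on [a, b) convolved with a Gaussian, per pixel.

    Uses the closed-form antiderivative psi(u) = u*Phi(u) + phi(u), which
    keeps total flux exact to machine precision away from the borders.
    """
    if b <= a:
        raise ConfigError("empty cell interval")
    edges = np.arange(n + 1, dtype=float)

    def psi(u):
        return u * ndtr(u) + np.exp(-0.5 * u * u) / math.sqrt(2.0 * math.pi)

    cdf = sigma * (psi((edges - a) / sigma) - psi((edges - b) / sigma)) / (b - a)
    return _renormalize(np.diff(cdf))


def _add_point_source(img: np.ndarray, row: float, col: float, flux: float, sigma: float) -> None:
    h, w = img.shape
    img += flux * np.outer(
        _gauss_pixel_profile(h, row, sigma), _gauss_pixel_profile(w, col, sigma)
    )


def _beam_profile(config: SceneConfig) -> np.ndarray:
    h, w = config.height, config.width
    if config.flat_beam:
        return np.ones((h, w))
    sig = config.beam_sigma_factor * max(h, w)
    rr, cc = np.meshgrid(np.arange(h) - h / 2.0, np.arange(w) - w / 2.0, indexing="ij")
    return np.exp(-(rr**2 + cc**2) / (2.0 * sig**2))


def _background(config: SceneConfig) -> np.ndarray:
    h, w = config.height, config.width
    rr, cc = np.meshgrid(np.arange(h) / max(h - 1, 1), np.arange(w) / max(w - 1, 1), indexing="ij")
    return config.background_offset + config.background_gradient * (0.5 * rr + 0.5 * cc)


def _apply_noise(img: np.ndarray, config: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    if not config.noise:
        return img
    g = config.camera_gain
    shot = g * rng.poisson(np.maximum(img, 0.0) / g)
    return shot + rng.normal(0.0, config.read_noise_sd, img.shape)


# ---------------------------------------------------------------------------
# cell-cycle simulation
# ---------------------------------------------------------------------------


def _truncated_normal(rng, mean, sd, lo, hi):
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return x
    return float(np.clip(mean, lo, hi))


def _bound_counts_for_cycle(
    cfg: SceneConfig,
    n_inherited: int,
    t_birth: float,
    t_init: float,
    t_term: float,
    t_div: float,
    times: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, int]:
    """Bound dimer counts at ``times`` (absolute, s) and the count at division.

    Piecewise exact simulation: pure decay on [birth, init), birth-death with
    loading on [init, term), pure decay on [term, div).
    """
    k = cfg.kinetics
    tau = k.t_unload

    def decay_counts(n0: int, t0: float, t1: float, query: np.ndarray) -> tuple[np.ndarray, int]:
        """Each clamp survives independently; thin sequentially for consistency."""
        pts = np.concatenate([query, [t1]])
        order = np.argsort(pts, kind="stable")
        out = np.empty(len(pts), dtype=int)
        n, t_prev = n0, t0
        for idx in order:
            t = pts[idx]
            p = math.exp(-max(t - t_prev, 0.0) / tau)
            n = rng.binomial(n, p) if n > 0 else 0
            out[idx] = n
            t_prev = t
        return out[:-1], int(out[-1])

    qa = times[(times >= t_birth) & (times < t_init)]
    qb = times[(times >= t_init) & (times < t_term)]
    qc = times[(times >= t_term) & (times < t_div)]

    counts_a, n_at_init = decay_counts(n_inherited, t_birth, t_init, qa)
    # loading active: exact birth-death started at initiation
    params_b = KineticParams(
        k_p=k.k_p, t_unload=tau, t_rep=max(t_term - t_init, 1e-9) * 2 + 1.0,
        dt=k.dt, n_init=n_at_init,
    )
    traj = simulate_exact(params_b, max(t_term - t_init, 1e-9), seed=int(rng.integers(2**31)))
    counts_b = sample_at(traj, qb - t_init)
    n_at_term = int(traj.counts[-1])
    counts_c, n_at_div = decay_counts(n_at_term, t_term, t_div, qc)
    return np.concatenate([counts_a, counts_b, counts_c]), n_at_div


def generate_timelapse(config: SceneConfig) -> TimelapseScene:
    """Render a mother-machine fluorescence/brightfield time-lapse with truth.

    Each growth channel holds its mother cell (the cell at the dead end);
    at division the mother retains the half at the dead end and the daughter
    is pushed out of the channel.  Per frame and per cell the stack contains
    (i) diffuse cytoplasmic signal ``(total - bound) * 2 * unit_intensity``
    spread over the PSF-blurred cell footprint, (ii) 1-2 diffraction-limited
    foci holding the bound clamps (one before sister-replisome separation,
    two after, split binomially), (iii) multiplicative illumination shading,
    (iv) additive background, (v) stage drift applied to cells and fiducial,
    and (vi) Poisson + Gaussian read noise.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.height, cfg.width
    beam = _beam_profile(cfg)
    bg = _background(cfg)
    frame_times = np.arange(cfg.n_frames) * cfg.frame_interval_s
    duration = cfg.n_frames * cfg.frame_interval_s

    drift = np.outer(np.arange(cfg.n_frames), np.asarray(cfg.drift_per_frame_px, dtype=float))
    fid = np.asarray(cfg.fiducial_pos) + drift

    frame_rows: list[dict] = []
    cycle_rows: list[dict] = []

    for ch in range(cfg.n_channels):
        ch_rng = np.random.default_rng((cfg.seed, 17, ch))
        t_birth = 0.0
        n_inherited = 0
        cycle_idx = 0
        while t_birth < duration:
            t_rep = _truncated_normal(
                ch_rng, cfg.t_rep_mean_s, cfg.t_rep_sd_s,
                0.6 * cfg.t_rep_mean_s, 1.4 * cfg.t_rep_mean_s,
            )
            slack = _truncated_normal(
                ch_rng, cfg.slack_mean_s, cfg.slack_sd_s, cfg.slack_min_s, 4 * cfg.slack_mean_s
            )
            t_double = t_rep + slack
            t_init = t_birth + cfg.b_period_fraction * slack
            t_term = t_init + t_rep
            t_div = t_birth + t_double

            times_in = frame_times[(frame_times >= t_birth) & (frame_times < t_div)]
            bound, n_at_div = _bound_counts_for_cycle(
                cfg, n_inherited, t_birth, t_init, t_term, t_div, times_in, ch_rng
            )
            complete = (t_birth > 0.0) and (t_div < duration)
            cycle_rows.append(
                dict(
                    channel=ch, cycle=cycle_idx, t_birth=t_birth, t_init=t_init,
                    t_term=t_term, t_div=t_div, t_rep=t_rep, t_double=t_double,
                    complete=complete,
                )
            )
            for t, nb in zip(times_in, bound):
                age = t - t_birth
                length = cfg.birth_length_px * 2.0 ** (age / t_double)
                row0 = 2.0
                row1 = row0 + length
                if t < t_init:
                    phase = "pre"
                elif t < t_term:
                    phase = "rep"
                else:
                    phase = "post"
                total = cfg.total_start * (cfg.total_end / cfg.total_start) ** (age / t_double)
                # focus geometry: 1 focus before sister separation, 2 after
                s = (t - t_init) / t_rep if t >= t_init else 0.0
                if phase == "rep" and s >= cfg.sister_separation_fraction:
                    off = 0.25 * length * (s - cfg.sister_separation_fraction) / max(
                        1.0 - cfg.sister_separation_fraction, 1e-9
                    )
                    n1 = int(ch_rng.binomial(nb, 0.5)) if nb > 0 else 0
                    foci = [(row0 + 0.5 * length - off, n1), (row0 + 0.5 * length + off, nb - n1)]
                else:
                    foci = [(row0 + 0.5 * length, int(nb))]
                foci = [(r, n) for r, n in foci if n > 0] if nb > 0 else []
                frame_rows.append(
                    dict(
                        channel=ch, cycle=cycle_idx, frame=int(round(t / cfg.frame_interval_s)),
                        time_s=t, row0=row0, row1=row1, bound=int(nb), total=total,
                        phase=phase,
                        f1_row=foci[0][0] if len(foci) > 0 else np.nan,
                        f1_n=foci[0][1] if len(foci) > 0 else 0,
                        f2_row=foci[1][0] if len(foci) > 1 else np.nan,
                        f2_n=foci[1][1] if len(foci) > 1 else 0,
                    )
                )
            # division: mother keeps the dead-end half
            n_inherited = int(ch_rng.binomial(n_at_div, 0.5)) if n_at_div > 0 else 0
            t_birth = t_div
            cycle_idx += 1

    frames_df = pd.DataFrame(frame_rows).sort_values(["frame", "channel"]).reset_index(drop=True)
    cycles_df = pd.DataFrame(cycle_rows)

    # photobleaching: per-fluorophore per-exposure survival, tracked per cell
    frames_df["intact_frac"] = 1.0
    p_surv = cfg.survival_per_exposure
    if p_surv < 1.0:
        for (ch, cyc), grp in frames_df.groupby(["channel", "cycle"], sort=True):
            grp = grp.sort_values("frame")
            cell_rng = np.random.default_rng((cfg.seed, 23, int(ch), int(cyc)))
            intact = None
            fracs = []
            prev_total_fluor = None
            for _, r in grp.iterrows():
                total_fluor = 2.0 * r.total
                if intact is None:
                    intact = total_fluor
                else:
                    intact = cell_rng.binomial(int(round(intact)), p_surv)
                    intact += max(total_fluor - prev_total_fluor, 0.0)
                prev_total_fluor = total_fluor
                fracs.append(intact / total_fluor if total_fluor > 0 else 1.0)
            frames_df.loc[grp.index, "intact_frac"] = fracs

    # render
    fluor = np.empty((cfg.n_frames, h, w), dtype=np.float64)
    bright = np.empty_like(fluor)
    by_frame = {f: g for f, g in frames_df.groupby("frame")}
    noise_rng = np.random.default_rng((cfg.seed, 31))
    for f in range(cfg.n_frames):
        img = np.zeros((h, w))
        bf_mask = np.zeros((h, w))
        dy, dx = drift[f]
        for _, r in by_frame.get(f, pd.DataFrame()).iterrows():
            ch = int(r.channel)
            c0, c1 = cfg.cell_cols(ch)
            col_prof = _rect_pixel_profile(w, c0 + dx, c1 + dx, cfg.psf_sigma_px)
            row_prof = _rect_pixel_profile(h, r.row0 + dy, r.row1 + dy, cfg.psf_sigma_px)
            diffuse_fluor = 2.0 * (r.total - r.bound) * r.intact_frac
            img += (diffuse_fluor * cfg.unit_intensity) * np.outer(row_prof, col_prof)
            mid_col = 0.5 * (c0 + c1) + dx
            for fr, fn in ((r.f1_row, r.f1_n), (r.f2_row, r.f2_n)):
                if fn > 0 and np.isfinite(fr):
                    _add_point_source(
                        img, fr + dy, mid_col, 2.0 * fn * r.intact_frac * cfg.unit_intensity,
                        cfg.psf_sigma_px,
                    )
            # brightfield proxy: dark cell body on bright background
            rr0, rr1 = int(max(r.row0 + dy, 0)), int(min(r.row1 + dy, h))
            cc0, cc1 = int(max(c0 + dx, 0)), int(min(c1 + dx, w))
            bf_mask[rr0:rr1, cc0:cc1] = 1.0
        _add_point_source(img, fid[f, 0], fid[f, 1], cfg.fiducial_flux, cfg.psf_sigma_px)
        img = img * beam + bg
        fluor[f] = _apply_noise(img, cfg, noise_rng)
        bf = 1000.0 - 700.0 * bf_mask
        if cfg.noise:
            bf = bf + noise_rng.normal(0.0, 15.0, bf.shape)
        bright[f] = bf

    meta = dict(
        pixel_size_nm=cfg.pixel_size_nm,
        frame_interval_s=cfg.frame_interval_s,
        exposure_s=cfg.exposure_s,
    )
    truth = SceneTruth(
        frames=frames_df, cycles=cycles_df, drift=drift, beam=beam, fiducial=fid, config=cfg
    )
    return TimelapseScene(
        fluorescence=ImageStack(fluor, **meta), brightfield=ImageStack(bright, **meta),
        truth=truth,
    )


# ---------------------------------------------------------------------------
# PALM movies
# ---------------------------------------------------------------------------


def sample_on_times(
    n: int,
    t_unload: float,
    t_bleach_wall: float,
    frame_interval_s: float,
    movie_length_s: float,
    seed: int,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Draw observed single-molecule on-times (truth-level, no imaging).

    Each molecule disappears at ``min(Exp(t_unload), Exp(t_bleach_wall))``;
    the observation is quantized up to the next frame boundary and
    right-censored at the movie length.  Returns ``(on_times_s, censored,
    latents)``.
    """
    rng = np.random.default_rng(seed)
    t_u = rng.exponential(t_unload, n) if np.isfinite(t_unload) else np.full(n, np.inf)
    t_b = (
        rng.exponential(t_bleach_wall, n) if np.isfinite(t_bleach_wall) else np.full(n, np.inf)
    )
    t = np.minimum(t_u, t_b)
    frames = np.ceil(t / frame_interval_s)
    on = frames * frame_interval_s
    censored = on > movie_length_s - frame_interval_s / 2
    on = np.where(censored, movie_length_s, on)
    return on, censored, dict(t_unload_latent=t_u, t_bleach_latent=t_b)


@dataclass(frozen=True)
class PalmConfig:
    """Acquisition settings of a synthetic PALM movie."""

    n_frames: int = 120
    frame_interval_s: float = 5.0
    exposure_s: float = 0.4
    cell_length_px: float = 20.0
    cell_width_px: float = 7.0
    cell_margin_px: int = 6
    psf_sigma_px: float = 1.3
    spot_intensity: float = 3000.0
    cytoplasm_intensity: float = 0.0
    background_offset: float = 100.0
    noise: bool = True
    camera_gain: float = 20.0
    read_noise_sd: float = 20.0
    seed: int = 0


def generate_palm_movie(
    config: PalmConfig,
    t_unload: float,
    n_spots: int,
    t_bleach_exposure_s: float = np.inf,
) -> tuple[ImageStack, dict]:
    """Render a PALM movie: one activated molecule per cell, imaged to loss.

    Frame 0 is the pre-activation frame (no spots).  From frame 1 each spot
    is visible at a fixed position inside its cell until the earlier of its
    exponential unloading time and its photobleaching time; bleaching acts
    only during the ``exposure_s`` illumination window of each frame, with
    exposure-domain time constant ``t_bleach_exposure_s``.

    Returns the stack and a truth dict with per-spot cells, positions,
    latent unloading/bleach frames, observed visible-frame counts and
    censoring flags.
    """
    if n_spots < 1:
        raise ConfigError("n_spots must be >= 1")
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_cols = int(math.ceil(math.sqrt(n_spots)))
    n_rows = int(math.ceil(n_spots / n_cols))
    pitch_r = cfg.cell_length_px + 2 * cfg.cell_margin_px
    pitch_c = cfg.cell_width_px + 2 * cfg.cell_margin_px
    h = int(n_rows * pitch_r)
    w = int(n_cols * pitch_c)

    n_obs_frames = cfg.n_frames - 1  # frame 0 is pre-activation
    # unloading measured in wall-clock time between frame starts
    big = np.iinfo(np.int64).max // 2
    if np.isfinite(t_unload):
        u = rng.exponential(t_unload, n_spots)
        unload_frames = np.minimum(np.ceil(u / cfg.frame_interval_s), big).astype(np.int64)
    else:
        unload_frames = np.full(n_spots, big, dtype=np.int64)
    if np.isfinite(t_bleach_exposure_s):
        p_surv = math.exp(-cfg.exposure_s / t_bleach_exposure_s)
        bleach_frames = rng.geometric(1.0 - p_surv, n_spots)
    else:
        bleach_frames = np.full(n_spots, big, dtype=np.int64)
    visible = np.minimum(unload_frames, bleach_frames)
    censored = visible > n_obs_frames
    visible = np.minimum(visible, n_obs_frames)

    cells = []
    positions = np.empty((n_spots, 2))
    for i in range(n_spots):
        gr, gc = divmod(i, n_cols)
        r0 = gr * pitch_r + cfg.cell_margin_px
        c0 = gc * pitch_c + cfg.cell_margin_px
        cells.append((r0, r0 + cfg.cell_length_px, c0, c0 + cfg.cell_width_px))
        positions[i] = (
            rng.uniform(r0 + 2.0, r0 + cfg.cell_length_px - 2.0),
            rng.uniform(c0 + 2.0, c0 + cfg.cell_width_px - 2.0),
        )

    stack = np.empty((cfg.n_frames, h, w))
    for f in range(cfg.n_frames):
        img = np.full((h, w), cfg.background_offset, dtype=float)
        if cfg.cytoplasm_intensity > 0:
            for (r0, r1, c0, c1) in cells:
                img += cfg.cytoplasm_intensity * np.outer(
                    _rect_pixel_profile(h, r0, r1, cfg.psf_sigma_px),
                    _rect_pixel_profile(w, c0, c1, cfg.psf_sigma_px),
                )
        if f >= 1:
            k = f  # observation frame index (1-based)
            for i in range(n_spots):
                if k <= visible[i]:
                    _add_point_source(
                        img, positions[i, 0], positions[i, 1], cfg.spot_intensity,
                        cfg.psf_sigma_px,
                    )
        if cfg.noise:
            g = cfg.camera_gain
            img = g * rng.poisson(img / g) + rng.normal(0.0, cfg.read_noise_sd, img.shape)
        stack[f] = img

    truth = dict(
        cells=cells,
        positions=positions,
        visible_frames=visible,
        censored=censored,
        unload_frames=unload_frames,
        bleach_frames=bleach_frames,
        on_times_s=visible * cfg.frame_interval_s,
    )
    meta = dict(pixel_size_nm=160.0, frame_interval_s=cfg.frame_interval_s,
                exposure_s=cfg.exposure_s)
    return ImageStack(stack, **meta), truth


# ---------------------------------------------------------------------------
# calibration fields
# ---------------------------------------------------------------------------


def generate_calibration_field(
    unit_intensity: float,
    n_molecules: int,
    seed: int,
    n_frames: int = 1,
    survival_per_frame: float = 1.0,
    background_offset: float = 100.0,
    psf_sigma_px: float = 1.3,
    min_separation_px: float = 18.0,
    noise: bool = True,
    camera_gain: float = 20.0,
    read_noise_sd: float = 20.0,
) -> tuple[ImageStack, pd.DataFrame]:
    """Sparse field of immobilized single fluorophores on a cover glass.

    Molecules are placed on a jittered grid so every spot is isolated at the
    PSF scale.  With ``n_frames > 1`` each molecule photobleaches in a single
    step with per-frame survival probability ``survival_per_frame``.
    """
    rng = np.random.default_rng(seed)
    if n_molecules < 0:
        raise ConfigError("n_molecules must be >= 0")
    pitch = float(min_separation_px)
    if pitch < 6 * psf_sigma_px:
        raise ConfigError("min_separation_px too small to guarantee isolated spots")
    n_grid = max(int(math.ceil(math.sqrt(max(n_molecules, 1)))), 1)
    side = int((n_grid + 1) * pitch + 2 * pitch)
    centers = []
    for i in range(n_molecules):
        gr, gc = divmod(i, n_grid)
        jitter = rng.uniform(-pitch / 6, pitch / 6, 2)
        centers.append(
            (pitch * 1.5 + gr * pitch + jitter[0], pitch * 1.5 + gc * pitch + jitter[1])
        )
    centers = np.asarray(centers).reshape(-1, 2)

    if n_frames > 1 and survival_per_frame < 1.0:
        bleach_frame = rng.geometric(1.0 - survival_per_frame, size=max(n_molecules, 1))
    else:
        bleach_frame = np.full(max(n_molecules, 1), n_frames + 1)

    stack = np.empty((n_frames, side, side))
    for f in range(n_frames):
        img = np.full((side, side), background_offset, dtype=float)
        for i, (r, c) in enumerate(centers):
            if f < bleach_frame[i]:
                _add_point_source(img, r, c, unit_intensity, psf_sigma_px)
        if noise:
            img = camera_gain * rng.poisson(img / camera_gain)
            img = img + rng.normal(0.0, read_noise_sd, img.shape)
        stack[f] = img

    truth = pd.DataFrame(
        dict(
            row=centers[:, 0] if len(centers) else np.empty(0),
            col=centers[:, 1] if len(centers) else np.empty(0),
            bleach_frame=bleach_frame[: len(centers)],
        )
    )
    return ImageStack(stack, pixel_size_nm=160.0, frame_interval_s=1.0, exposure_s=0.08), truth
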