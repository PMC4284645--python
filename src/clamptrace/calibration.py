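"""Intensity-to-molecule conversion and population averaging.

The absolute scale comes from a single-fluorophore standard: sparse purified
fluorescent proteins immobilized on a cover glass, whose mean integrated spot
intensity defines the camera counts one fluorophore contributes per frame.
Cell intensities are corrected for per-exposure photobleaching, divided by
the unit intensity, and halved when counting clamp dimers (each clamp carries
two fluorophore fusions).  Single-cell traces are aligned on a normalized
replication phase (0 = initiation, 1 = termination) and averaged into
population curves with plateau statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from .core import ConfigError, DataError, ImageStack
from . import palm as _palm
from .timelapse import CellCycleTrace

__all__ = [
    "CalibrationStandard",
    "CalibrationError",
    "MoleculeCountTrace",
    "unit_intensity",
    "bleach_correction",
    "to_molecules",
    "align_and_average",
    "ReplicationCycleEnsemble",
    "PopulationCurves",
]


class CalibrationError(RuntimeError):
    """No usable calibration standard."""


@dataclass(frozen=True)
class CalibrationStandard:
    """Unit intensity of a single fluorophore.

    ``i1`` is in camera counts per fluorophore per frame at ``exposure_s``;
    intensity is linear in exposure, so standards can be rescaled across
    exposures with :meth:`at_exposure`.
    """

    i1: float
    sem: float
    n_spots: int
    exposure_s: float

    def __post_init__(self) -> None:
        if self.i1 <= 0:
            raise CalibrationError(f"unit intensity must be > 0, got {self.i1}")

    def at_exposure(self, exposure_s: float) -> "CalibrationStandard":
        scale = exposure_s / self.exposure_s
        return CalibrationStandard(self.i1 * scale, self.sem * scale, self.n_spots, exposure_s)


def unit_intensity(
    field_stack: ImageStack,
    trim_fraction: float = 0.1,
    min_spots: int = 10,
    detect_kwargs: dict | None = None,
) -> CalibrationStandard:
    """Measure the single-fluorophore unit intensity from calibration fields.

    Spots are detected with the wavelet detector and integrated with aperture
    photometry; the standard is the trimmed mean over all isolated spots in
    all frames of the field.  Fewer than ``min_spots`` spots is an error.
    """
    kwargs = dict(aperture_radius_px=5)
    kwargs.update(detect_kwargs or {})
    intensities: list[float] = []
    for f in range(field_stack.n_frames):
        det = _palm.detect_spots(field_stack.pixels[f], **kwargs)
        intensities.extend(det.intensity.tolist())
    if len(intensities) < min_spots:
        raise CalibrationError(
            f"only {len(intensities)} spots detected; need >= {min_spots}"
        )
    arr = np.sort(np.asarray(intensities))
    k = int(len(arr) * trim_fraction)
    trimmed = arr[k: len(arr) - k] if k > 0 else arr
    return CalibrationStandard(
        i1=float(trimmed.mean()),
        sem=float(trimmed.std(ddof=1) / math.sqrt(len(trimmed))),
        n_spots=len(arr),
        exposure_s=field_stack.exposure_s,
    )


def bleach_correction(
    intensities: np.ndarray, survival_per_exposure: float
) -> tuple[np.ndarray, np.ndarray]:
    """Undo per-exposure photobleaching on an intensity trace.

    Frame ``n`` (counted in fluorescence exposures since the movie start) is
    multiplied by ``survival**(-n)``.  Returns (corrected, factors).
    """
    if not (0.0 < survival_per_exposure <= 1.0):
        raise ConfigError(
            f"survival probability must be in (0, 1], got {survival_per_exposure}"
        )
    intensities = np.asarray(intensities, dtype=float)
    factors = survival_per_exposure ** (-np.arange(len(intensities), dtype=float))
    return intensities * factors, factors


def to_molecules(
    intensity: float | np.ndarray,
    standard: CalibrationStandard,
    dimeric: bool = False,
) -> tuple[float | np.ndarray, float | np.ndarray]:
    """Convert intensity to fluorophore (or clamp-dimer) counts.

    ``count = intensity / i1``, halved when ``dimeric`` (two fluorophore
    fusions per clamp).  The uncertainty propagates the standard's s.e.m. to
    first order.
    """
    if standard is None:
        raise CalibrationError("missing calibration standard")
    intensity = np.asarray(intensity, dtype=float)
    count = intensity / standard.i1
    err = np.abs(count) * (standard.sem / standard.i1)
    if dimeric:
        count, err = count / 2.0, err / 2.0
    if count.ndim == 0:
        return float(count), float(err)
    return count, err


@dataclass
class MoleculeCountTrace:
    """One cell's molecule counts per frame, with its replication phase."""

    cell_id: str
    frames: np.ndarray
    bound: np.ndarray            # clamp (dimer) counts when dimeric, else fluorophores
    total: np.ndarray
    init_frame: int
    term_frame: int
    bleach_factors: np.ndarray | None = None

    @property
    def phase(self) -> np.ndarray:
        """Normalized replication phase of each frame (0=initiation, 1=termination)."""
        span = max(self.term_frame - self.init_frame, 1)
        return (self.frames - self.init_frame) / span

    @property
    def bound_fraction(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.total > 0, self.bound / self.total, np.nan)


def trace_to_molecules(
    trace: CellCycleTrace,
    standard: CalibrationStandard,
    dimeric: bool = True,
    survival_per_exposure: float = 1.0,
) -> MoleculeCountTrace | None:
    """Convert a decomposed cell-cycle trace to molecule counts.

    Applies the photobleaching correction (exposure counter = absolute frame
    index) before dividing by the unit intensity.  Returns None when the
    trace has no defined replication window.
    """
    if trace.init_frame is None or trace.term_frame is None:
        return None
    factors = survival_per_exposure ** (-trace.frames.astype(float))
    foci = trace.foci * factors
    total = (trace.cytoplasm + trace.foci) * factors
    bound, _ = to_molecules(foci, standard, dimeric=dimeric)
    tot, _ = to_molecules(total, standard, dimeric=dimeric)
    return MoleculeCountTrace(
        cell_id=trace.cell_id,
        frames=trace.frames,
        bound=bound,
        total=tot,
        init_frame=trace.init_frame,
        term_frame=trace.term_frame,
        bleach_factors=factors,
    )


@dataclass
class PopulationCurves:
    """Population-averaged replication-phase curves and plateau statistics."""

    phase: np.ndarray
    bound_mean: np.ndarray
    bound_sem: np.ndarray
    total_mean: np.ndarray
    total_sem: np.ndarray
    fraction_mean: np.ndarray
    fraction_sem: np.ndarray
    plateau_mean: float
    plateau_sd: float
    plateau_sem: float
    n_traces: int
    plateau_window: tuple[float, float]
    per_cell_plateau: np.ndarray = field(repr=False, default=None)

    def summary(self) -> str:
        lines = [
            "Population replication-phase average",
            "=" * 46,
            f"cells averaged                 {self.n_traces:>10d}",
            f"plateau window (phase)         [{self.plateau_window[0]:.2f}, "
            f"{self.plateau_window[1]:.2f}]",
            f"plateau mean bound count       {self.plateau_mean:>10.1f}",
            f"plateau s.d. (cell-to-cell)    {self.plateau_sd:>10.1f}",
            f"plateau s.e.m.                 {self.plateau_sem:>10.2f}",
            f"bound fraction at mid-phase    {float(np.interp(0.5, self.phase, self.fraction_mean)):>10.2f}",
        ]
        return "\n".join(lines)


def align_and_average(
    traces: list[MoleculeCountTrace],
    n_phase: int = 50,
    plateau_window: tuple[float, float] = (0.3, 0.9),
) -> PopulationCurves:
    """Align single-cell traces on replication phase and average.

    Each trace is resampled by linear interpolation onto a common phase grid
    spanning initiation (0) to termination (1); pointwise mean and s.e.m. are
    reported, the bound fraction is computed per cell before averaging, and
    plateau statistics are per-cell means over ``plateau_window``.
    """
    usable = [t for t in traces if t is not None and t.term_frame > t.init_frame]
    if len(usable) < 2:
        raise DataError("need >= 2 traces with defined initiation and termination")
    grid = np.linspace(0.0, 1.0, n_phase)
    bound = np.empty((len(usable), n_phase))
    total = np.empty_like(bound)
    frac = np.empty_like(bound)
    plateau_cell = np.empty(len(usable))
    for i, t in enumerate(usable):
        ph = t.phase
        bound[i] = np.interp(grid, ph, t.bound)
        total[i] = np.interp(grid, ph, t.total)
        frac[i] = np.interp(grid, ph, t.bound_fraction)
        in_win = (ph >= plateau_window[0]) & (ph <= plateau_window[1])
        plateau_cell[i] = t.bound[in_win].mean() if in_win.any() else np.nan
    plateau_cell = plateau_cell[np.isfinite(plateau_cell)]
    sem = lambda a: a.std(axis=0, ddof=1) / math.sqrt(a.shape[0])
    return PopulationCurves(
        phase=grid,
        bound_mean=bound.mean(axis=0),
        bound_sem=sem(bound),
        total_mean=total.mean(axis=0),
        total_sem=sem(total),
        fraction_mean=np.nanmean(frac, axis=0),
        fraction_sem=np.nanstd(frac, axis=0, ddof=1) / math.sqrt(frac.shape[0]),
        plateau_mean=float(plateau_cell.mean()),
        plateau_sd=float(plateau_cell.std(ddof=1)),
        plateau_sem=float(plateau_cell.std(ddof=1) / math.sqrt(len(plateau_cell))),
        n_traces=len(usable),
        plateau_window=plateau_window,
        per_cell_plateau=plateau_cell,
    )


class ReplicationCycleEnsemble:
    """Model facade: an ensemble of single-cell molecule-count traces.

    ``fit()`` aligns the traces on replication phase and returns the
    population curves with plateau statistics.
    """

    def __init__(self, traces: list[MoleculeCountTrace],
                 plateau_window: tuple[float, float] = (0.3, 0.9)) -> None:
        self.traces = [t for t in traces if t is not None]
        self.plateau_window = plateau_window

    def fit(self, n_phase: int = 50) -> PopulationCurves:
        return align_and_average(self.traces, n_phase=n_phase,
                                 plateau_window=self.plateau_window)
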