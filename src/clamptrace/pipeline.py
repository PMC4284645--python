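"""End-to-end orchestration of the time-lapse quantification.

Chains the processing stages over a whole mother-machine stack: rolling-ball
background subtraction, flat-fielding against the beam profile, fiducial
drift correction, per-channel kymographs, cycle segmentation and selection,
and finally calibration into molecule counts and population curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calibration import (
    CalibrationStandard,
    MoleculeCountTrace,
    ReplicationCycleEnsemble,
    trace_to_molecules,
)
from .core import ImageStack
from .timelapse import (
    CellCycleTrace,
    DecompositionSettings,
    build_kymograph,
    correct_drift,
    correct_illumination,
    segment_channel_poles,
    segment_cycles,
    select_cells,
    subtract_background,
)

__all__ = ["TimelapseAnalysisConfig", "TimelapseAnalysis", "analyze_timelapse"]


@dataclass
class TimelapseAnalysisConfig:
    """Geometry and thresholds of the full time-lapse analysis."""

    channel_cols: list[tuple[int, int]]
    channel_length_px: int
    expected_birth_length_px: float
    fiducial_region: tuple[int, int, int, int] | None = None
    band_pad_px: int = 2
    ball_radius_px: float = 15.0
    decomposition: DecompositionSettings = field(default_factory=DecompositionSettings)
    length_band: tuple[float, float] = (0.5, 2.0)
    min_elongation: float = 1.4
    division_drop: float = 0.25
    min_cycle_frames: int = 6

    @classmethod
    def from_scene_config(cls, scene_cfg) -> "TimelapseAnalysisConfig":
        """Derive analysis geometry from a synthetic scene's configuration."""
        fr, fc = scene_cfg.fiducial_pos
        return cls(
            channel_cols=[scene_cfg.channel_cols(ch) for ch in range(scene_cfg.n_channels)],
            channel_length_px=scene_cfg.channel_length_px,
            expected_birth_length_px=scene_cfg.birth_length_px,
            fiducial_region=(
                int(fr) - 6, int(fr) + 7, max(int(fc) - 6, 0), min(int(fc) + 7, scene_cfg.width)
            ),
        )


@dataclass
class TimelapseAnalysis:
    """Result bundle of :func:`analyze_timelapse`."""

    traces: list[CellCycleTrace]
    selection_report: dict
    drift: np.ndarray
    frame_interval_s: float

    @property
    def selected(self) -> list[CellCycleTrace]:
        return [t for t in self.traces if t.selected]

    def replication_times_s(self) -> np.ndarray:
        """Initiation-to-termination durations of selected cells, s."""
        # inclusive frame count: both crossing frames belong to replication,
        # which cancels the ceil/floor quantization of the two crossings
        out = [
            (t.term_frame - t.init_frame + 1) * self.frame_interval_s
            for t in self.selected
            if t.init_frame is not None and t.term_frame is not None
        ]
        return np.asarray(out, dtype=float)

    def doubling_times_s(self) -> np.ndarray:
        """Birth-to-division durations of selected cells, s."""
        return np.asarray(
            [len(t.frames) * self.frame_interval_s for t in self.selected], dtype=float
        )

    def to_molecule_traces(
        self,
        standard: CalibrationStandard,
        dimeric: bool = True,
        survival_per_exposure: float = 1.0,
    ) -> list[MoleculeCountTrace]:
        out = []
        for t in self.selected:
            m = trace_to_molecules(
                t, standard, dimeric=dimeric, survival_per_exposure=survival_per_exposure
            )
            if m is not None:
                out.append(m)
        return out

    def ensemble(
        self,
        standard: CalibrationStandard,
        dimeric: bool = True,
        survival_per_exposure: float = 1.0,
        plateau_window: tuple[float, float] = (0.3, 0.9),
    ) -> ReplicationCycleEnsemble:
        return ReplicationCycleEnsemble(
            self.to_molecule_traces(standard, dimeric, survival_per_exposure),
            plateau_window=plateau_window,
        )


def analyze_timelapse(
    fluorescence: ImageStack,
    brightfield: ImageStack,
    config: TimelapseAnalysisConfig,
    beam_profile: np.ndarray | None = None,
) -> TimelapseAnalysis:
    """Run the full per-cell quantification of a mother-machine stack."""
    px = np.empty_like(np.asarray(fluorescence.pixels, dtype=float))
    for f in range(fluorescence.n_frames):
        frame = subtract_background(fluorescence.pixels[f], config.ball_radius_px)
        if beam_profile is not None:
            frame = correct_illumination(frame, beam_profile)
        px[f] = frame
    fl = ImageStack(
        px, fluorescence.pixel_size_nm, fluorescence.frame_interval_s, fluorescence.exposure_s
    )
    bf = ImageStack(
        np.asarray(brightfield.pixels, dtype=float).copy(),
        brightfield.pixel_size_nm, brightfield.frame_interval_s, brightfield.exposure_s,
    )
    if config.fiducial_region is not None:
        fl, drift = correct_drift(fl, config.fiducial_region, extra=[bf])
    else:
        drift = np.zeros((fl.n_frames, 2), dtype=int)

    traces: list[CellCycleTrace] = []
    for ch, cols in enumerate(config.channel_cols):
        poles = segment_channel_poles(bf, cols, config.channel_length_px)
        # sum over a band wider than the channel so the PSF-blurred sides of
        # the cell are integrated with it (poles keep the narrow band for
        # contrast)
        band = (
            max(cols[0] - config.band_pad_px, 0),
            min(cols[1] + config.band_pad_px, fl.shape[2]),
        )
        kymo = build_kymograph(fl, band)
        ch_traces = segment_cycles(
            kymo,
            poles,
            channel=ch,
            division_drop=config.division_drop,
            min_cycle_frames=config.min_cycle_frames,
            channel_length_px=config.channel_length_px,
            settings=config.decomposition,
        )
        traces.extend(ch_traces)
    report = select_cells(
        traces,
        expected_birth_length_px=config.expected_birth_length_px,
        length_band=config.length_band,
        min_elongation=config.min_elongation,
    )
    return TimelapseAnalysis(
        traces=traces,
        selection_report=report,
        drift=drift,
        frame_interval_s=fluorescence.frame_interval_s,
    )
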