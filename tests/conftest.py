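"""Shared fixtures: one medium synthetic time-lapse analysed end to end."""

import numpy as np
import pytest

from clamptrace.calibration import unit_intensity
from clamptrace.pipeline import TimelapseAnalysisConfig, analyze_timelapse
from clamptrace.synthgen import SceneConfig, generate_calibration_field, generate_timelapse


@pytest.fixture(scope="session")
def default_scene():
    """A default-condition mother-machine movie (~25-30 complete cycles)."""
    cfg = SceneConfig(n_frames=200, n_channels=8, seed=7)
    return generate_timelapse(cfg)


@pytest.fixture(scope="session")
def analyzed_scene(default_scene):
    cfg = default_scene.truth.config
    acfg = TimelapseAnalysisConfig.from_scene_config(cfg)
    res = analyze_timelapse(
        default_scene.fluorescence,
        default_scene.brightfield,
        acfg,
        beam_profile=default_scene.truth.beam,
    )
    return res


@pytest.fixture(scope="session")
def standard(default_scene):
    """Calibration standard at the scene's unit intensity (3-frame field)."""
    cfg = default_scene.truth.config
    fld, _ = generate_calibration_field(cfg.unit_intensity, 200, seed=71, n_frames=3)
    return unit_intensity(fld)


def match_truth_cycle(trace, truth, frame_interval_s):
    """The truth cycle containing a trace's temporal midpoint (or None)."""
    t_mid = 0.5 * (trace.frames[0] + trace.frames[-1]) * frame_interval_s
    m = truth.cycles[
        (truth.cycles.channel == trace.channel)
        & (truth.cycles.t_birth <= t_mid)
        & (truth.cycles.t_div > t_mid)
    ]
    return m.iloc[0] if len(m) == 1 else None
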