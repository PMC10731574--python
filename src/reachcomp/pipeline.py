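"""End-to-end per-trial analysis: canonicalize, filter, window, decompose."""

from __future__ import annotations

from .config import AnalysisConfig
from .decomposition import decompose
from .preprocess import (
    ReachWindow,
    detect_reach_window,
    lowpass_filter,
    mirror_to_canonical_side,
)
from .trial import TrialRecording


def analyze_trial(
    trial: TrialRecording,
    config: AnalysisConfig = AnalysisConfig(),
    *,
    filter_trajectories: bool = True,
    window: ReachWindow | None = None,
):
    """Run the standard per-trial pipeline; returns (window, decomposition).

    Steps: mirror left-side trials to the canonical right side, zero-phase
    low-pass filter (skippable for noise-free data), detect the reach
    window from the end-effector speed profile (unless one is supplied),
    and decompose start-to-end displacements into named components.
    """
    trial = mirror_to_canonical_side(trial)
    if filter_trajectories:
        trial = lowpass_filter(trial, config.filter_cutoff_hz, config.filter_order)
    if window is None:
        window = detect_reach_window(
            trial, config.threshold_fraction, config.speed_floor_mm_s
        )
    dec = decompose(
        trial, window, config.denominator_mode, config.degenerate_floor_mm
    )
    return window, dec
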