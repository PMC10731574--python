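"""Trajectory conditioning: filtering, reach-window detection, side
canonicalization, and the pelvis-calibrated displacement primitive.

Every quantity the decompositions report is a start-to-end position
difference, so the job of this module is (a) to pick defensible start/end
frames and (b) to remove whole-body drift by referencing each marker's
displacement to the reaching-side greater trochanter.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .errors import MissingDataError, NoMovementError, ParameterError
from .markers import MarkerName, Side, sided
from .trial import TrialRecording, axis_index

#: Conventional low-pass cutoff for reaching kinematics at 60 Hz capture.
DEFAULT_CUTOFF_HZ = 6.0
DEFAULT_FILTER_ORDER = 4
DEFAULT_THRESHOLD_FRACTION = 0.05
DEFAULT_SPEED_FLOOR_MM_S = 20.0
#: Frames a speed crossing must persist to count (suppresses jitter).
SUSTAIN_FRAMES = 3


@dataclass(frozen=True)
class ReachWindow:
    """Start/end frames of the analyzed movement within a trial."""

    start_frame: int
    end_frame: int
    peak_speed: float
    detection_rule: str
    clamped: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.start_frame < self.end_frame:
            raise ValueError(
                f"invalid window [{self.start_frame}, {self.end_frame}]"
            )


def full_trial_window(trial: TrialRecording) -> ReachWindow:
    """A window spanning the whole trial (no detection)."""
    return ReachWindow(0, trial.n_frames - 1, np.nan, "full_trial")


def lowpass_filter(
    trial: TrialRecording,
    cutoff: float = DEFAULT_CUTOFF_HZ,
    order: int = DEFAULT_FILTER_ORDER,
) -> TrialRecording:
    """Zero-phase Butterworth low-pass filter of every marker trajectory.

    Filtering is forward-backward (``filtfilt``), so the effective
    attenuation is the squared magnitude response of the designed
    ``order``-pole filter and no phase lag is introduced.  NaN samples are
    preserved: each contiguous finite segment is filtered independently and
    NaN spans pass through untouched.
    """
    nyquist = trial.sampling_rate / 2.0
    if cutoff >= nyquist:
        raise ParameterError(
            f"cutoff {cutoff} Hz must be below the Nyquist frequency {nyquist} Hz"
        )
    b, a = signal.butter(order, cutoff / nyquist)
    min_len = 3 * max(len(a), len(b))

    out: dict[MarkerName, np.ndarray] = {}
    for marker, arr in trial.positions.items():
        filtered = arr.copy()
        finite = np.isfinite(arr).all(axis=1)
        edges = np.flatnonzero(np.diff(np.concatenate(([0], finite.view(np.int8), [0]))))
        for start, stop in zip(edges[::2], edges[1::2]):
            seg = arr[start:stop]
            if len(seg) <= min_len:
                continue  # too short to filter stably; leave raw
            filtered[start:stop] = signal.filtfilt(b, a, seg, axis=0)
        out[marker] = filtered
    return replace(
        trial,
        positions=out,
        provenance=trial.provenance + (f"lowpass:butter{order}:{cutoff}Hz",),
    )


def tangential_speed(trial: TrialRecording, marker: MarkerName) -> np.ndarray:
    """Per-frame speed (mm/s) of ``marker`` from central differences."""
    pos = trial.marker(marker)
    vel = np.gradient(pos, 1.0 / trial.sampling_rate, axis=0)
    return np.linalg.norm(vel, axis=1)


def _sustained_runs(mask: np.ndarray, run: int) -> np.ndarray:
    """Indices i where ``mask[i : i + run]`` is all True."""
    if run <= 1:
        return np.flatnonzero(mask)
    window = np.convolve(mask.astype(int), np.ones(run, dtype=int), "valid")
    return np.flatnonzero(window == run)


def detect_reach_window(
    trial: TrialRecording,
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
    speed_floor: float = DEFAULT_SPEED_FLOOR_MM_S,
    sustain_frames: int = SUSTAIN_FRAMES,
) -> ReachWindow:
    """Find the movement window from the end-effector speed profile.

    Detection is anchored at the frame of peak tangential speed of the
    reaching-side MP joint and walks outward: the start frame is the last
    frame before the peak where speed sits at or below
    ``threshold_fraction`` x peak for ``sustain_frames`` consecutive
    frames, and the end frame is the first such frame after the peak.
    Anchoring at the peak keeps a noisy quiet-phase blip from opening (and
    immediately closing) a spurious window.  If the trial begins or ends
    mid-movement the window clamps to the trial bounds and is flagged.

    With ``threshold_fraction = 0`` on noise-free data the window spans all
    moving frames, so the windowed displacement equals the full-trial
    displacement.

    Raises
    ------
    NoMovementError
        If peak speed is below ``speed_floor`` (default 20 mm/s).
    """
    marker = sided("MP", trial.reaching_side)
    speed = tangential_speed(trial, marker)
    peak = float(np.nanmax(speed))
    if not peak >= speed_floor:
        raise NoMovementError(
            f"peak {marker.value} speed {peak:.1f} mm/s is below the "
            f"movement floor {speed_floor} mm/s"
        )
    peak_idx = int(np.nanargmax(speed))
    thr = threshold_fraction * peak
    below = ~(speed > thr)  # NaN counts as quiet

    clamped = False
    quiet_starts = _sustained_runs(below, sustain_frames)
    # last quiet run ending before the peak: window start is its final frame
    ends = quiet_starts + sustain_frames - 1
    before = ends[ends < peak_idx]
    if before.size:
        start = int(before[-1])
    else:
        start = 0
        clamped = True
    after = quiet_starts[quiet_starts > peak_idx]
    if after.size:
        end = int(after[0])
    else:
        end = trial.n_frames - 1
        clamped = True
    rule = (
        f"velocity_threshold:frac={threshold_fraction}:floor={speed_floor}"
        f":sustain={sustain_frames}"
    )
    return ReachWindow(start, end, peak, rule, clamped)


def mirror_trial(trial: TrialRecording) -> TrialRecording:
    """Reflect a trial across the sagittal plane (an involution).

    X coordinates are negated, left/right marker names swapped, and the
    reaching side flipped.  Y and Z series — the only axes the
    decompositions read — are untouched, so applying this twice returns the
    original trial and applying it once never changes a component value.
    """
    positions = {}
    for marker, arr in trial.positions.items():
        flipped = arr.copy()
        flipped[:, 0] = -flipped[:, 0]
        positions[marker.mirrored] = flipped
    return replace(
        trial,
        positions=positions,
        reaching_side=trial.reaching_side.other,
        provenance=trial.provenance + ("mirrored",),
    )


def mirror_to_canonical_side(trial: TrialRecording) -> TrialRecording:
    """Canonicalize to a right-side reach; identity for right-side trials."""
    if trial.reaching_side is Side.RIGHT:
        return trial.replace()
    return mirror_trial(trial)


def pelvis_calibrated_displacement(
    trial: TrialRecording,
    marker: MarkerName,
    axis: str | int,
    window: ReachWindow,
) -> float:
    """Start-to-end displacement of ``marker`` minus the trochanter's.

    Subtracting the reaching-side greater trochanter's displacement on the
    same axis removes any whole-body translation (chair shifts, pelvis
    drift), leaving only motion of the body relative to the pelvis:

    ``[p_marker(end) - p_marker(start)] - [p_troch(end) - p_troch(start)]``

    Positions are taken as stored in ``trial`` — filter first if desired.
    """
    marker = MarkerName(marker)
    ax = axis_index(axis)
    troch = sided("TROCHANTER", trial.reaching_side)
    if window.end_frame >= trial.n_frames:
        raise ValueError(
            f"window end {window.end_frame} outside trial of {trial.n_frames} frames"
        )
    values = {}
    for m in (marker, troch):
        series = trial.marker(m)[:, ax]
        for frame in (window.start_frame, window.end_frame):
            v = series[frame]
            if np.isnan(v):
                raise MissingDataError(
                    f"marker {m.value} is NaN at window frame {frame}"
                )
        values[m] = series[window.end_frame] - series[window.start_frame]
    return float(values[marker] - values[troch])
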