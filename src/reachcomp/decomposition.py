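"""Component decomposition of reach displacements.

Both tasks are decomposed telescopically along the marker chain, so the
named components sum to the total by construction:

Forward reach (all on the anterior Y axis, trochanter-calibrated):

* ``shoulder_elbow``   — MP joint relative to the acromion (shoulder
  flexion + elbow extension),
* ``trunk_rotation``   — acromion relative to C7,
* ``trunk_flexion``    — C7 itself.

Hand-to-mouth reach (vertical Z axis, trochanter-calibrated; the total is
the vertical hand-mouth gap closed, so the chin's drop counts toward it):

* ``shoulder_elbow_flexion`` — hand elevation relative to the acromion
  beyond what shoulder abduction explains,
* ``shoulder_abduction``     — epicondyle elevation relative to the
  acromion (assumes constant acromion-epicondyle length),
* ``girdle_elevation``       — acromion elevation (shrug),
* ``cervical_flexion``       — chin drop (positive downward).

Components are signed and never clipped; a component can legitimately be
negative (e.g. slight neck extension during hand-to-mouth).
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import DegenerateTrialError, MetadataError, MissingDataError, ReachcompError
from .markers import MarkerName, Task, sided
from .preprocess import ReachWindow, pelvis_calibrated_displacement
from .trial import TrialRecording
from .trial_io import validate_marker_set

FORWARD_COMPONENTS = ("shoulder_elbow", "trunk_rotation", "trunk_flexion")
HAND_TO_MOUTH_COMPONENTS = (
    "shoulder_elbow_flexion",
    "shoulder_abduction",
    "girdle_elevation",
    "cervical_flexion",
)

#: Below this total displacement (mm), percentages are meaningless.
DEFAULT_DEGENERATE_FLOOR_MM = 20.0

#: Fraction of upper-extremity length used as the nominal reach distance in
#: ``arm_length`` denominator mode.  The protocol starts the hand one third
#: of the upper-limb length from the acromion and ends at full extension,
#: leaving two thirds of the limb length as the nominal transport distance.
ARM_LENGTH_DENOMINATOR_FRACTION = 2.0 / 3.0

DENOMINATOR_MODES = ("measured_total", "arm_length")


def percent_contributions(components: list[float], denominator: float) -> list[float]:
    """Express signed component displacements as percentages of a total.

    Raises :class:`DegenerateTrialError` on a zero denominator.  Signs are
    preserved, so values below 0 or above 100 are possible and meaningful.
    """
    if denominator == 0:
        raise DegenerateTrialError("percentage denominator is zero")
    return [100.0 * c / denominator for c in components]


def components_mapping(decomposition) -> dict[str, float]:
    """Name -> signed mm for either decomposition type."""
    return {name: getattr(decomposition, name) for name in decomposition.component_names}


def percents_mapping(decomposition) -> dict[str, float]:
    """Name -> signed percent for either decomposition type."""
    return {
        name: getattr(decomposition, f"percent_{name}")
        for name in decomposition.component_names
    }


@dataclass(frozen=True)
class ForwardReachDecomposition:
    """Forward (Y-axis) reach split into three signed components (mm, %)."""

    total_forward: float
    shoulder_elbow: float
    trunk_rotation: float
    trunk_flexion: float
    percent_shoulder_elbow: float
    percent_trunk_rotation: float
    percent_trunk_flexion: float
    denominator_mode: str
    denominator: float

    component_names = FORWARD_COMPONENTS
    task = Task.FORWARD_REACH
    total_name = "total_forward"

    @property
    def total(self) -> float:
        return self.total_forward


@dataclass(frozen=True)
class HandToMouthDecomposition:
    """Vertical (Z-axis) hand-mouth gap closure split into four components."""

    total_vertical: float
    shoulder_elbow_flexion: float
    shoulder_abduction: float
    girdle_elevation: float
    cervical_flexion: float
    percent_shoulder_elbow_flexion: float
    percent_shoulder_abduction: float
    percent_girdle_elevation: float
    percent_cervical_flexion: float
    denominator_mode: str
    denominator: float

    component_names = HAND_TO_MOUTH_COMPONENTS
    task = Task.HAND_TO_MOUTH
    total_name = "total_vertical"

    @property
    def total(self) -> float:
        return self.total_vertical


def _resolve_denominator(
    trial: TrialRecording, total: float, mode: str, floor: float
) -> float:
    if mode not in DENOMINATOR_MODES:
        raise ValueError(f"denominator_mode must be one of {DENOMINATOR_MODES}")
    if mode == "measured_total":
        if abs(total) < floor:
            raise DegenerateTrialError(
                f"total displacement {total:.1f} mm is below the floor {floor} mm; "
                "percent contributions are undefined"
            )
        return total
    if trial.upper_extremity_length is None:
        raise MetadataError(
            "arm_length denominator mode requires trial.upper_extremity_length"
        )
    return ARM_LENGTH_DENOMINATOR_FRACTION * trial.upper_extremity_length


def _check_markers(trial: TrialRecording) -> None:
    problems = validate_marker_set(trial)
    if problems:
        raise MissingDataError(
            "trial fails marker validation: " + "; ".join(str(p) for p in problems)
        )


def decompose_forward_reach(
    trial: TrialRecording,
    window: ReachWindow,
    denominator_mode: str = "measured_total",
    degenerate_floor: float = DEFAULT_DEGENERATE_FLOOR_MM,
) -> ForwardReachDecomposition:
    """Decompose a forward-reach trial over ``window``.

    All displacements are trochanter-calibrated Y-axis start-to-end
    differences.  The telescoping construction guarantees the three
    components sum to the MP joint's total forward displacement.
    """
    if trial.task is not Task.FORWARD_REACH:
        raise ReachcompError(f"trial task is {trial.task.value}, not forward_reach")
    _check_markers(trial)
    side = trial.reaching_side

    def disp(marker: MarkerName) -> float:
        return pelvis_calibrated_displacement(trial, marker, "Y", window)

    d_mp = disp(sided("MP", side))
    d_acr = disp(sided("ACROMION", side))
    d_c7 = disp(MarkerName.C7)

    total = d_mp
    shoulder_elbow = d_mp - d_acr
    trunk_rotation = d_acr - d_c7
    trunk_flexion = d_c7

    denom = _resolve_denominator(trial, total, denominator_mode, degenerate_floor)
    p_se, p_tr, p_tf = percent_contributions(
        [shoulder_elbow, trunk_rotation, trunk_flexion], denom
    )
    return ForwardReachDecomposition(
        total_forward=total,
        shoulder_elbow=shoulder_elbow,
        trunk_rotation=trunk_rotation,
        trunk_flexion=trunk_flexion,
        percent_shoulder_elbow=p_se,
        percent_trunk_rotation=p_tr,
        percent_trunk_flexion=p_tf,
        denominator_mode=denominator_mode,
        denominator=denom,
    )


def decompose_hand_to_mouth(
    trial: TrialRecording,
    window: ReachWindow,
    denominator_mode: str = "measured_total",
    degenerate_floor: float = DEFAULT_DEGENERATE_FLOOR_MM,
) -> HandToMouthDecomposition:
    """Decompose a hand-to-mouth trial over ``window``.

    The total is the vertical hand-mouth gap closed: the MP joint's rise
    plus the chin's drop.  The abduction component uses the epicondyle's
    elevation relative to the acromion, so girdle elevation is not
    double-counted; the shoulder/elbow flexion component is the residual of
    the hand's rise relative to the acromion.
    """
    if trial.task is not Task.HAND_TO_MOUTH:
        raise ReachcompError(f"trial task is {trial.task.value}, not hand_to_mouth")
    _check_markers(trial)
    side = trial.reaching_side

    def disp(marker: MarkerName) -> float:
        return pelvis_calibrated_displacement(trial, marker, "Z", window)

    d_mp = disp(sided("MP", side))
    d_epi = disp(sided("EPICONDYLE", side))
    d_acr = disp(sided("ACROMION", side))
    d_chin = disp(MarkerName.CHIN)

    hand_rise_rel_acromion = d_mp - d_acr  # components 4 + 5 combined
    shoulder_abduction = d_epi - d_acr
    shoulder_elbow_flexion = hand_rise_rel_acromion - shoulder_abduction
    girdle_elevation = d_acr
    cervical_flexion = -d_chin  # chin drop counts positive
    total = d_mp + cervical_flexion

    denom = _resolve_denominator(trial, total, denominator_mode, degenerate_floor)
    p_sef, p_ab, p_ge, p_cf = percent_contributions(
        [shoulder_elbow_flexion, shoulder_abduction, girdle_elevation, cervical_flexion],
        denom,
    )
    return HandToMouthDecomposition(
        total_vertical=total,
        shoulder_elbow_flexion=shoulder_elbow_flexion,
        shoulder_abduction=shoulder_abduction,
        girdle_elevation=girdle_elevation,
        cervical_flexion=cervical_flexion,
        percent_shoulder_elbow_flexion=p_sef,
        percent_shoulder_abduction=p_ab,
        percent_girdle_elevation=p_ge,
        percent_cervical_flexion=p_cf,
        denominator_mode=denominator_mode,
        denominator=denom,
    )


def decompose(
    trial: TrialRecording,
    window: ReachWindow,
    denominator_mode: str = "measured_total",
    degenerate_floor: float = DEFAULT_DEGENERATE_FLOOR_MM,
):
    """Dispatch to the decomposition matching ``trial.task``."""
    if trial.task is Task.FORWARD_REACH:
        return decompose_forward_reach(trial, window, denominator_mode, degenerate_floor)
    return decompose_hand_to_mouth(trial, window, denominator_mode, degenerate_floor)


def component_names(task: Task) -> tuple[str, ...]:
    return FORWARD_COMPONENTS if Task(task) is Task.FORWARD_REACH else HAND_TO_MOUTH_COMPONENTS
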