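"""Seated kinematic-chain simulator and analytic decomposition oracle.

The chain is pelvis -> trunk -> shoulder girdle -> upper arm -> forearm,
with a head segment hanging off C7.  Seven degrees of freedom drive it:

======================  =======  ==========================================
DOF                     units    effect
======================  =======  ==========================================
trunk_flexion           deg      pitches the trunk forward about the pelvis
trunk_rotation          deg      yaws the trunk (reaching shoulder forward)
girdle_elevation        mm       translates the acromion along trunk-up
shoulder_flexion        deg      raises the arm forward from hanging
shoulder_abduction      deg      raises the arm laterally
elbow_flexion           deg      flexes the forearm (90 deg = protocol rest)
neck_flexion            deg      drops the chin forward/down
======================  =======  ==========================================

Each DOF follows a rest-to-rest minimum-jerk profile between a start and
end value.  Marker trajectories are produced for the full ten-marker set;
the contralateral limb stays in the rest posture.  Gaussian marker noise is
added per axis at configurable standard deviations matching optical-capture
device error (roughly 0.5-2.4 mm per axis).

:func:`analytic_decomposition_oracle` evaluates the decomposition formulas
directly on the exact endpoint poses — no sampling, filtering, or window
detection — and serves as the independent ground truth for pipeline tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .decomposition import (
    FORWARD_COMPONENTS,
    HAND_TO_MOUTH_COMPONENTS,
)
from .errors import ReachcompError
from .markers import MarkerName, Side, Task, sided
from .trial import SubjectRecord, TrialRecording

DOF_NAMES = (
    "trunk_flexion",
    "trunk_rotation",
    "girdle_elevation",
    "shoulder_flexion",
    "shoulder_abduction",
    "elbow_flexion",
    "neck_flexion",
)

#: Protocol start posture: arm hanging, forearm level on the start table.
REST_POSE = {name: 0.0 for name in DOF_NAMES} | {"elbow_flexion": 90.0}

#: Acromion->MP distance as a fraction of measured upper-extremity length
#: (which is taken to the fingertip, distal to the MP joint).
MP_FRACTION_OF_UE_LENGTH = 0.88


@dataclass(frozen=True)
class ChainConfig:
    """Segment lengths (mm) of the simulated chain.

    Defaults give an acromion->MP reach of 630 mm, consistent with an
    upper-extremity length around 72 cm once the MP-to-fingertip span is
    discounted.  If ``upper_extremity_length`` is declared, the arm segments
    must be consistent with it within 5%.
    """

    trunk_length: float = 450.0
    shoulder_offset: float = 180.0
    upper_arm_length: float = 300.0
    forearm_length: float = 330.0
    chin_offset: tuple[float, float] = (60.0, 120.0)  # (forward, up) from C7
    hip_width: float = 160.0
    upper_extremity_length: float | None = None

    def __post_init__(self) -> None:
        for name in ("trunk_length", "shoulder_offset", "upper_arm_length", "forearm_length"):
            if not getattr(self, name) > 0:
                raise ReachcompError(f"{name} must be > 0")
        if self.upper_extremity_length is not None:
            nominal = MP_FRACTION_OF_UE_LENGTH * self.upper_extremity_length
            arm = self.upper_arm_length + self.forearm_length
            if abs(arm - nominal) > 0.05 * nominal:
                raise ReachcompError(
                    f"arm segments sum to {arm:.0f} mm, inconsistent with "
                    f"upper-extremity length {self.upper_extremity_length:.0f} mm "
                    f"(expected ~{nominal:.0f} mm acromion->MP)"
                )

    @classmethod
    def from_upper_extremity_length(cls, uel_mm: float, **overrides) -> "ChainConfig":
        """Scale the default proportions to a measured limb length."""
        reach = MP_FRACTION_OF_UE_LENGTH * uel_mm
        scale = reach / (300.0 + 330.0)
        return cls(
            trunk_length=450.0 * scale,
            shoulder_offset=180.0 * scale,
            upper_arm_length=300.0 * scale,
            forearm_length=330.0 * scale,
            chin_offset=(60.0 * scale, 120.0 * scale),
            upper_extremity_length=uel_mm,
            **overrides,
        )


@dataclass(frozen=True)
class DOFMotion:
    """Minimum-jerk transition of one DOF from ``start`` to ``end``."""

    start: float
    end: float
    onset: float = 0.0
    duration: float = 1.0

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise ReachcompError("DOF motion duration must be > 0")


@dataclass(frozen=True)
class JointProgram:
    """Per-DOF angle programs; unspecified DOFs hold their rest value."""

    motions: Mapping[str, DOFMotion] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.motions) - set(DOF_NAMES)
        if unknown:
            raise ReachcompError(f"unknown DOF name(s): {sorted(unknown)}")
        object.__setattr__(self, "motions", dict(self.motions))

    @classmethod
    def from_end_values(
        cls, end_values: Mapping[str, float], duration: float = 1.0, onset: float = 0.0
    ) -> "JointProgram":
        """Program every listed DOF from its rest value to ``end_values``."""
        return cls(
            {
                dof: DOFMotion(REST_POSE[dof], end, onset, duration)
                for dof, end in end_values.items()
            }
        )

    @property
    def span(self) -> float:
        """Time from 0 to the last motion's completion (>= small epsilon)."""
        if not self.motions:
            return 0.0
        return max(m.onset + m.duration for m in self.motions.values())

    def pose_at(self, t: float | np.ndarray) -> dict[str, np.ndarray]:
        """Pose (scalar or array per DOF) at time(s) ``t``."""
        pose: dict[str, np.ndarray] = {}
        for dof in DOF_NAMES:
            motion = self.motions.get(dof)
            if motion is None:
                pose[dof] = np.broadcast_to(np.float64(REST_POSE[dof]), np.shape(t)).copy() \
                    if np.ndim(t) else np.float64(REST_POSE[dof])
                continue
            frac = minimum_jerk_profile(t, motion.onset, motion.duration)
            pose[dof] = motion.start + (motion.end - motion.start) * frac
        return pose

    @property
    def start_pose(self) -> dict[str, float]:
        return {
            dof: float(self.motions[dof].start) if dof in self.motions else REST_POSE[dof]
            for dof in DOF_NAMES
        }

    @property
    def end_pose(self) -> dict[str, float]:
        return {
            dof: float(self.motions[dof].end) if dof in self.motions else REST_POSE[dof]
            for dof in DOF_NAMES
        }


def minimum_jerk_profile(
    t: float | np.ndarray, onset: float, duration: float
) -> float | np.ndarray:
    """Rest-to-rest quintic profile: 0 before onset, 1 after completion.

    Between, the fraction is ``10 tau^3 - 15 tau^4 + 6 tau^5`` with
    ``tau = (t - onset) / duration``: monotone, with zero velocity and
    acceleration at both ends.
    """
    if not duration > 0:
        raise ReachcompError("duration must be > 0")
    tau = np.clip((np.asarray(t, dtype=np.float64) - onset) / duration, 0.0, 1.0)
    out = tau**3 * (10.0 - 15.0 * tau + 6.0 * tau**2)
    return float(out) if np.ndim(t) == 0 else out


# ---------------------------------------------------------------------------
# forward kinematics


def _trunk_rotate(flexion: np.ndarray, rotation: np.ndarray, v: tuple) -> np.ndarray:
    """Apply the trunk rotation Rz(rotation) @ Rx(-flexion) to vector ``v``.

    ``flexion``/``rotation`` are radian arrays of shape (...,); ``v`` is a
    3-vector (components may themselves be arrays).  Returns shape (..., 3).
    """
    vx, vy, vz = v
    cf, sf = np.cos(flexion), np.sin(flexion)
    cr, sr = np.cos(rotation), np.sin(rotation)
    # pitch forward: Rx(-f) maps (0,0,1) -> (0, sin f, cos f)
    y1 = vy * cf + vz * sf
    z1 = -vy * sf + vz * cf
    x2 = vx * cr - y1 * sr
    y2 = vx * sr + y1 * cr
    return np.stack(np.broadcast_arrays(x2, y2, z1), axis=-1)


def marker_positions_from_pose(
    config: ChainConfig,
    pose: Mapping[str, float | np.ndarray],
    side: Side = Side.RIGHT,
) -> dict[MarkerName, np.ndarray]:
    """Forward kinematics: DOF values -> all ten marker positions (mm).

    Accepts scalar or equal-shape array DOF values; returns arrays of shape
    ``(..., 3)`` per marker.  The reaching-side trochanter sits at the
    origin; lateral X is positive toward the reaching side.

    Geometry: C7 rides the trunk vector (pitched by trunk flexion, yawed by
    trunk rotation); the acromion adds a lateral offset in the trunk frame
    plus girdle elevation along trunk-up; the upper arm hangs from the
    acromion rotated by shoulder flexion then abduction; the forearm adds
    elbow flexion in the same plane; the chin rides C7 through neck flexion.
    """
    rad = math.pi / 180.0
    f = np.asarray(pose["trunk_flexion"], dtype=np.float64) * rad
    r = np.asarray(pose["trunk_rotation"], dtype=np.float64) * rad
    g = np.asarray(pose["girdle_elevation"], dtype=np.float64)
    sf = np.asarray(pose["shoulder_flexion"], dtype=np.float64) * rad
    ab = np.asarray(pose["shoulder_abduction"], dtype=np.float64) * rad
    ef = np.asarray(pose["elbow_flexion"], dtype=np.float64) * rad
    nf = np.asarray(pose["neck_flexion"], dtype=np.float64) * rad
    zero = np.zeros(np.broadcast_shapes(f.shape, r.shape, g.shape, sf.shape))
    one = zero + 1.0

    trunk_up = _trunk_rotate(f, r, (zero, zero, one))
    lateral = _trunk_rotate(f, r, (one, zero, zero))
    c7 = config.trunk_length * trunk_up
    acromion = c7 + config.shoulder_offset * lateral + g[..., None] * trunk_up
    acromion_other = c7 - config.shoulder_offset * lateral

    # arm directions in the world frame (the shoulder orients the arm
    # toward the goal regardless of trunk posture, so trunk motion moves
    # the arm only by carrying the acromion)
    def arm_dir(flex: np.ndarray, abd: np.ndarray) -> np.ndarray:
        # Ry(-abd) @ Rx(flex) applied to (0, 0, -1): abduction raises the
        # arm toward +X (the reaching side), flexion raises it toward +Y.
        return np.stack(
            np.broadcast_arrays(
                np.sin(abd) * np.cos(flex),
                np.sin(flex),
                -np.cos(abd) * np.cos(flex),
            ),
            axis=-1,
        )

    upper_dir = arm_dir(sf, ab)
    fore_dir = arm_dir(sf + ef, ab)
    epicondyle = acromion + config.upper_arm_length * upper_dir
    mp = epicondyle + config.forearm_length * fore_dir

    rest_upper = np.stack(np.broadcast_arrays(zero, zero, -one), axis=-1)
    rest_fore = np.stack(np.broadcast_arrays(zero, one, zero), axis=-1)
    epicondyle_other = acromion_other + config.upper_arm_length * rest_upper
    mp_other = epicondyle_other + config.forearm_length * rest_fore

    cy, cz = config.chin_offset
    chin_local = (
        zero,
        cy * np.cos(nf) + cz * np.sin(nf),
        -cy * np.sin(nf) + cz * np.cos(nf),
    )
    chin = c7 + _trunk_rotate(f, r, chin_local)

    troch = np.zeros_like(c7)
    troch_other = np.zeros_like(c7)
    troch_other[..., 0] = -config.hip_width

    out = {
        MarkerName.CHIN: chin,
        MarkerName.C7: c7,
        sided("ACROMION", side): acromion,
        sided("ACROMION", side.other): acromion_other,
        sided("EPICONDYLE", side): epicondyle,
        sided("EPICONDYLE", side.other): epicondyle_other,
        sided("MP", side): mp,
        sided("MP", side.other): mp_other,
        sided("TROCHANTER", side): troch,
        sided("TROCHANTER", side.other): troch_other,
    }
    if side is Side.LEFT:
        # reaching with the left arm: lateral-positive is toward the left,
        # so flip X into the shared world frame where +X is to the right
        out = {m: a.copy() for m, a in out.items()}
        for a in out.values():
            a[..., 0] = -a[..., 0]
    return out


# ---------------------------------------------------------------------------
# trial simulation


def simulate_trial(
    config: ChainConfig,
    program: JointProgram,
    task: Task | str,
    *,
    side: Side | str = Side.RIGHT,
    sampling_rate: float = 60.0,
    noise_sd: float | tuple[float, float, float] = 0.0,
    seed: int | None = None,
    rest_padding: float = 0.5,
    subject_id: str = "sim",
) -> TrialRecording:
    """Render a joint program into a noisy sampled :class:`TrialRecording`.

    The trial is ``rest_padding`` seconds of quiet posture, the program, and
    another ``rest_padding`` of quiet posture, sampled at ``sampling_rate``.
    Independent Gaussian noise with per-axis standard deviation ``noise_sd``
    (scalar or an (X, Y, Z) triple, mm) is added to every marker sample;
    the generator is seeded, so equal seeds give identical recordings.
    """
    task = Task(task)
    side = Side(side)
    if not sampling_rate > 0:
        raise ReachcompError("sampling_rate must be > 0")
    total_time = program.span + 2.0 * rest_padding
    n = max(2, int(round(total_time * sampling_rate)) + 1)
    t = np.arange(n) / sampling_rate - rest_padding
    pose = program.pose_at(t)
    markers = marker_positions_from_pose(config, pose, side)

    sd = np.broadcast_to(np.asarray(noise_sd, dtype=np.float64), (3,)).copy()
    rng = np.random.default_rng(seed)
    positions: dict[MarkerName, np.ndarray] = {}
    for m in MarkerName:
        arr = np.asarray(markers[m], dtype=np.float64)
        if (sd > 0).any():
            arr = arr + rng.normal(0.0, 1.0, arr.shape) * sd
        positions[m] = arr
    return TrialRecording(
        positions=positions,
        sampling_rate=sampling_rate,
        task=task,
        reaching_side=side,
        subject_id=subject_id,
        upper_extremity_length=config.upper_extremity_length,
        source="simulated",
        metadata={"seed": seed, "noise_sd": tuple(sd), "program": program},
    )


def analytic_decomposition_oracle(
    config: ChainConfig,
    program: JointProgram,
    task: Task | str,
    side: Side | str = Side.RIGHT,
) -> dict[str, float]:
    """Exact expected component displacements for a joint program.

    Evaluates the chain at the program's start and end poses only and
    applies the decomposition formulas to those exact positions
    (trochanter-calibrated), bypassing sampling, noise, filtering, and
    window detection.  Returns ``{"total": mm, <component>: mm, ...}``.
    """
    task = Task(task)
    side = Side(side)
    p0 = marker_positions_from_pose(config, program.start_pose, side)
    p1 = marker_positions_from_pose(config, program.end_pose, side)
    troch = sided("TROCHANTER", side)

    def disp(marker: MarkerName, ax: int) -> float:
        return float(
            (p1[marker][ax] - p0[marker][ax]) - (p1[troch][ax] - p0[troch][ax])
        )

    if task is Task.FORWARD_REACH:
        d_mp = disp(sided("MP", side), 1)
        d_acr = disp(sided("ACROMION", side), 1)
        d_c7 = disp(MarkerName.C7, 1)
        return {
            "total": d_mp,
            FORWARD_COMPONENTS[0]: d_mp - d_acr,
            FORWARD_COMPONENTS[1]: d_acr - d_c7,
            FORWARD_COMPONENTS[2]: d_c7,
        }
    d_mp = disp(sided("MP", side), 2)
    d_epi = disp(sided("EPICONDYLE", side), 2)
    d_acr = disp(sided("ACROMION", side), 2)
    d_chin = disp(MarkerName.CHIN, 2)
    abduction = d_epi - d_acr
    return {
        "total": d_mp - d_chin,
        HAND_TO_MOUTH_COMPONENTS[0]: (d_mp - d_acr) - abduction,
        HAND_TO_MOUTH_COMPONENTS[1]: abduction,
        HAND_TO_MOUTH_COMPONENTS[2]: d_acr,
        HAND_TO_MOUTH_COMPONENTS[3]: -d_chin,
    }


# ---------------------------------------------------------------------------
# cohort presets

#: Device-error-scale default marker noise, mm per (X, Y, Z) axis.
DEFAULT_NOISE_SD = (2.0, 1.1, 1.65)


@dataclass(frozen=True)
class TruncatedNormal:
    """End-value distribution for one DOF, truncated to plausible bounds."""

    mean: float
    sd: float
    low: float
    high: float

    def __post_init__(self) -> None:
        if self.sd < 0 or self.low > self.high:
            raise ReachcompError("invalid truncated-normal parameters")

    def sample(self, rng: np.random.Generator) -> float:
        if self.sd == 0:
            return float(np.clip(self.mean, self.low, self.high))
        for _ in range(1000):
            x = rng.normal(self.mean, self.sd)
            if self.low <= x <= self.high:
                return float(x)
        return float(np.clip(self.mean, self.low, self.high))


@dataclass(frozen=True)
class StrategyPreset:
    """Distributional joint-strategy recipe for one group and task.

    The numeric ranges below are tuning constants chosen to produce
    plausible magnitudes; only the *direction* of the healthy-vs-stroke
    differences (more trunk flexion, abduction and girdle elevation in the
    stroke group) is anchored to published group comparisons.
    """

    name: str
    group: str
    task: Task
    dof_end: Mapping[str, TruncatedNormal]
    duration: float = 1.2
    noise_sd: tuple[float, float, float] = DEFAULT_NOISE_SD
    uel_mean: float = 717.0  # upper-extremity length, mm
    uel_sd: float = 39.0

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.noise_sd):
            raise ReachcompError("noise_sd must be >= 0")
        unknown = set(self.dof_end) - set(DOF_NAMES)
        if unknown:
            raise ReachcompError(f"unknown DOF name(s) in preset: {sorted(unknown)}")
        object.__setattr__(self, "task", Task(self.task))
        object.__setattr__(self, "dof_end", dict(self.dof_end))


def _tn(mean: float, sd: float, low: float, high: float) -> TruncatedNormal:
    return TruncatedNormal(mean, sd, low, high)


PRESETS: dict[tuple[str, Task], StrategyPreset] = {
    ("healthy", Task.FORWARD_REACH): StrategyPreset(
        name="healthy_forward",
        group="healthy",
        task=Task.FORWARD_REACH,
        dof_end={
            "shoulder_flexion": _tn(72.0, 6.0, 55.0, 90.0),
            "elbow_flexion": _tn(8.0, 6.0, 0.0, 25.0),  # from 90 deg: extension
            "trunk_rotation": _tn(9.0, 3.5, 0.0, 20.0),
            "trunk_flexion": _tn(2.0, 1.5, 0.0, 8.0),
        },
    ),
    ("stroke", Task.FORWARD_REACH): StrategyPreset(
        name="stroke_forward",
        group="stroke",
        task=Task.FORWARD_REACH,
        dof_end={
            "shoulder_flexion": _tn(38.0, 14.0, 10.0, 65.0),
            "elbow_flexion": _tn(50.0, 18.0, 20.0, 85.0),  # incomplete extension
            "trunk_rotation": _tn(11.0, 5.0, 0.0, 25.0),
            "trunk_flexion": _tn(20.0, 10.0, 2.0, 45.0),
        },
        uel_mean=694.0,
        uel_sd=51.0,
    ),
    ("healthy", Task.HAND_TO_MOUTH): StrategyPreset(
        name="healthy_hand_to_mouth",
        group="healthy",
        task=Task.HAND_TO_MOUTH,
        dof_end={
            "elbow_flexion": _tn(140.0, 7.0, 120.0, 160.0),
            "shoulder_flexion": _tn(8.0, 4.0, 0.0, 20.0),
            "shoulder_abduction": _tn(3.0, 3.0, 0.0, 12.0),
            "girdle_elevation": _tn(12.0, 5.0, 0.0, 25.0),  # mm
            "neck_flexion": _tn(0.0, 1.5, -4.0, 4.0),
        },
    ),
    ("stroke", Task.HAND_TO_MOUTH): StrategyPreset(
        name="stroke_hand_to_mouth",
        group="stroke",
        task=Task.HAND_TO_MOUTH,
        dof_end={
            "elbow_flexion": _tn(118.0, 12.0, 95.0, 145.0),
            "shoulder_flexion": _tn(6.0, 4.0, 0.0, 18.0),
            "shoulder_abduction": _tn(28.0, 12.0, 5.0, 60.0),
            "girdle_elevation": _tn(30.0, 10.0, 8.0, 55.0),  # mm
            "neck_flexion": _tn(3.0, 4.0, -4.0, 15.0),
        },
        uel_mean=694.0,
        uel_sd=51.0,
    ),
}


def get_preset(group: str, task: Task | str) -> StrategyPreset:
    """Built-in strategy preset for a group/task pair."""
    try:
        return PRESETS[(group, Task(task))]
    except KeyError:
        raise ReachcompError(f"no preset for group={group!r}, task={task!r}") from None


def simulate_cohort(
    preset: StrategyPreset,
    n: int,
    config: ChainConfig | None = None,
    seed: int | None = None,
    *,
    sampling_rate: float = 60.0,
    side: Side | None = None,
) -> list[tuple[TrialRecording, SubjectRecord]]:
    """Draw ``n`` subjects from a strategy preset, one trial each.

    Per-subject DOF end values come from the preset's truncated normals;
    segment lengths are scaled to a drawn upper-extremity length unless a
    fixed ``config`` is supplied.  Stroke subjects reach with the left arm
    and healthy subjects with the right (mirroring the typical measured
    sides), unless ``side`` is forced.  Fully reproducible given ``seed``.
    """
    if n < 1:
        raise ReachcompError("n must be >= 1")
    rng = np.random.default_rng(seed)
    reach_side = side if side is not None else (
        Side.LEFT if preset.group == "stroke" else Side.RIGHT
    )
    out: list[tuple[TrialRecording, SubjectRecord]] = []
    for k in range(n):
        uel = float(rng.normal(preset.uel_mean, preset.uel_sd)) if config is None else None
        chain = config if config is not None else ChainConfig.from_upper_extremity_length(uel)
        end_values = {dof: dist.sample(rng) for dof, dist in preset.dof_end.items()}
        program = JointProgram.from_end_values(end_values, duration=preset.duration)
        subject_id = f"sim-{preset.group}-{k + 1:03d}"
        trial = simulate_trial(
            chain,
            program,
            preset.task,
            side=reach_side,
            sampling_rate=sampling_rate,
            noise_sd=preset.noise_sd,
            seed=int(rng.integers(0, 2**31 - 1)),
            subject_id=subject_id,
        )
        record = SubjectRecord(
            subject_id=subject_id,
            group=preset.group,
            affected_side=reach_side if preset.group == "stroke" else None,
            upper_extremity_length=chain.upper_extremity_length,
        )
        out.append((trial, record))
    return out


def add_rigid_translation(trial: TrialRecording, offsets: np.ndarray) -> TrialRecording:
    """Add a per-frame (n, 3) whole-body translation to every marker.

    Useful for testing reference-frame invariance: trochanter calibration
    must cancel any such common-mode motion exactly.
    """
    offsets = np.asarray(offsets, dtype=np.float64)
    if offsets.shape != (trial.n_frames, 3):
        raise ReachcompError(
            f"offsets must have shape ({trial.n_frames}, 3), got {offsets.shape}"
        )
    positions = {m: a + offsets for m, a in trial.positions.items()}
    return replace(trial, positions=positions,
                   provenance=trial.provenance + ("rigid_translation_added",))
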