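"""Trial and subject data models.

A :class:`TrialRecording` is the unit every other module consumes: a set of
time-aligned 3D marker trajectories plus the metadata needed to interpret
them (task, reaching side, sampling rate).  Positions are always float64
arrays of shape ``(n_frames, 3)`` in millimetres, with missing samples kept
as explicit NaN rows/cells rather than dropped.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import ReachcompError
from .markers import MarkerName, Side, Task

AXES = ("X", "Y", "Z")


def axis_index(axis: str | int) -> int:
    """Map ``'X'|'Y'|'Z'`` (or 0/1/2) to a column index."""
    if isinstance(axis, int):
        if axis not in (0, 1, 2):
            raise ValueError(f"axis index out of range: {axis}")
        return axis
    try:
        return AXES.index(axis.upper())
    except ValueError:
        raise ValueError(f"unknown axis {axis!r}; expected one of {AXES}") from None


@dataclass
class TrialRecording:
    """One recorded (or simulated) reaching trial.

    Parameters
    ----------
    positions
        Mapping from marker name to an ``(n_frames, 3)`` float array in mm,
        columns ordered X (lateral), Y (anterior), Z (vertical).
    sampling_rate
        Frames per second; the reference protocol value is 60.
    task
        Which reaching task the trial records.
    reaching_side
        Which arm performed the reach.
    upper_extremity_length
        Acromion-to-fingertip length in mm, if measured (used only by the
        arm-length percentage denominator).
    provenance
        Free-form processing notes (gap interpolation, filtering, mirroring).
    """

    positions: dict[MarkerName, np.ndarray]
    sampling_rate: float
    task: Task
    reaching_side: Side
    subject_id: str = ""
    upper_extremity_length: float | None = None
    source: str = ""
    provenance: tuple[str, ...] = ()
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.task = Task(self.task)
        self.reaching_side = Side(self.reaching_side)
        if not self.positions:
            raise ReachcompError("trial has no markers")
        if not self.sampling_rate > 0:
            raise ReachcompError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        clean: dict[MarkerName, np.ndarray] = {}
        n_ref: int | None = None
        for name, arr in self.positions.items():
            name = MarkerName(name)
            arr = np.asarray(arr, dtype=np.float64)
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise ReachcompError(
                    f"marker {name.value}: expected shape (n, 3), got {arr.shape}"
                )
            if arr.shape[0] < 2:
                raise ReachcompError(f"marker {name.value}: need >= 2 frames")
            if n_ref is None:
                n_ref = arr.shape[0]
            elif arr.shape[0] != n_ref:
                raise ReachcompError(
                    f"marker {name.value}: {arr.shape[0]} frames, expected {n_ref}"
                )
            clean[name] = arr
        # deterministic marker order (enumeration order)
        self.positions = {m: clean[m] for m in MarkerName if m in clean}

    # -- convenience accessors -------------------------------------------

    @property
    def n_frames(self) -> int:
        return next(iter(self.positions.values())).shape[0]

    @property
    def markers(self) -> tuple[MarkerName, ...]:
        return tuple(self.positions)

    def marker(self, name: MarkerName) -> np.ndarray:
        try:
            return self.positions[MarkerName(name)]
        except KeyError:
            raise ReachcompError(f"marker {MarkerName(name).value} not in trial") from None

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.sampling_rate

    def replace(self, **changes) -> "TrialRecording":
        """Return a copy with ``changes`` applied (positions are copied)."""
        if "positions" not in changes:
            changes["positions"] = {m: a.copy() for m, a in self.positions.items()}
        return dataclasses.replace(self, **changes)

    def with_note(self, note: str) -> "TrialRecording":
        return self.replace(provenance=self.provenance + (note,))

    def allclose(self, other: "TrialRecording", atol: float = 1e-9) -> bool:
        """Positional + metadata equality within ``atol`` mm (NaN == NaN)."""
        if set(self.positions) != set(other.positions):
            return False
        if (self.task, self.reaching_side) != (other.task, other.reaching_side):
            return False
        if abs(self.sampling_rate - other.sampling_rate) > 1e-9:
            return False
        return all(
            np.allclose(self.positions[m], other.positions[m], atol=atol, rtol=0.0, equal_nan=True)
            for m in self.positions
        )


@dataclass(frozen=True)
class SubjectRecord:
    """Demographic/clinical metadata attached to a subject's trials.

    Clinical motor scores (``fma_total``, ``fma_proximal``) are metadata
    carried through to cohort tables; they are admissible only for the
    stroke group.
    """

    subject_id: str
    group: str
    age: float | None = None
    sex: str | None = None
    affected_side: Side | None = None
    fma_total: float | None = None
    fma_proximal: float | None = None
    upper_extremity_length: float | None = None

    def __post_init__(self) -> None:
        if self.group not in ("healthy", "stroke"):
            raise ReachcompError(f"group must be 'healthy' or 'stroke', got {self.group!r}")
        if self.group == "healthy" and (
            self.fma_total is not None or self.fma_proximal is not None
        ):
            raise ReachcompError("FMA scores are only admissible for the stroke group")


@dataclass(frozen=True)
class MarkerDiagnostic:
    """One problem found by marker-set validation (returned, never raised)."""

    marker: MarkerName
    reason: str
    nan_fraction: float = 0.0

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.marker.value}: {self.reason}"
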