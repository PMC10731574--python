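"""Readers and writers for the tab-separated trial table dialect.

Dialect: UTF-8, tab-separated. Metadata lines come first, one ``#key=value``
per line; mandatory keys are ``task``, ``side`` and ``sampling_rate``.  The
header row declares ``time`` followed by ``<MARKER>_x``/``_y``/``_z`` column
triples; each subsequent row is one frame.  Missing samples are literal
``nan`` cells.

Short occlusion gaps (<= ``max_gap_interp_s``, default 0.2 s) are linearly
interpolated at read time and flagged in the trial's provenance; longer gaps
are left as NaN for :func:`validate_marker_set` to report.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np

from .errors import TrialFormatError, TrialParseError
from .markers import MarkerName, Side, Task, required_markers
from .trial import MarkerDiagnostic, TrialRecording

_MANDATORY_KEYS = ("task", "side", "sampling_rate")
_AXIS_SUFFIXES = ("_x", "_y", "_z")

#: Default maximum occlusion gap (seconds) repaired by linear interpolation.
DEFAULT_MAX_GAP_INTERP_S = 0.2


def _format_float(x: float) -> str:
    if math.isnan(x):
        return "nan"
    return format(x, ".17g")


def write_trial_table(trial: TrialRecording, path: str | Path) -> Path:
    """Write ``trial`` in the trial-table dialect; returns the path written.

    Output is deterministic: metadata keys in fixed order, marker columns in
    :class:`MarkerName` enumeration order, floats in shortest round-trip
    ``%.17g`` form.  Re-reading the file reproduces the trial to 1e-9 mm.
    """
    path = Path(path)
    lines = [
        f"#task={trial.task.value}",
        f"#side={trial.reaching_side.value}",
        f"#sampling_rate={_format_float(trial.sampling_rate)}",
    ]
    if trial.subject_id:
        lines.append(f"#subject_id={trial.subject_id}")
    if trial.upper_extremity_length is not None:
        lines.append(f"#upper_extremity_length={_format_float(trial.upper_extremity_length)}")
    if trial.source:
        lines.append(f"#source={trial.source}")

    markers = [m for m in MarkerName if m in trial.positions]
    header = ["time"] + [f"{m.value}{sfx}" for m in markers for sfx in _AXIS_SUFFIXES]
    lines.append("\t".join(header))
    dt = 1.0 / trial.sampling_rate
    for i in range(trial.n_frames):
        row = [format(i * dt, ".9f")]
        for m in markers:
            row.extend(_format_float(v) for v in trial.positions[m][i])
        lines.append("\t".join(row))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def _interpolate_short_gaps(
    positions: dict[MarkerName, np.ndarray], rate: float, max_gap_s: float
) -> list[str]:
    """In-place linear repair of interior NaN runs <= max_gap_s; returns notes."""
    max_frames = int(round(max_gap_s * rate))
    notes: list[str] = []
    if max_frames < 1:
        return notes
    for marker, arr in positions.items():
        repaired = 0
        for ax in range(3):
            col = arr[:, ax]
            isnan = np.isnan(col)
            if not isnan.any() or isnan.all():
                continue
            idx = np.flatnonzero(np.diff(np.concatenate(([0], isnan.view(np.int8), [0]))))
            for start, stop in zip(idx[::2], idx[1::2]):  # NaN run is [start, stop)
                run = stop - start
                if run > max_frames or start == 0 or stop == len(col):
                    continue  # too long, or touches trial edge: leave as NaN
                x0, x1 = col[start - 1], col[stop]
                t = np.arange(1, run + 1) / (run + 1)
                col[start:stop] = x0 + t * (x1 - x0)
                repaired += run
        if repaired:
            notes.append(f"interpolated:{marker.value}:{repaired}")
    return notes


def read_trial_table(
    path: str | Path,
    max_gap_interp_s: float | None = DEFAULT_MAX_GAP_INTERP_S,
) -> TrialRecording:
    """Parse a trial-table file into a :class:`TrialRecording`.

    Frame spacing is verified against the declared sampling rate to within
    1e-6 s.  Pass ``max_gap_interp_s=None`` (or 0) to disable gap repair.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    lines = path.read_text(encoding="utf-8").splitlines()
    i = 0
    while i < len(lines) and lines[i].startswith("#"):
        body = lines[i][1:]
        if "=" not in body:
            raise TrialFormatError(f"{path}: malformed metadata line {i + 1}: {lines[i]!r}")
        key, _, value = body.partition("=")
        meta[key.strip()] = value.strip()
        i += 1
    for key in _MANDATORY_KEYS:
        if key not in meta:
            raise TrialFormatError(f"{path}: missing mandatory metadata key '#{key}='")
    if i >= len(lines):
        raise TrialFormatError(f"{path}: no header row")

    header = lines[i].split("\t")
    i += 1
    if not header or header[0] != "time":
        raise TrialFormatError(f"{path}: header must start with 'time', got {header[:1]}")
    markers: list[MarkerName] = []
    seen: set[str] = set()
    for j in range(1, len(header), 3):
        triple = header[j : j + 3]
        base = triple[0][:-2] if triple[0].endswith(_AXIS_SUFFIXES) else triple[0]
        expected = [f"{base}{sfx}" for sfx in _AXIS_SUFFIXES]
        if triple != expected:
            raise TrialFormatError(
                f"{path}: expected column triple {expected}, got {triple}"
            )
        if base in seen:
            raise TrialFormatError(f"{path}: duplicate marker column {base}")
        seen.add(base)
        try:
            markers.append(MarkerName(base))
        except ValueError:
            raise TrialFormatError(f"{path}: unknown marker column {base!r}") from None

    data_rows = [ln for ln in lines[i:] if ln.strip()]
    n = len(data_rows)
    if n < 2:
        raise TrialFormatError(f"{path}: need at least 2 frames, found {n}")
    width = 1 + 3 * len(markers)
    times = np.empty(n)
    data = np.empty((n, 3 * len(markers)))
    for r, ln in enumerate(data_rows):
        cells = ln.split("\t")
        if len(cells) != width:
            raise TrialFormatError(
                f"{path}: row {r + 1} has {len(cells)} cells, expected {width}"
            )
        for c, cell in enumerate(cells):
            try:
                v = float(cell)
            except ValueError:
                raise TrialParseError(
                    f"{path}: non-numeric cell {cell!r} at data row {r + 1}, "
                    f"column {header[c]!r}"
                ) from None
            if c == 0:
                times[r] = v
            else:
                data[r, c - 1] = v

    try:
        rate = float(meta["sampling_rate"])
    except ValueError:
        raise TrialFormatError(
            f"{path}: sampling_rate is not numeric: {meta['sampling_rate']!r}"
        ) from None
    dt = 1.0 / rate
    if np.max(np.abs(np.diff(times) - dt)) > 1e-6:
        raise TrialFormatError(
            f"{path}: frame spacing deviates from 1/sampling_rate by more than 1e-6 s"
        )

    positions = {
        m: data[:, 3 * k : 3 * k + 3].copy() for k, m in enumerate(markers)
    }
    notes: list[str] = []
    if max_gap_interp_s:
        notes = _interpolate_short_gaps(positions, rate, max_gap_interp_s)

    try:
        task = Task(meta["task"])
    except ValueError:
        raise TrialFormatError(f"{path}: unknown task {meta['task']!r}") from None
    try:
        side = Side(meta["side"])
    except ValueError:
        raise TrialFormatError(f"{path}: unknown side {meta['side']!r}") from None

    uel = meta.get("upper_extremity_length")
    return TrialRecording(
        positions=positions,
        sampling_rate=rate,
        task=task,
        reaching_side=side,
        subject_id=meta.get("subject_id", ""),
        upper_extremity_length=float(uel) if uel is not None else None,
        source=meta.get("source", str(path)),
        provenance=tuple(notes),
    )


def validate_marker_set(
    trial: TrialRecording, max_nan_fraction: float = 0.10
) -> list[MarkerDiagnostic]:
    """Check that the markers required by ``trial.task`` are usable.

    Returns an empty list iff every required marker is present with fewer
    than ``max_nan_fraction`` NaN frames.  Problems are reported as
    diagnostics, never raised, so callers can batch-screen trials.
    """
    diagnostics: list[MarkerDiagnostic] = []
    for marker in required_markers(trial.task, trial.reaching_side):
        if marker not in trial.positions:
            diagnostics.append(
                MarkerDiagnostic(marker, f"required for {trial.task.value} but absent")
            )
            continue
        frac = float(np.mean(np.isnan(trial.positions[marker]).any(axis=1)))
        if frac >= max_nan_fraction:
            diagnostics.append(
                MarkerDiagnostic(
                    marker,
                    f"gap fraction {frac:.1%} exceeds limit {max_nan_fraction:.0%}",
                    nan_fraction=frac,
                )
            )
    return diagnostics
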