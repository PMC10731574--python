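"""Minimal C3D interchange support.

A compact, dependency-free reader/writer for the subset of the C3D standard
needed to move marker trajectories in and out of this package: Intel
byte-order files, 3D point data stored as floats or scaled integers, POINT
group parameters (USED, LABELS, RATE, SCALE, UNITS, FRAMES).  Analog
channels are skipped.  This is not a general C3D library — force platforms,
multi-subject files and DEC/MIPS encodings are out of scope.

:func:`ingest_c3d` converts a C3D file to a :class:`TrialRecording`,
relabelling markers through a caller-supplied map, converting positions to
millimetres, and permuting axes into the package convention (X lateral,
Y forward, Z up).
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import MarkerMappingError, TrialFormatError, UnitError
from .markers import MarkerName, Side, Task, required_markers
from .trial import TrialRecording
from .trial_io import DEFAULT_MAX_GAP_INTERP_S, _interpolate_short_gaps

_BLOCK = 512
_INTEL = 84

_UNIT_TO_MM = {"mm": 1.0, "cm": 10.0, "m": 1000.0}


@dataclass
class C3DContent:
    """Raw point data pulled from a C3D file (positions in file units)."""

    labels: list[str]
    points: np.ndarray  # (n_frames, n_points, 3), NaN where residual < 0
    rate: float
    units: str


# ---------------------------------------------------------------------------
# reading


def _parse_parameters(buf: bytes) -> dict[tuple[str, str], object]:
    """Parse the parameter section into {(GROUP, PARAM): value}."""
    if len(buf) < 4:
        raise TrialFormatError("C3D parameter section truncated")
    processor = buf[3]
    if processor != _INTEL:
        raise TrialFormatError(f"unsupported C3D processor type {processor} (only Intel)")
    groups: dict[int, str] = {}
    params: list[tuple[int, str, object]] = []
    pos = 4
    while pos + 2 <= len(buf):
        n_chars = struct.unpack_from("<b", buf, pos)[0]
        group_id = struct.unpack_from("<b", buf, pos + 1)[0]
        if n_chars == 0 or group_id == 0:
            break
        name_len = abs(n_chars)
        name = buf[pos + 2 : pos + 2 + name_len].decode("ascii").strip()
        offset_pos = pos + 2 + name_len
        offset = struct.unpack_from("<h", buf, offset_pos)[0]
        body = offset_pos + 2
        if group_id < 0:  # group definition record
            groups[-group_id] = name
        else:  # parameter record
            dtype = struct.unpack_from("<b", buf, body)[0]
            n_dims = struct.unpack_from("<B", buf, body + 1)[0]
            dims = list(buf[body + 2 : body + 2 + n_dims])
            n_elem = int(np.prod(dims)) if dims else 1
            data_pos = body + 2 + n_dims
            if dtype == -1:
                raw = buf[data_pos : data_pos + n_elem]
                if len(dims) <= 1:
                    value: object = raw.decode("ascii")
                else:
                    width = dims[0]
                    count = n_elem // width
                    value = [
                        raw[k * width : (k + 1) * width].decode("ascii").strip()
                        for k in range(count)
                    ]
            elif dtype == 1:
                value = list(struct.unpack_from(f"<{n_elem}b", buf, data_pos))
            elif dtype == 2:
                value = list(struct.unpack_from(f"<{n_elem}h", buf, data_pos))
            elif dtype == 4:
                value = list(struct.unpack_from(f"<{n_elem}f", buf, data_pos))
            else:
                raise TrialFormatError(f"unknown C3D parameter type {dtype}")
            if dtype != -1 and len(dims) == 0:
                value = value[0]
            params.append((group_id, name, value))
        if offset == 0:
            break
        pos = offset_pos + offset

    out: dict[tuple[str, str], object] = {}
    for gid, name, value in params:
        out[(groups.get(gid, str(gid)), name)] = value
    return out


def read_c3d(path: str | Path) -> C3DContent:
    """Read point trajectories from an Intel-format C3D file."""
    raw = Path(path).read_bytes()
    if len(raw) < _BLOCK or raw[1] != 0x50:
        raise TrialFormatError(f"{path}: not a C3D file")
    param_block = raw[0]
    n_points = struct.unpack_from("<H", raw, 2)[0]
    analog_per_frame = struct.unpack_from("<H", raw, 4)[0]
    first_frame = struct.unpack_from("<H", raw, 6)[0]
    last_frame = struct.unpack_from("<H", raw, 8)[0]
    scale = struct.unpack_from("<f", raw, 12)[0]
    data_block = struct.unpack_from("<H", raw, 16)[0]
    rate = struct.unpack_from("<f", raw, 20)[0]

    params = _parse_parameters(raw[(param_block - 1) * _BLOCK :])
    n_points = int(params.get(("POINT", "USED"), n_points))
    rate = float(params.get(("POINT", "RATE"), rate))
    scale = float(params.get(("POINT", "SCALE"), scale))
    units = str(params.get(("POINT", "UNITS"), "mm")).strip()
    labels_val = params.get(("POINT", "LABELS"))
    if isinstance(labels_val, list):
        labels = [str(x).strip() for x in labels_val[:n_points]]
    else:
        labels = [f"P{k + 1}" for k in range(n_points)]
    n_frames = int(params.get(("POINT", "FRAMES"), last_frame - first_frame + 1))

    float_data = scale < 0
    word = 4 if float_data else 2
    frame_words = 4 * n_points + analog_per_frame
    start = (data_block - 1) * _BLOCK
    needed = start + n_frames * frame_words * word
    if needed > len(raw):
        raise TrialFormatError(f"{path}: data section truncated")

    if float_data:
        flat = np.frombuffer(raw, dtype="<f4", count=n_frames * frame_words, offset=start)
    else:
        flat = np.frombuffer(raw, dtype="<i2", count=n_frames * frame_words, offset=start)
    frames = flat.reshape(n_frames, frame_words)[:, : 4 * n_points].reshape(
        n_frames, n_points, 4
    )
    coords = frames[:, :, :3].astype(np.float64)
    if float_data:
        residual = frames[:, :, 3].astype(np.float64)
    else:
        coords *= abs(scale)
        residual = frames[:, :, 3].astype(np.float64)
    coords[residual < 0] = np.nan
    return C3DContent(labels=labels, points=coords, rate=rate, units=units)


# ---------------------------------------------------------------------------
# writing (float storage, no analog) — used for interchange and test fixtures


def _param_record(group_id: int, name: str, dtype: int, dims: list[int], data: bytes) -> bytes:
    body = struct.pack("<bB", dtype, len(dims)) + bytes(dims) + data + b"\x00"
    head = struct.pack("<bb", len(name), group_id) + name.encode("ascii")
    return head + struct.pack("<h", 2 + len(body)) + body


def write_c3d(
    path: str | Path,
    labels: list[str],
    points: np.ndarray,
    rate: float,
    units: str = "mm",
) -> Path:
    """Write ``points`` of shape (n_frames, n_points, 3) as a float C3D file.

    NaN samples are stored with a negative residual (the C3D convention for
    invalid points) and read back as NaN.
    """
    path = Path(path)
    points = np.asarray(points, dtype=np.float64)
    n_frames, n_points, _ = points.shape
    if len(labels) != n_points:
        raise ValueError("labels/points mismatch")

    label_width = max(4, max(len(s) for s in labels))
    label_bytes = b"".join(s.ljust(label_width).encode("ascii") for s in labels)

    records = b"".join(
        [
            struct.pack("<bb", 5, -1) + b"POINT" + struct.pack("<h", 3) + b"\x00",
            _param_record(1, "USED", 2, [], struct.pack("<h", n_points)),
            _param_record(1, "FRAMES", 2, [], struct.pack("<h", min(n_frames, 32767))),
            _param_record(1, "RATE", 4, [], struct.pack("<f", rate)),
            _param_record(1, "SCALE", 4, [], struct.pack("<f", -1.0)),
            _param_record(1, "UNITS", -1, [len(units)], units.encode("ascii")),
            _param_record(
                1, "LABELS", -1, [label_width, n_points], label_bytes
            ),
        ]
    )
    param_payload = struct.pack("<BBBB", 0x50, 0x50, 0, _INTEL) + records
    n_param_blocks = -(-len(param_payload) // _BLOCK)
    param_payload = param_payload.ljust(n_param_blocks * _BLOCK, b"\x00")
    # patch declared parameter block count
    param_payload = param_payload[:2] + bytes([n_param_blocks]) + param_payload[3:]
    data_block = 2 + n_param_blocks

    header = bytearray(_BLOCK)
    header[0] = 2  # parameter section starts at block 2
    header[1] = 0x50
    struct.pack_into("<H", header, 2, n_points)
    struct.pack_into("<H", header, 4, 0)  # no analog
    struct.pack_into("<H", header, 6, 1)
    struct.pack_into("<H", header, 8, min(n_frames, 65535))
    struct.pack_into("<f", header, 12, -1.0)
    struct.pack_into("<H", header, 16, data_block)
    struct.pack_into("<H", header, 18, 1)
    struct.pack_into("<f", header, 20, rate)

    frames = np.zeros((n_frames, n_points, 4), dtype="<f4")
    frames[:, :, :3] = points
    invalid = np.isnan(points).any(axis=2)
    frames[:, :, 3] = np.where(invalid, -1.0, 0.0)
    frames[:, :, :3][invalid] = 0.0

    path.write_bytes(bytes(header) + param_payload + frames.tobytes())
    return path


# ---------------------------------------------------------------------------
# ingest into the package data model


def _axis_permutation(axes: tuple[str, str, str]) -> tuple[list[int], np.ndarray]:
    """Parse an axis spec like ('+y', '-x', '+z') into indices and signs."""
    order: list[int] = []
    signs: list[float] = []
    for spec in axes:
        spec = spec.lower().strip()
        sign = -1.0 if spec.startswith("-") else 1.0
        letter = spec.lstrip("+-")
        if letter not in ("x", "y", "z"):
            raise ValueError(f"bad axis spec {spec!r}")
        order.append("xyz".index(letter))
        signs.append(sign)
    if sorted(order) != [0, 1, 2]:
        raise ValueError(f"axis spec {axes!r} is not a permutation of x, y, z")
    return order, np.asarray(signs)


def ingest_c3d(
    path: str | Path,
    marker_map: dict[str, MarkerName | str],
    *,
    task: Task | str,
    side: Side | str,
    axes: tuple[str, str, str] = ("+x", "+y", "+z"),
    subject_id: str = "",
    upper_extremity_length: float | None = None,
    max_gap_interp_s: float | None = DEFAULT_MAX_GAP_INTERP_S,
) -> TrialRecording:
    """Load a C3D file as a :class:`TrialRecording`.

    Parameters
    ----------
    marker_map
        Mapping from C3D point labels to package marker names, e.g.
        ``{"RFIN": "MP_R", "RSHO": "ACROMION_R"}``.
    axes
        Where each output axis comes from in the file's frame:
        ``axes[0]`` feeds output X (lateral), ``axes[1]`` output Y
        (forward), ``axes[2]`` output Z (up); each entry is ``±x|y|z``.

    Raises
    ------
    MarkerMappingError
        If a marker required by ``task`` is not covered by ``marker_map``
        (the message lists the file's unmapped labels as candidates).
    UnitError
        If POINT:UNITS is not one of mm, cm, m.
    """
    task = Task(task)
    side = Side(side)
    content = read_c3d(path)
    unit = content.units.lower()
    if unit not in _UNIT_TO_MM:
        raise UnitError(f"{path}: unsupported POINT:UNITS {content.units!r}")
    to_mm = _UNIT_TO_MM[unit]

    order, signs = _axis_permutation(axes)
    label_index = {lbl: k for k, lbl in enumerate(content.labels)}
    positions: dict[MarkerName, np.ndarray] = {}
    for label, marker in marker_map.items():
        if label not in label_index:
            continue  # map may cover labels absent from this particular file
        arr = content.points[:, label_index[label], :][:, order] * signs * to_mm
        positions[MarkerName(marker)] = arr

    missing = [m for m in required_markers(task, side) if m not in positions]
    if missing:
        unmapped = [lbl for lbl in content.labels if lbl not in marker_map]
        raise MarkerMappingError(
            f"{path}: no mapping yields required marker(s) "
            f"{', '.join(m.value for m in missing)}; unmapped labels in file: "
            f"{unmapped}"
        )

    notes: list[str] = [f"ingest_c3d:axes={','.join(axes)}:unit={unit}"]
    if max_gap_interp_s:
        notes += _interpolate_short_gaps(positions, content.rate, max_gap_interp_s)
    return TrialRecording(
        positions=positions,
        sampling_rate=content.rate,
        task=task,
        reaching_side=side,
        subject_id=subject_id,
        upper_extremity_length=upper_extremity_length,
        source=str(path),
        provenance=tuple(notes),
    )
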