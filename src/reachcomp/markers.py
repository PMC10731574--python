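"""Marker vocabulary, tasks, sides, and per-task marker requirements.

The marker set is a deliberately small, clinically practical one: ten
anatomical sites covering the chin, upper trunk, both shoulder girdles, both
elbows, both index-finger MP joints, and both greater trochanters.  The
trochanter on the reaching side serves as the pelvis reference for every
displacement.

Axis convention used throughout the package: X lateral (positive toward the
reaching side after canonicalization), Y anterior (positive forward),
Z vertical (positive up).  Units are millimetres and seconds everywhere.
"""

from __future__ import annotations

from enum import Enum


class Side(str, Enum):
    LEFT = "left"
    RIGHT = "right"

    @property
    def suffix(self) -> str:
        return "L" if self is Side.LEFT else "R"

    @property
    def other(self) -> "Side":
        return Side.RIGHT if self is Side.LEFT else Side.LEFT


class Task(str, Enum):
    FORWARD_REACH = "forward_reach"
    HAND_TO_MOUTH = "hand_to_mouth"


class MarkerName(str, Enum):
    """The ten admissible marker names, in canonical (file-column) order."""

    CHIN = "CHIN"
    C7 = "C7"
    ACROMION_L = "ACROMION_L"
    ACROMION_R = "ACROMION_R"
    EPICONDYLE_L = "EPICONDYLE_L"
    EPICONDYLE_R = "EPICONDYLE_R"
    MP_L = "MP_L"
    MP_R = "MP_R"
    TROCHANTER_L = "TROCHANTER_L"
    TROCHANTER_R = "TROCHANTER_R"

    @property
    def base(self) -> str:
        """Anatomical site without the side suffix."""
        name = self.value
        if name.endswith(("_L", "_R")):
            return name[:-2]
        return name

    @property
    def side(self) -> Side | None:
        """Side of a bilateral marker, or None for midline markers."""
        if self.value.endswith("_L"):
            return Side.LEFT
        if self.value.endswith("_R"):
            return Side.RIGHT
        return None

    @property
    def mirrored(self) -> "MarkerName":
        """The contralateral marker (identity for midline markers)."""
        if self.value.endswith("_L"):
            return MarkerName(self.value[:-2] + "_R")
        if self.value.endswith("_R"):
            return MarkerName(self.value[:-2] + "_L")
        return self


#: Bilateral anatomical sites (each present as _L and _R).
BILATERAL_SITES = ("ACROMION", "EPICONDYLE", "MP", "TROCHANTER")
#: Midline sites.
MIDLINE_SITES = ("CHIN", "C7")


def sided(site: str, side: Side) -> MarkerName:
    """Resolve a bilateral site name to the marker on ``side``."""
    return MarkerName(f"{site}_{side.suffix}")


def required_markers(task: Task, side: Side) -> tuple[MarkerName, ...]:
    """Markers a decomposition needs for ``task`` reaching with ``side``.

    Forward reach uses the MP joint, acromion, C7 and trochanter chain;
    hand-to-mouth additionally needs the humeral epicondyle and the chin.
    """
    base = (
        sided("MP", side),
        sided("ACROMION", side),
        MarkerName.C7,
        sided("TROCHANTER", side),
    )
    if task is Task.FORWARD_REACH:
        return base
    return base + (sided("EPICONDYLE", side), MarkerName.CHIN)
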