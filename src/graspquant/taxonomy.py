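"""Grasp taxonomy: the 13 training grasps and the per-finger subsets.

Not every finger contacts the object in every grasp, so each finger is
trained on its own subset: the ring and little fingers flex out of the
way in tool-oriented grasps (finger extension, light tool, palmar
pinch, tripod, writing tripod) and the middle finger takes no part in
the palmar pinch.  The index finger uses all 13 grasps, the middle 12,
the ring and little fingers 8 each.
"""

from __future__ import annotations

FINGERS: tuple[str, ...] = ("index", "middle", "ring", "little")

#: The 13 taxonomy grasps used for training, alphabetical.
GRASPS: tuple[str, ...] = (
    "adducted_thumb",
    "finger_extension",
    "lateral",
    "light_tool",
    "medium_wrap",
    "palmar_pinch",
    "parallel_extension",
    "power_sphere",
    "precision_disc",
    "precision_sphere",
    "prismatic_4_fingers",
    "tripod",
    "writing_tripod",
)

_RING_LITTLE_EXCLUDED = frozenset(
    {"finger_extension", "light_tool", "palmar_pinch", "tripod", "writing_tripod"}
)

_FINGER_SUBSETS: dict[str, tuple[str, ...]] = {
    "index": GRASPS,
    "middle": tuple(g for g in GRASPS if g != "palmar_pinch"),
    "ring": tuple(g for g in GRASPS if g not in _RING_LITTLE_EXCLUDED),
    "little": tuple(g for g in GRASPS if g not in _RING_LITTLE_EXCLUDED),
}

#: Human-readable grasp names as they appear in occurrence reports.
DISPLAY_NAMES: dict[str, str] = {
    "adducted_thumb": "Adducted thumb",
    "finger_extension": "Finger extension",
    "lateral": "Lateral",
    "light_tool": "Light tool",
    "medium_wrap": "Medium wrap",
    "palmar_pinch": "Palmar pinch",
    "parallel_extension": "Parallel extension",
    "power_sphere": "Power sphere",
    "precision_disc": "Precision disc",
    "precision_sphere": "Precision sphere",
    "prismatic_4_fingers": "Prismatic 4 fingers",
    "tripod": "Tripod",
    "writing_tripod": "Writing tripod",
}


def check_finger(finger: str) -> str:
    if finger not in FINGERS:
        raise ValueError(f"unknown finger {finger!r}; expected one of {FINGERS}")
    return finger


def finger_grasps(finger: str) -> tuple[str, ...]:
    """Return the ordered grasp subset a given finger is trained on."""
    return _FINGER_SUBSETS[check_finger(finger)]
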