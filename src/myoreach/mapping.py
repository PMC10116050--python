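"""Motion classes and limb-motion -> cursor-motion mappings.

Three presets cover the study's participant groups:

* ``right_handed`` — wrist flexion/extension drive cursor left/right, hand
  open/close drive up/down (pattern recognition); in direct control the same
  flexor/extensor pair is reused on whichever axis is active, extension
  positive.
* ``left_handed`` — flexion/extension reversed on both methods.
* ``dmd`` — the supinated-forearm variant: hand close/open drive left/right
  and wrist extension/flexion drive up/down in pattern recognition; the
  direct-control sign convention matches the left-handed preset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum


class MotionClass(Enum):
    HAND_OPEN = "hand_open"
    HAND_CLOSE = "hand_close"
    WRIST_FLEXION = "wrist_flexion"
    WRIST_EXTENSION = "wrist_extension"
    NO_MOTION = "no_motion"


MOTION_CLASSES = tuple(MotionClass)

# unit cursor directions
_LEFT = (-1.0, 0.0)
_RIGHT = (1.0, 0.0)
_UP = (0.0, 1.0)
_DOWN = (0.0, -1.0)


@dataclass(frozen=True)
class MotionMapping:
    """Limb-motion to cursor-direction mapping for one participant group.

    ``pr_directions`` maps each motion class to a signed unit direction
    (``NO_MOTION`` is absent — it yields no motion).  ``dc_axis_sign`` gives,
    per axis (x, y), the cursor sign produced by a positive direct-control
    signal, i.e. by extensor-minus-flexor dominance.
    """

    name: str
    pr_directions: dict[MotionClass, tuple[float, float]] = field(hash=False)
    dc_axis_sign: tuple[float, float]

    def __post_init__(self) -> None:
        moving = {c for c in MotionClass if c is not MotionClass.NO_MOTION}
        if set(self.pr_directions) != moving:
            raise ValueError("mapping must cover the four moving motion classes")
        dirs = set(self.pr_directions.values())
        if len(dirs) != 4:
            raise ValueError("mapping must be bijective: each direction used once")

    def pr_vector(self, cls: MotionClass, magnitude: float) -> tuple[float, float]:
        if cls is MotionClass.NO_MOTION:
            return (0.0, 0.0)
        dx, dy = self.pr_directions[cls]
        return (dx * magnitude, dy * magnitude)

    def class_for_direction(self, axis: int, sign: float) -> MotionClass:
        """Inverse lookup: the motion class that moves the cursor along
        ``axis`` (0=x, 1=y) with the given sign."""
        want = [0.0, 0.0]
        want[axis] = 1.0 if sign > 0 else -1.0
        for cls, d in self.pr_directions.items():
            if d == tuple(want):
                return cls
        raise KeyError(f"no class maps to axis {axis} sign {sign}")


RIGHT_HANDED = MotionMapping(
    name="right_handed",
    pr_directions={
        MotionClass.WRIST_FLEXION: _LEFT,
        MotionClass.WRIST_EXTENSION: _RIGHT,
        MotionClass.HAND_OPEN: _UP,
        MotionClass.HAND_CLOSE: _DOWN,
    },
    dc_axis_sign=(1.0, -1.0),  # extension -> right on x, down on y
)

LEFT_HANDED = MotionMapping(
    name="left_handed",
    pr_directions={
        MotionClass.WRIST_EXTENSION: _LEFT,
        MotionClass.WRIST_FLEXION: _RIGHT,
        MotionClass.HAND_OPEN: _UP,
        MotionClass.HAND_CLOSE: _DOWN,
    },
    dc_axis_sign=(-1.0, 1.0),
)

DMD = MotionMapping(
    name="dmd",
    pr_directions={
        MotionClass.HAND_CLOSE: _LEFT,
        MotionClass.HAND_OPEN: _RIGHT,
        MotionClass.WRIST_EXTENSION: _UP,
        MotionClass.WRIST_FLEXION: _DOWN,
    },
    dc_axis_sign=(-1.0, 1.0),  # extension -> left on x, up on y
)

PRESETS: dict[str, MotionMapping] = {
    "right_handed": RIGHT_HANDED,
    "left_handed": LEFT_HANDED,
    "dmd": DMD,
}


def get_mapping(name: str) -> MotionMapping:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown mapping preset '{name}'; choose from {sorted(PRESETS)}"
        ) from None
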