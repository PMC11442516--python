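"""Homogeneous 4x4 transforms between named coordinate frames.

The simulated rig chains four frames: robot base {b}, flange {f}, probe tip
{p} and ultrasound volume {vol}.  A transform ``jTi`` maps points expressed in
frame {i} into frame {j}; composition is plain left-to-right matrix product,
and the frame names are checked at composition time so a silently reversed
chain raises instead of producing a transposed result.

Rigid transforms carry an SO(3) rotation block; the probe-to-volume
calibration matrix additionally absorbs the anisotropic pixel-spacing scaling
and is therefore affine, so rigidity is validated only on request.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import yaml

__all__ = ["HomogeneousTransform", "FrameChainError"]

_RIGID_TOL = 1e-9


class FrameChainError(ValueError):
    """Raised when transforms are composed against a mismatched frame chain."""


@dataclass(frozen=True)
class HomogeneousTransform:
    """A 4x4 homogeneous transform mapping ``from_frame`` into ``to_frame``."""

    matrix: np.ndarray
    from_frame: str = "?"
    to_frame: str = "?"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValueError(f"transform matrix must be 4x4, got {m.shape}")
        if not np.allclose(m[3], [0.0, 0.0, 0.0, 1.0], atol=1e-12):
            raise ValueError("bottom row of a homogeneous transform must be (0,0,0,1)")
        object.__setattr__(self, "matrix", m)

    # -- constructors ------------------------------------------------------
    @classmethod
    def identity(cls, frame: str = "?") -> "HomogeneousTransform":
        return cls(np.eye(4), from_frame=frame, to_frame=frame)

    @classmethod
    def from_rotation_translation(
        cls,
        rotation: np.ndarray,
        translation: np.ndarray,
        from_frame: str = "?",
        to_frame: str = "?",
    ) -> "HomogeneousTransform":
        m = np.eye(4)
        m[:3, :3] = np.asarray(rotation, dtype=float)
        m[:3, 3] = np.asarray(translation, dtype=float)
        return cls(m, from_frame=from_frame, to_frame=to_frame)

    @classmethod
    def from_translation(
        cls, translation, from_frame: str = "?", to_frame: str = "?"
    ) -> "HomogeneousTransform":
        return cls.from_rotation_translation(np.eye(3), translation, from_frame, to_frame)

    # -- accessors ---------------------------------------------------------
    @property
    def rotation(self) -> np.ndarray:
        return self.matrix[:3, :3]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:3, 3]

    @property
    def is_rigid(self) -> bool:
        r = self.rotation
        return (
            np.allclose(r @ r.T, np.eye(3), atol=_RIGID_TOL)
            and abs(np.linalg.det(r) - 1.0) < _RIGID_TOL
        )

    def require_rigid(self) -> "HomogeneousTransform":
        if not self.is_rigid:
            raise ValueError(
                f"transform {self.from_frame}->{self.to_frame} is not rigid "
                "(rotation block not in SO(3))"
            )
        return self

    # -- algebra -----------------------------------------------------------
    def compose(self, other: "HomogeneousTransform") -> "HomogeneousTransform":
        """Return ``self @ other`` (apply ``other`` first), frame-checked.

        ``self`` maps {m}->{j}, ``other`` maps {i}->{m}; the result maps
        {i}->{j}.  Unknown frames (``"?"``) match anything.
        """
        if "?" not in (self.from_frame, other.to_frame) and self.from_frame != other.to_frame:
            raise FrameChainError(
                f"cannot chain {other.from_frame}->{other.to_frame} into "
                f"{self.from_frame}->{self.to_frame}: frame names do not meet"
            )
        return HomogeneousTransform(
            self.matrix @ other.matrix,
            from_frame=other.from_frame,
            to_frame=self.to_frame,
        )

    def __matmul__(self, other: "HomogeneousTransform") -> "HomogeneousTransform":
        return self.compose(other)

    def inverse(self) -> "HomogeneousTransform":
        return HomogeneousTransform(
            np.linalg.inv(self.matrix), from_frame=self.to_frame, to_frame=self.from_frame
        )

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to a point (3,) or an array of points (..., 3)."""
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "from_frame": self.from_frame,
            "to_frame": self.to_frame,
            "matrix": [list(map(float, row)) for row in self.matrix],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HomogeneousTransform":
        return cls(
            np.asarray(d["matrix"], dtype=float),
            from_frame=d.get("from_frame", "?"),
            to_frame=d.get("to_frame", "?"),
        )

    def save(self, path) -> None:
        path = str(path)
        payload = self.to_dict()
        with open(path, "w") as fh:
            if path.endswith(".json"):
                json.dump(payload, fh, indent=2)
            else:
                yaml.safe_dump(payload, fh)

    @classmethod
    def load(cls, path) -> "HomogeneousTransform":
        path = str(path)
        with open(path) as fh:
            payload = json.load(fh) if path.endswith(".json") else yaml.safe_load(fh)
        return cls.from_dict(payload)
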