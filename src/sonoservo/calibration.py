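"""Probe-to-volume calibration for robotic ultrasound.

The pixel-to-base mapping chains base<-flange (forward kinematics),
flange<-probe (probe-holder CAD) and probe<-volume (calibration):

    bT_vol = bT_f · fT_p · pT_vol

Instead of a phantom-based spatial calibration, the probe-to-volume transform
is built from quantities every ultrasound station reports — volume size in
pixels and pixel spacing — under the assumption that the volume sits centered
under the probe tip:

    pT_vol,smp = pT_vol,grd · S,   o_x = (l/2)·s_x,  o_y = (w/2)·s_y,  o_z = 0

where S = diag(s_x, s_y, s_z, 1) is the spacing scaling.  The only remaining
unknown is the sign convention of the rotation R between the probe and volume
frames, which is resolved experimentally: translate the probe a small distance
along +probe-y while tracking a fixed structure in the volume xy-plane.  A
positive shift of the structure's volume-x coordinate means the axes are
opposed (R1); a negative shift means they agree (R2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .transforms import HomogeneousTransform

__all__ = [
    "VolumeSpec",
    "RotationChoice",
    "R1",
    "R2",
    "InconclusiveCalibrationError",
    "compose_base_to_volume",
    "build_simplified_probe_to_volume",
    "determine_rotation_sign",
    "pixel_to_base",
    "run_rotation_sign_experiment",
]


class InconclusiveCalibrationError(RuntimeError):
    """The calibration displacement produced no measurable image shift."""


@dataclass(frozen=True)
class VolumeSpec:
    """Ultrasound volume extents in pixels and spacing in mm/px."""

    length_px: int
    width_px: int
    depth_px: int
    spacing: tuple  # (s_x, s_y, s_z)

    def __post_init__(self) -> None:
        if min(self.length_px, self.width_px, self.depth_px) <= 0:
            raise ValueError("volume extents must be positive")
        if min(self.spacing) <= 0:
            raise ValueError("spacing must be positive")


@dataclass(frozen=True)
class RotationChoice:
    """One of the two admissible probe-to-volume rotation matrices."""

    name: str
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if not np.allclose(m @ m.T, np.eye(3), atol=1e-12) or abs(np.linalg.det(m) - 1) > 1e-12:
            raise ValueError("rotation choice must be in SO(3)")
        object.__setattr__(self, "matrix", m)


# Stored as literal constants; R1 is the axes-opposed case, R2 the axes-aligned
# case of the rotation-sign experiment.
R1 = RotationChoice("R1", np.array([[0.0, 0.0, -1.0], [-1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]))
R2 = RotationChoice("R2", np.array([[0.0, 0.0, 1.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]))


def compose_base_to_volume(
    bTf: HomogeneousTransform, fTp: HomogeneousTransform, pTvol: HomogeneousTransform
) -> HomogeneousTransform:
    """Chain bT_f · fT_p · pT_vol into the base-from-volume transform."""
    return bTf @ fTp @ pTvol


def build_simplified_probe_to_volume(
    rotation: RotationChoice, vol: VolumeSpec
) -> HomogeneousTransform:
    """Simplified probe-from-volume calibration matrix pT_vol,smp.

    Composes the rigid guess [R | (o_x, o_y, 0)] with the spacing scaling S.
    The depth offset o_z is neglected: it is only the small standoff between
    the probe-frame origin and the first transducer row.
    """
    s_x, s_y, s_z = (float(v) for v in vol.spacing)
    o = np.array([vol.length_px / 2.0 * s_x, vol.width_px / 2.0 * s_y, 0.0])
    grd = HomogeneousTransform.from_rotation_translation(
        rotation.matrix, o, from_frame="vol_mm", to_frame="p"
    )
    scale = np.diag([s_x, s_y, s_z, 1.0])
    S = HomogeneousTransform(scale, from_frame="vol", to_frame="vol_mm")
    return grd @ S


def determine_rotation_sign(x_start_px: float, x_end_px: float) -> RotationChoice:
    """Resolve the probe/volume rotation sign from the displacement test.

    ``x_start_px`` and ``x_end_px`` are the volume-x coordinates of the same
    tracked structure before and after a +probe-y translation.  A positive
    difference means volume-x and probe-y are opposed (R1); negative means
    they agree (R2); zero is inconclusive (repeat with a larger move).
    """
    diff = float(x_end_px) - float(x_start_px)
    if diff > 0:
        return R1
    if diff < 0:
        return R2
    raise InconclusiveCalibrationError(
        "no lateral image shift measured; repeat the calibration move with a larger displacement"
    )


def pixel_to_base(
    point_px, bTvol: HomogeneousTransform, vol: VolumeSpec | None = None
) -> np.ndarray:
    """Map a volume pixel (x, y, z) into base-frame millimetres."""
    p = np.asarray(point_px, dtype=float)
    if vol is not None:
        bounds = np.array([vol.length_px, vol.width_px, vol.depth_px], dtype=float)
        if np.any(p < 0) or np.any(p >= bounds):
            warnings.warn(f"pixel {tuple(p)} outside volume bounds {tuple(bounds)}", stacklevel=2)
    return bTvol.apply(p)


def run_rotation_sign_experiment(
    config,
    displacement_mm: float = 5.0,
    u_mm: float = 10.0,
    template_halfsize_px: int = 60,
):
    """Simulate the calibration move on the phantom and classify R1 vs R2.

    Renders a B-mode frame over the vessel, cuts a template around the vessel
    cross-section, translates the probe ``displacement_mm`` along +probe-y,
    renders again, and locates the template peak in the new frame.  The
    x-shift of the peak decides the rotation sign.  The default 5 mm move is
    about one vessel radius — large enough for an unambiguous shift, small
    enough to keep the structure in view.

    Returns ``(choice, x_start_px, x_end_px)``.
    """
    from . import phantom as ph
    from .tracking import Template, match_template, rank_template_candidates

    geometry = ph.generate_geometry(config)
    pose0 = ph.canonical_probe_pose(config, u_mm=u_mm)
    frame0 = ph.render_bmode(geometry, pose0, config, time_s=0.0)
    if frame0.true_center_px is None:
        raise InconclusiveCalibrationError("vessel not visible at the calibration start pose")
    cx, cy = frame0.true_center_px
    hs = template_halfsize_px
    x0, y0 = int(round(cx)) - hs, int(round(cy)) - hs
    patch = frame0.pixels[y0 : y0 + 2 * hs + 1, x0 : x0 + 2 * hs + 1]
    template = Template(pixels=patch, origin_px=(x0, y0), source_frame_index=0)

    # +probe-y is -base-y under the canonical scanning orientation
    probe_y_base = pose0.rotation[:, 1]
    shift = displacement_mm * probe_y_base
    pose1 = HomogeneousTransform.from_rotation_translation(
        pose0.rotation, pose0.translation + shift, from_frame="p", to_frame="b"
    )
    frame1 = ph.render_bmode(geometry, pose1, config, time_s=0.04)
    cmap = match_template(frame1, template)
    candidates = rank_template_candidates(cmap, n=1)
    if not candidates:
        raise InconclusiveCalibrationError("structure lost after the calibration move")
    x_end = candidates[0].position_px[0]
    return determine_rotation_sign(cx, x_end), float(cx), float(x_end)
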